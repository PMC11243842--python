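"""Record schemas, readers/writers and configuration loading.

JSON-lines is the canonical interchange format (one flat record object per
line); CSV is a flattened convenience view with identical columns.  Each
record carries the subject identifier and an opaque ``tag_number`` linking
the physiological data to the subject's identity record, mirroring a
two-node store (device data keyed by tag, user data keyed by identity).

A full protocol record flattens to::

    subject_id, tag_number, day, phase, timestamp, hr, prv, rr, spo2,
    gsr, bt, sbp, dbp, glucose, glucose_state, latent_stress

Bare eight-parameter samples (no day/phase/glucose columns) are accepted
wherever only the vitals are needed.  Timestamps are ISO 8601 with an
explicit offset.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml

from .bands import GlucoseReading, GlucoseState
from .cohort import CohortSpec, Phase, ProtocolRecord
from .engine import (
    CRISP_CUTS,
    EngineConfig,
    Parameter,
    PhysioSample,
    ReferenceRange,
    StressLabel,
)
from .errors import InvalidInputError, SchemaError

__all__ = [
    "SCHEMA_VERSION",
    "RecordFormat",
    "RecordFile",
    "flatten_record",
    "read_records",
    "write_records",
    "default_config_dict",
    "load_config",
]

log = logging.getLogger("fuzzphys")

SCHEMA_VERSION = "1.0"

_VITAL_FIELDS = [p.value for p in Parameter]
_PROTOCOL_FIELDS = ["day", "phase", "glucose", "glucose_state", "latent_stress"]
_ALL_FIELDS = (
    ["subject_id", "tag_number", "day", "phase", "timestamp"]
    + _VITAL_FIELDS
    + ["glucose", "glucose_state", "latent_stress"]
)


class RecordFormat(str, enum.Enum):
    CSV = "csv"
    JSONL = "jsonl"


@dataclass(frozen=True)
class RecordFile:
    format: RecordFormat
    records: list
    schema_version: str = SCHEMA_VERSION


def _infer_format(path: Path, fmt: RecordFormat | str | None) -> RecordFormat:
    if fmt is not None:
        return RecordFormat(fmt)
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("jsonl", "ndjson", "json"):
        return RecordFormat.JSONL
    if suffix == "csv":
        return RecordFormat.CSV
    raise InvalidInputError(f"cannot infer record format from {path.name!r}")


def flatten_record(record: ProtocolRecord | PhysioSample, tag_number: str = "") -> dict:
    """Flatten a record into the interchange row schema."""
    if isinstance(record, PhysioSample):
        row: dict[str, Any] = {
            "subject_id": record.subject_id,
            "tag_number": tag_number,
            "timestamp": record.timestamp.isoformat(),
        }
        row.update({p.value: record.value(p) for p in Parameter})
        return row
    row = flatten_record(record.sample, tag_number)
    row.update(
        {
            "day": record.day,
            "phase": record.phase.value,
            "glucose": record.glucose.value,
            "glucose_state": record.glucose.state.value,
            "latent_stress": record.latent_stress.name.capitalize(),
        }
    )
    return row


def _parse_timestamp(raw: str, line: int) -> datetime:
    try:
        return datetime.fromisoformat(str(raw))
    except ValueError:
        raise SchemaError(f"line {line}: invalid timestamp {raw!r}") from None


def _parse_row(row: dict, line: int):
    """Validate one flat row, returning a ProtocolRecord or PhysioSample."""
    for field in ("subject_id", "timestamp"):
        if not row.get(field):
            raise SchemaError(f"line {line}: missing required field {field!r}")
    vitals = {}
    for name in _VITAL_FIELDS:
        if row.get(name) in (None, ""):
            raise SchemaError(f"line {line}: missing vital {name!r}")
        try:
            vitals[name] = float(row[name])
        except (TypeError, ValueError):
            raise SchemaError(
                f"line {line}: field {name!r} is not numeric: {row[name]!r}"
            ) from None
    ts = _parse_timestamp(row["timestamp"], line)
    try:
        sample = PhysioSample(subject_id=str(row["subject_id"]), timestamp=ts, **vitals)
    except InvalidInputError as exc:
        raise SchemaError(f"line {line}: {exc}") from None

    has_protocol = any(row.get(f) not in (None, "") for f in _PROTOCOL_FIELDS)
    if not has_protocol:
        return sample
    try:
        glucose = GlucoseReading(
            value=float(row["glucose"]),
            state=GlucoseState(row.get("glucose_state", "fasting")),
            timestamp=ts,
        )
        return ProtocolRecord(
            subject_id=sample.subject_id,
            day=int(row["day"]),
            phase=Phase(row["phase"]),
            timestamp=ts,
            sample=sample,
            glucose=glucose,
            latent_stress=StressLabel[str(row["latent_stress"]).upper()],
        )
    except (KeyError, TypeError, ValueError, InvalidInputError) as exc:
        raise SchemaError(f"line {line}: invalid protocol fields: {exc}") from None


def read_records(path: str | Path, fmt: RecordFormat | str | None = None) -> RecordFile:
    """Read and validate a record file; malformed rows name their line."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows: list[tuple[dict, int]] = []
    if fmt is RecordFormat.JSONL:
        with path.open() as fh:
            for i, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    rows.append((json.loads(raw), i))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {i}: invalid JSON: {exc}") from None
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            # data rows start on line 2, after the header
            rows = [(row, i) for i, row in enumerate(reader, start=2)]
    if not rows:
        log.warning("record file %s is empty", path)
        return RecordFile(format=fmt, records=[])
    return RecordFile(format=fmt, records=[_parse_row(r, i) for r, i in rows])


def write_records(
    records: Iterable[ProtocolRecord | PhysioSample] | Iterable[dict],
    path: str | Path,
    fmt: RecordFormat | str | None = None,
    extra_fields: Sequence[str] = (),
) -> None:
    """Write records (or pre-flattened row dicts) as JSONL or CSV."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows = [
        r if isinstance(r, dict) else flatten_record(r)
        for r in records
    ]
    if fmt is RecordFormat.JSONL:
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
        return
    columns = [f for f in _ALL_FIELDS if any(f in r for r in rows)]
    columns += [f for f in extra_fields if f not in columns]
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def default_config_dict() -> dict:
    """The full default configuration as a plain mapping (YAML-serializable)."""
    engine = EngineConfig()
    spec = CohortSpec()
    return {
        "ranges": {
            p.value: {"low_cut": lo, "high_cut": hi}
            for p, (lo, hi) in CRISP_CUTS.items()
        },
        "engine": {
            "tnorm": engine.tnorm.value,
            "transition_fraction": engine.transition_fraction,
            "degenerate_policy": engine.degenerate_policy.value,
            "t_low": engine.t_low,
            "t_high": engine.t_high,
        },
        "cohort": {
            "n_subjects": spec.n_subjects,
            "n_male": spec.n_male,
            "age_mean": spec.age_mean,
            "age_sd": spec.age_sd,
            "age_range": list(spec.age_range),
            "stress_glucose_coupling": spec.stress_glucose_coupling,
            "stress_bp_coupling": spec.stress_bp_coupling,
            "glucose_bp_coupling": spec.glucose_bp_coupling,
            "noise_sd": {p.value: v for p, v in spec.noise_sd.items()},
            "glucose_noise_sd": spec.glucose_noise_sd,
            "meal_rise": spec.meal_rise,
            "med_drop": spec.med_drop,
            "n_days": spec.n_days,
        },
        "ppg": {"spo2_intercept": 110.0, "spo2_slope": 25.0, "fs": 300.0},
    }


@dataclass(frozen=True)
class LoadedConfig:
    ranges: dict[Parameter, ReferenceRange]
    engine: EngineConfig
    cohort: CohortSpec
    ppg: dict


def load_config(path: str | Path | None = None) -> LoadedConfig:
    """Merge a YAML config file over the defaults and build typed objects."""
    merged = default_config_dict()
    if path is not None:
        with Path(path).open() as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise InvalidInputError(f"config file {path} must contain a mapping")
        for section, values in user.items():
            if section not in merged:
                raise InvalidInputError(f"unknown config section {section!r}")
            if isinstance(values, dict):
                for key, v in values.items():
                    if isinstance(merged[section].get(key), dict) and isinstance(v, dict):
                        merged[section][key].update(v)
                    else:
                        merged[section][key] = v
            else:
                merged[section] = values

    eng_cfg = merged["engine"]
    engine = EngineConfig(
        tnorm=eng_cfg["tnorm"],
        transition_fraction=float(eng_cfg["transition_fraction"]),
        degenerate_policy=eng_cfg["degenerate_policy"],
        t_low=float(eng_cfg["t_low"]),
        t_high=float(eng_cfg["t_high"]),
    )
    fraction = engine.transition_fraction
    ranges = {}
    for p in Parameter:
        cuts = merged["ranges"][p.value]
        lo, hi = float(cuts["low_cut"]), float(cuts["high_cut"])
        delta = fraction * (hi - lo)
        if p is Parameter.SPO2:
            delta = min(delta, 100.0 - hi)
        ranges[p] = ReferenceRange(p, lo, hi, delta)

    coh = dict(merged["cohort"])
    coh["age_range"] = tuple(coh["age_range"])
    cohort = CohortSpec(**coh)
    return LoadedConfig(ranges=ranges, engine=engine, cohort=cohort, ppg=merged["ppg"])
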