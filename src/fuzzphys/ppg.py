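"""Two-channel PPG synthesis and vital-sign extraction.

The sensing chain samples infrared and red photoplethysmograms at 300 Hz
and derives heart rate, pulse-rate variability (RMSSD), respiratory rate
and SpO2 from them, emitting two estimates of each parameter per second.

The synthesizer produces a quasi-periodic pulse waveform (systolic peak
plus a smaller dicrotic bump) whose amplitude and baseline are modulated at
the respiratory frequency.  The red channel's AC/DC perfusion ratio is set
relative to the infrared channel by inverting the same linear SpO2
calibration the estimator applies, so clean signals round-trip.

Estimator choices (adaptive-prominence peak picking with a 0.25 s
refractory period, periodogram-based respiratory frequency in 0.1-0.5 Hz,
linear ratio-of-ratios calibration SpO2 = 110 - 25 R) are standard
pulse-oximetry practice; the calibration coefficients are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidSignalError,
    NoBeatsError,
)

__all__ = [
    "PPGSignal",
    "BeatSeries",
    "SpO2Calibration",
    "RespiratoryEstimate",
    "synthesize_ppg",
    "detect_peaks",
    "estimate_hr",
    "estimate_prv_rmssd",
    "estimate_rr",
    "estimate_spo2",
    "spo2_from_ratio",
    "extract_vitals",
]

DEFAULT_FS = 300.0  # samples per second per channel
REFRACTORY_S = 0.25  # minimum inter-beat spacing enforced by the peak picker
RESP_BAND_HZ = (0.1, 0.5)  # plausible respiratory frequencies (6-30 brpm)

#: Infrared perfusion index (AC/DC) used by the synthesizer; the red
#: channel's perfusion follows from the target SpO2.
_IR_PERFUSION = 0.02


@dataclass(frozen=True)
class SpO2Calibration:
    """Linear ratio-of-ratios calibration: SpO2 = intercept - slope * R."""

    intercept: float = 110.0
    slope: float = 25.0

    def spo2(self, ratio: float) -> float:
        return float(np.clip(self.intercept - self.slope * ratio, 0.0, 100.0))

    def ratio(self, spo2: float) -> float:
        return (self.intercept - spo2) / self.slope


DEFAULT_CALIBRATION = SpO2Calibration()


@dataclass(frozen=True)
class PPGSignal:
    """Synchronous infrared/red photoplethysmogram pair."""

    fs: float
    ir: np.ndarray
    red: np.ndarray
    start_time: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if len(self.ir) != len(self.red):
            raise InvalidInputError("IR and red channels must have equal length")

    @property
    def duration(self) -> float:
        return len(self.ir) / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.ir)) / self.fs

    def segment(self, t0: float, t1: float) -> "PPGSignal":
        i0 = max(0, int(round((t0 - self.start_time) * self.fs)))
        i1 = min(len(self.ir), int(round((t1 - self.start_time) * self.fs)))
        return PPGSignal(self.fs, self.ir[i0:i1], self.red[i0:i1],
                         self.start_time + i0 / self.fs)


@dataclass(frozen=True)
class BeatSeries:
    """Detected systolic peak times (s) and the inter-beat intervals (ms)."""

    peak_times: np.ndarray
    _ibis_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        if len(pt) and np.any(np.diff(pt) <= 0):
            raise InvalidInputError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", pt)

    @property
    def ibis_ms(self) -> np.ndarray:
        if self._ibis_ms is not None:
            return self._ibis_ms
        return np.diff(self.peak_times) * 1000.0

    @classmethod
    def from_ibis_ms(cls, ibis_ms, start: float = 0.0) -> "BeatSeries":
        """Build a series from exact intervals (kept verbatim, not re-derived)."""
        ibis = np.asarray(ibis_ms, dtype=float)
        times = start + np.concatenate(([0.0], np.cumsum(ibis))) / 1000.0
        return cls(peak_times=times, _ibis_ms=ibis)


@dataclass(frozen=True)
class RespiratoryEstimate:
    """Respiratory rate in breaths/min with a modulation-strength flag."""

    value: float
    low_confidence: bool = False

    def __float__(self) -> float:
        return self.value


# --------------------------------------------------------------------------
# Synthesis
# --------------------------------------------------------------------------

def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    """Single-period pulse: systolic peak at phase 0.3, dicrotic bump at 0.62."""
    main = np.exp(-0.5 * ((phase - 0.30) / 0.055) ** 2)
    dicrotic = 0.30 * np.exp(-0.5 * ((phase - 0.62) / 0.10) ** 2)
    return main + dicrotic


def synthesize_ppg(
    hr: float,
    rr: float,
    spo2: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    calibration: SpO2Calibration = DEFAULT_CALIBRATION,
) -> PPGSignal:
    """Generate a clean or noisy two-channel PPG at the requested vitals.

    Parameters are heart rate (beats/min, 20-240), respiratory rate
    (breaths/min), target SpO2 (%), duration (s), additive Gaussian noise
    standard deviation (in units of the DC level, 1.0) and an RNG seed.
    """
    if not (20.0 <= hr <= 240.0):
        raise InvalidInputError(f"heart rate {hr} outside plausible 20-240 bpm")
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if not (0.0 < rr <= 60.0):
        raise InvalidInputError(f"respiratory rate {rr} outside (0, 60] brpm")
    if not (50.0 <= spo2 <= 100.0):
        raise InvalidInputError(f"SpO2 {spo2} outside plausible 50-100%")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    beat_period = 60.0 / hr
    phase = np.mod(t, beat_period) / beat_period
    pulse = _pulse_shape(phase)
    pulse = pulse - pulse.mean()

    f_resp = rr / 60.0
    resp = np.sin(2.0 * np.pi * f_resp * t)
    # amplitude modulation of the pulse plus baseline wander, both at the
    # respiratory frequency and shared between channels so the red/IR AC
    # ratio is preserved exactly
    modulated = pulse * (1.0 + 0.20 * resp) + 0.25 * resp

    ratio = calibration.ratio(spo2)
    ir = 1.0 + _IR_PERFUSION * modulated
    red = 1.0 + ratio * _IR_PERFUSION * modulated
    if noise_sd > 0:
        ir = ir + rng.normal(0.0, noise_sd, n)
        red = red + rng.normal(0.0, noise_sd, n)
    return PPGSignal(fs=fs, ir=ir, red=red)


# --------------------------------------------------------------------------
# Beat detection and time-domain vitals
# --------------------------------------------------------------------------

def detect_peaks(ppg: PPGSignal) -> BeatSeries:
    """Locate systolic peaks in the infrared channel.

    The channel is band-passed to the cardiac band (0.5-8 Hz, zero-phase
    Butterworth) to suppress baseline wander and wideband noise, then local
    maxima are kept if they clear an adaptive prominence threshold (half the
    5th-95th percentile spread) and are at least 0.25 s apart.
    """
    x = np.asarray(ppg.ir, dtype=float)
    if len(x) < 2 * ppg.fs:
        raise InsufficientDataError("need at least 2 s of signal")
    if np.ptp(x) == 0:
        raise NoBeatsError("flat signal: no pulsatile component")
    sos = sps.butter(2, [0.5, 8.0], btype="bandpass", fs=ppg.fs, output="sos")
    detrended = sps.sosfiltfilt(sos, x)
    spread = np.percentile(detrended, 95) - np.percentile(detrended, 5)
    if spread <= 0:
        raise NoBeatsError("flat signal: no pulsatile component")
    peaks, _ = sps.find_peaks(
        detrended,
        distance=max(1, int(REFRACTORY_S * ppg.fs)),
        prominence=0.5 * spread,
    )
    if len(peaks) == 0:
        raise NoBeatsError("no beats detected")
    return BeatSeries(peak_times=ppg.start_time + peaks / ppg.fs)


def estimate_hr(beats: BeatSeries) -> float:
    """Mean heart rate in beats/min: 60000 / mean inter-beat interval (ms)."""
    ibis = beats.ibis_ms
    if len(ibis) < 1:
        raise InsufficientDataError("need at least 2 beats to estimate HR")
    return 60000.0 / float(np.mean(ibis))


def estimate_prv_rmssd(beats: BeatSeries) -> float:
    """RMSSD pulse-rate variability in ms.

    Root mean square of successive differences of the inter-beat intervals;
    invariant to adding a constant to every interval.
    """
    ibis = beats.ibis_ms
    if len(ibis) < 2:
        raise InsufficientDataError("need at least 3 beats (2 intervals) for RMSSD")
    diffs = np.diff(ibis)
    return float(np.sqrt(np.mean(diffs ** 2)))


# --------------------------------------------------------------------------
# Respiratory rate and SpO2
# --------------------------------------------------------------------------

def estimate_rr(
    ppg: PPGSignal,
    beats: BeatSeries | None = None,
    min_duration: float = 30.0,
) -> RespiratoryEstimate:
    """Respiratory rate from the 0.1-0.5 Hz modulation of the PPG baseline.

    A zero-padded periodogram of the mean-removed infrared channel is
    evaluated over the respiratory band and the dominant frequency is
    converted to breaths/min.  The estimate is flagged low-confidence when
    the band peak does not stand out from the band's median power.
    """
    x = np.asarray(ppg.ir, dtype=float)
    if len(x) < min_duration * ppg.fs:
        raise InsufficientDataError(
            f"need at least {min_duration:g} s of signal for a stable "
            f"respiratory estimate, got {len(x) / ppg.fs:.1f} s"
        )
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(len(x) * 8)))
    freqs, power = sps.periodogram(x, fs=ppg.fs, nfft=nfft)
    band = (freqs >= RESP_BAND_HZ[0]) & (freqs <= RESP_BAND_HZ[1])
    band_power = power[band]
    band_freqs = freqs[band]
    peak_idx = int(np.argmax(band_power))
    med = float(np.median(band_power))
    low_conf = med <= 0 or band_power[peak_idx] < 20.0 * med
    return RespiratoryEstimate(
        value=float(band_freqs[peak_idx] * 60.0), low_confidence=bool(low_conf)
    )


def spo2_from_ratio(
    ratio: float, calibration: SpO2Calibration = DEFAULT_CALIBRATION
) -> float:
    """Map a red/IR ratio-of-ratios through the linear calibration, clipped to [0, 100]."""
    if not math.isfinite(ratio) or ratio < 0:
        raise InvalidInputError(f"ratio-of-ratios must be finite and >= 0, got {ratio!r}")
    return calibration.spo2(ratio)


def estimate_spo2(
    ppg: PPGSignal,
    beats: BeatSeries | None = None,
    calibration: SpO2Calibration = DEFAULT_CALIBRATION,
) -> float:
    """SpO2 from the ratio-of-ratios of the two channels.

    AC is taken as the standard deviation and DC as the mean of each
    channel over the supplied window; R = (AC/DC)_red / (AC/DC)_ir.
    """
    ir = np.asarray(ppg.ir, dtype=float)
    red = np.asarray(ppg.red, dtype=float)
    if len(ir) < ppg.fs:  # need at least one beat's worth of samples
        raise InsufficientDataError("need at least 1 s of signal for SpO2")
    dc_ir, dc_red = float(np.mean(ir)), float(np.mean(red))
    if dc_ir == 0 or dc_red == 0:
        raise InvalidSignalError("zero DC component in a PPG channel")
    ac_ir = float(np.std(ir))
    ac_red = float(np.std(red))
    if ac_ir == 0:
        raise InvalidSignalError("no pulsatile component in the IR channel")
    ratio = (ac_red / dc_red) / (ac_ir / dc_ir)
    return spo2_from_ratio(ratio, calibration)


# --------------------------------------------------------------------------
# Windowed extractor (2 estimates per second)
# --------------------------------------------------------------------------

def extract_vitals(
    ppg: PPGSignal,
    window_s: float = 8.0,
    hop_s: float = 0.5,
    rr_window_s: float = 30.0,
    calibration: SpO2Calibration = DEFAULT_CALIBRATION,
) -> pd.DataFrame:
    """Sliding-window vitals at the sensing chain's 2 Hz output cadence.

    Each row is one 8 s analysis window advanced by 0.5 s (two estimates
    per second of signal) with columns ``t`` (window end, s), ``hr``,
    ``prv_rmssd``, ``rr`` and ``spo2``.  The respiratory estimate uses a
    longer trailing window and is NaN until enough signal has accrued.
    """
    if ppg.duration < window_s:
        raise InsufficientDataError(
            f"signal shorter than one {window_s:g} s analysis window"
        )
    rows = []
    t_end = ppg.start_time + window_s
    last = ppg.start_time + ppg.duration
    while t_end <= last + 1e-9:
        win = ppg.segment(t_end - window_s, t_end)
        hr = prv = spo2 = rr = float("nan")
        try:
            beats = detect_peaks(win)
            hr = estimate_hr(beats)
            prv = estimate_prv_rmssd(beats)
            spo2 = estimate_spo2(win, beats, calibration)
        except (NoBeatsError, InsufficientDataError):
            pass
        if t_end - ppg.start_time >= rr_window_s:
            rr_win = ppg.segment(t_end - rr_window_s, t_end)
            try:
                rr = estimate_rr(rr_win, min_duration=rr_window_s).value
            except InsufficientDataError:
                pass
        rows.append({"t": t_end, "hr": hr, "prv_rmssd": prv, "rr": rr, "spo2": spo2})
        t_end += hop_s
    return pd.DataFrame(rows)
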