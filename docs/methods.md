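# Methods

## Fuzzy inference engine

The engine maps an eight-parameter physiological sample onto a continuous
stress score in [1, 3] and one of three labels (Calm = 1, Normal = 2,
Stressed = 3).

**Reference bands.** Each parameter has a crisp Low/Normal/High band with
the cut points belonging to Normal:

| parameter | units | Low | Normal | High |
|---|---|---|---|---|
| HR | beats/min | < 60 | 60–90 | > 90 |
| PRV (RMSSD) | ms | < 32 | 32–77 | > 77 |
| RR | breaths/min | < 12 | 12–18 | > 18 |
| SpO2 | % | < 97 | 97–99 | > 99 |
| GSR | kOhm | < 30 | 30–50 | > 50 |
| BT | °C | < 36.5 | 36.5–37.5 | > 37.5 |
| SBP | mmHg | < 90 | 90–120 | > 120 |
| DBP | mmHg | < 60 | 60–80 | > 80 |

The body-temperature Low cut and the start of its Normal band are both
taken as 36.5 °C; published reference tables sometimes quote 36.0 °C for
the latter, and 36.5 °C was adopted so the bands partition the axis.

GSR is expressed as skin *resistance*: sweating under stress lowers it, so
the Stressed rule matches Low(GSR) and the Calm rule High(GSR). The
simulator honours the same sign convention.

**Membership functions.** Only crisp cuts are published for these bands,
so the vertex placement is a package design choice: each cut point gets a
linear transition of half-width δ_p = f · (high_cut − low_cut), with the
transition fraction f = 0.10 by default (configurable in (0, 0.5)). *Low*
is 1 below low_cut − δ and falls linearly to 0 at low_cut + δ; *High*
mirrors this around high_cut; *Normal* is a triangle with apex at the band
midpoint and feet at low_cut − δ and high_cut + δ. As δ → 0 the degrees
degenerate to the crisp bands, which the tests exploit as an oracle. SpO2
vertices are clipped so none exceeds the physical ceiling of 100 %. For
any value at most two of the three degrees are nonzero.

**Rule aggregation.** The conjunction Λ of the eight antecedent degrees is
configurable: `mean` (default), `min`, or `product`. The published rule
base does not fix the operator; with an eight-way strict minimum (or
product) a single out-of-pattern parameter zeroes all three rules and the
defuzzification denominator vanishes for most realistic samples, whereas
the arithmetic mean keeps graded activations. The strict t-norms remain
available for fidelity experiments.

**Defuzzification.** The score is the weighted average of the rule
consequents, Stress = (R1·1 + R2·2 + R3·3)/(R1 + R2 + R3) — a
Sugeno-style weighted average over singleton consequents (equal
activations give exactly 2). If all activations are zero the default
policy returns score 2 flagged `degenerate=True`; a strict policy that
raises is available. Labels: Calm below 1.5, Stressed above 2.5, Normal
otherwise (thresholds on the boundary map to Normal). The computed score
is clamped to [1, 3] to guard floating-point round-off.

## Clinical banding

Glucose categories use prandial-state-specific cuts (mg/dL): fasting —
hypoglycemia < 70, normal 70–99, pre-diabetes 100–125, diabetes > 125;
post-meal — hypoglycemia < 70, normal 70–139, pre-diabetes 140–199,
diabetes > 199. Values in the printed gaps (e.g. fasting 99.5) are
assigned to the lower band (normal), making the mapping total. The
overall blood-pressure band is High if either component is High, Low if
either is Low and none High, else Normal; the components are also
reported separately, and the combination rule is package plumbing rather
than a published convention.

## PPG chain

The synthesizer generates 300 Hz IR/red waveforms: a periodic pulse shape
(narrow systolic peak at 30 % of the beat period, a dicrotic bump of 0.30
relative amplitude at 62 %) is amplitude-modulated by ±20 % at the
respiratory frequency and summed with a respiratory baseline wander of
0.25 relative amplitude; both channels share the same modulated waveform,
scaled by their AC/DC perfusion (IR fixed at 0.02, red at R × 0.02 with R
obtained by inverting the SpO2 calibration), so the ratio-of-ratios is
exact by construction. Additive white Gaussian noise is optional;
generation is seed-deterministic.

Estimators (none of which is published for this sensing chain; all are
standard pulse-oximetry practice and fixed here as design choices):

- **Peak detection** — zero-phase Butterworth band-pass 0.5–8 Hz, then
  local maxima with an adaptive prominence threshold (half the 5th–95th
  percentile spread) and a 0.25 s refractory period.
- **HR** — 60000 / mean inter-beat interval (ms); needs ≥ 2 beats.
- **PRV** — RMSSD = √(mean of squared successive IBI differences); needs
  ≥ 2 intervals; shift-invariant by construction.
- **RR** — dominant frequency of a zero-padded periodogram of the
  mean-removed IR channel restricted to 0.1–0.5 Hz, × 60; requires ≥ 30 s
  for a stable estimate and is flagged low-confidence when the band peak
  is under 20× the band's median power (no visible modulation).
- **SpO2** — R = (AC/DC)_red / (AC/DC)_ir with AC the window standard
  deviation and DC the mean, mapped through SpO2 = 110 − 25 R (clipped to
  [0, 100]; coefficients configurable).

The windowed extractor slides an 8 s window with a 0.5 s hop, matching the
hardware's two estimates per second; the respiratory estimate uses a 30 s
trailing window and is NaN until one has accrued.

## Synthetic cohort

The generator emulates the validation study's structure, not its data: a
cohort of 128 diabetic volunteers (68 male, 60 female) with ages drawn
from a normal(42, 17) truncated to 12–75 years (the per-sex means 41/43
are collapsed to the overall 42), and per subject a five-day protocol
with four acquisitions a day: ~40 min after breakfast (digestion has
raised glucose), ~60 min after the morning medication (glucose has
fallen), before lunch, and ~40 min after lunch. Clock times 08:40, 10:00,
12:30 and 13:40 implement those latencies; the exact times are a
documented choice, configurable only through the code.

Per record a latent stress class is drawn (uniform prevalence by
default). The eight vitals are placed at a band target dictated by that
class's rule direction — the Normal-band midpoint, or 25 % of the band
width beyond the Low/High cut, far enough that memberships saturate at
the default transition fraction — and perturbed by per-parameter Gaussian
noise (defaults: HR 3 bpm, PRV 4 ms, RR 0.8 brpm, SpO2 0.3 %, GSR 2 kOhm,
BT 0.1 °C, SBP 3 / DBP 2 mmHg, glucose 5 mg/dL, roughly the repeatability
of consumer-grade sensors). Glucose is baseline (uniform 75–170 mg/dL,
spanning normal to diabetic fasting bands) plus a +60 mg/dL meal excursion
at the post-meal phases, a net −29 mg/dL at the post-medication phase
(residual meal rise minus a 50 mg/dL dose effect), plus 15 mg/dL per
latent stress step. Blood pressure adds 5 mmHg per stress step and
0.08 mmHg per mg/dL of glucose excursion to both components, plus a
subject-level offset; a floor keeps SBP > DBP.

Consequences used as test oracles: at zero noise every vital sits in its
class's crisp band, post-lunch glucose exceeds pre-lunch glucose every
day, and within a fixed phase glucose is strictly increasing in the
latent stress level (Spearman ρ = 1). The label-recovery harness runs the
engine over a generated dataset and scores it against the latent classes;
at zero noise recovery is essentially perfect, and it degrades as noise
grows.

What the simulator deliberately does not model: pharmacokinetic realism
beyond the two fixed latencies, circadian variation beyond the four
phases, motion artefacts, sensor drift, inter-parameter correlations
beyond the stress/glucose/BP couplings, or any attempt to reproduce the
real validation database. Passing the recovery tests therefore shows the
engine is consistent with its own band semantics under realistic sensor
noise — not that it attains the published field accuracy, whose confusion
matrix cannot be rebuilt from the published tables alone. The one check
that does touch the published numbers is internal consistency: the F1
row of the published metric table equals the harmonic mean of its
precision and sensitivity rows (0.94 / 0.85 / 0.90 to two decimals).

"Accuracy" in the per-class metric table is one-vs-rest accuracy
(TP+TN)/N — the only reading under which five distinct per-class values
coexist. Metric cells with a zero denominator are reported as NaN, never
as 0.

## Problem sizes

The default cohort (128 subjects × 20 records) is used for the recovery
experiment; the noise-degradation check averages 10 seeds at 32 subjects
per condition, and the metrics oracle uses 100 random fixtures of 20–120
records — sizes at which every statistic concerned is stable to well
inside its test tolerance.
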