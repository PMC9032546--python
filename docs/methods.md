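# Methods

## The measurement model

The bending-and-return (b and r) test records a person performing 50 trunk
flexion–return cycles with a six-channel IMU fixed on the sacrum (X to the
left, Y up, Z backwards as worn), sampled at 100 Hz. The analysis treats the
movement as essentially sagittal: the pitch rate GyrX carries the planned
movement, and all other channels carry either its geometric consequences
(gravity projection, centripetal acceleration) or unplanned variation.

Protocol layout of a recording: quiet standing, a left–right rotation
marker, a short pause, the 50 cycles, a quiet tail. The marker exists purely
to localise the start of the test; the analysed span runs from the last
near-zero GyrX sample before the first cycle to the first near-zero sample
after the last cycle.

## Sample Entropy

SampEn(m, r) = −ln(A/B) with template pairs counted over the first N − m
embedding vectors (the ones that admit an (m+1)-length extension), Chebyshev
distance, inclusive (≤ r) matching, self-matches excluded, ordered-pair
counts. This is the counting convention of the short-time-series entropy
literature and guarantees A ≤ B. Consequences worth knowing:

- **Defaults** m = 2, r = 0.2 × SD, with SD the population (divisor N)
  standard deviation, since r scales with it. Both are exposed as
  parameters (`SampEnParams`), and r can be given in absolute units.
- **Undefined results.** When A = 0 (or B = 0) the entropy estimate is
  undefined; the result carries a NaN value and a `defined=False` flag
  rather than raising or returning +inf, so cohort aggregation skips it.
- **Length floor.** 200 samples by default (`min_length`), the conservative
  minimum for stable estimates on physiological data; the first analysis
  window (2 s at 100 Hz) sits exactly at this floor.
- **Boundary asymmetry under reversal.** Restricting B to the first N − m
  templates makes B (and hence the value, very slightly) depend on which end
  of the series is the boundary: a series and its reversal share A exactly
  but can differ in B by up to the pair count of one template. The effect is
  ~0.01 nats at N = 220 and shrinks with N; shift, negation and (in relative
  mode) affine transformations leave the counts exactly invariant.
- **Verification.** The production path is a compiled (numba) early-abort
  double loop; it must agree bit-exactly in A and B with an exhaustive
  per-template broadcasting oracle (`sampen_oracle`), and the test suite
  checks this on hundreds of series. No approximate neighbour search is
  used anywhere.

## Segmentation

The study located the test span by eye; the package automates it. Marker
detection requires the marker channel (GyrY by convention — a left–right
rotation is a rotation about the longitudinal axis as worn) to exceed
5 × `zero_tol`; the marker ends at the last crossing of half its peak. A
cycle "launch" is a sustained excursion of |GyrX| above 10% of its
post-marker peak for at least 0.25 s — the sustained-run requirement exists
because correlated sensor noise can spike above the threshold for a sample
or two during the pause. The span start is the last |GyrX| ≤ `zero_tol`
sample before the first launch; the end is the first such sample after the
last launch. Defaults: `zero_tol` = 2 °/s, launch fraction 0.1. Indices are
0-based and half-open throughout.

Trimming is idempotent: re-segmenting an already-trimmed recording (which no
longer contains a marker — pass `require_marker=False`) returns the full
span unchanged.

## Kinematics

Pitch angle = cumulative trapezoidal integral of GyrX (dt = 1/rate),
integration constant fixed at zero at the trim start. Detrending (on by
default) removes the slope of a least-squares line fitted to the integrated
trace while keeping the trim-start value, so angle[0] = 0 survives; this is
the minimal correction for gyro-bias drift, and a 1 °/s bias over a 100 s
test then moves the mean amplitude by < 2%.

Cycle extraction finds local extrema with prominence ≥ 0.2 × global range
and same-type separation ≥ half the median zero-crossing period of the
mean-centred trace (robust for 1–4 s cycles without merging neighbours).
Runs of same-type extrema are collapsed to the most extreme; amplitudes pair
each minimum with the following maximum. Because a bending test starts at
standing — the angle minimum — a trace whose first detected extremum is a
maximum gets the minimum of its leading segment inserted as the first
minimum, which is what makes 50 cycles yield 50 amplitudes. Ties in
extremum value resolve to the earliest index (via the underlying peak
finder).

## Windowed convergence

SampEn50 is the entropy of the whole trimmed span. Partial values SampEn10I
use half-open sample windows [10·rate, I·rate) relative to the trim start,
I = 12 … 70 s in 2 s steps, so window I holds exactly (I − 10)·rate samples.
The 10 s offset discards habituation; 70 s equalises window lengths (every
test in the reference cohort exceeded 72 s, and the synthetic generator
reproduces that property). The offset is interpreted from the *trim start*
(the recording start would include the marker); an offset option exists for
sensitivity checks. In relative mode, r is resolved per window from the
window's own SD — each window is self-contained — with `r_scope="full"`
preserving the alternative (one absolute r from the full-span SD). Tables
truncate with a warning when a span is shorter than 70 s.

## Agreement statistics

- Through-origin regression: k = Σxy/Σx², R² = 1 − Σ(y−kx)²/Σy². The
  uncentered total sum of squares is the standard convention for
  no-intercept fits (the centered variant can leave [0, 1]; it is available
  via `r2_convention="centered"`). The slope's standard error
  √(Σ(y−kx)²/(n−1)/Σx²) is reported for parameter-recovery checks.
- Duration selection: smallest tabulated I with R² strictly above 0.99 and
  k strictly above 0.95 (both thresholds configurable); `optimal_I=None`
  when none qualifies. Raising either threshold can never select a smaller
  window.
- Bland–Altman: bias = mean difference, limits = bias ± 1.96 × sample SD
  (divisor n − 1). In the pipeline the differences are *partial − full*
  (SampEn10I − SampEn50), so a short window that slightly underestimates the
  full-test entropy gives a small negative bias.
- Condition contrasts: two-sided Wilcoxon signed-rank for durations, SDs
  and entropies (exact null for n ≤ 25 without zeros or ties, tie-corrected
  normal approximation otherwise), paired t for amplitudes; identical pairs
  under the t-test report (0, 1). Significance level 5%, no multiplicity
  correction. Cross-condition Pearson correlations per channel complete the
  picture.

## The synthetic generator

Within cycle c (duration T_c, peak angle A_c), pitch follows the raised
cosine θ(τ) = A_c(1 − cos 2πτ)/2 — the simplest C¹ waveform with
zero-velocity endpoints, which is what trunk flexion between two rest
postures requires. GyrX is its analytic derivative; AccY = cos θ (g),
AccZ = sin θ + (GyrX in rad/s)²·sensor_radius/9.81; GyrZ receives a small
(10%) leak of the clean GyrX; AccX is noise only. All channels carry
stationary AR(1) noise (coefficient 0.9 by default — sensor and
physiological noise are correlated, and SampEn is sensitive to that
structure; innovation SD set so the stationary SD equals the configured
level). T_c and A_c are truncated-normal ([0.3, 3] × mean for durations,
positive for amplitudes) to exclude degenerate cycles.

Defaults encode the stool condition of the reference protocol: 50 cycles of
2.05 s with a 22° sacral pitch amplitude — back-computed from the reported
mean 50-cycle duration (~102.5 s) and pitch-rate SD (~24 °/s; for the
raised cosine, SDX ≈ Aπ/(T√2)). Gyro noise 2 °/s and accelerometer noise
0.02 g are plausible MEMS-plus-soft-tissue levels. The box condition scales
amplitude by 1.59 and cycle duration by 1.09, reproducing the reported
direction of both contrasts (box: larger, slightly slower, higher SDX).
Cohorts draw per-participant amplitude and noise multipliers with a 0.15
between-subject CV; the pace multiplier is truncated to [0.7, 1.45], the
relative spread of the reference cohort's test durations, which also
guarantees every test exceeds the 70 s window cap.

What the generator does *not* emulate: multi-joint coordination (hip, knee,
ankle contributions and lumbopelvic rhythm), fatigue or habituation drift
across the 50 cycles, non-sagittal movement beyond noise, magnetometer
output, and patient-specific dynamics. Passing tests on synthetic cohorts
therefore demonstrate that the *analysis chain* is correct and that its
qualitative orderings (channel entropy ranking, condition contrasts, window
convergence) follow from the assumed signal structure — not that real LBP
patients would show any particular entropy value.

## Problem sizes and numerical choices

Cohort-scale checks use 23 participants × 2 conditions (the reference cohort
size), 20 replicate seeds for qualitative orderings, and 50 replicates for
regression parameter recovery; unit tests use the smallest series the 200-
sample floor allows. Sampling-rate inference tolerates up to 1% of
non-conforming time steps, because dropping non-finite rows (which the
reader does, with a reported count) necessarily perforates the time axis.
File round-trips are exact: floats are written at full precision and parsed
with round-trip precision. Reports serialise with sorted keys so reruns are
byte-identical; NaN becomes JSON null.

## Known limitations

- Automatic segmentation replaces the study's manual trimming; on real
  recordings with unusual pre-test movement the marker convention (GyrY) and
  the launch heuristics may need the exposed parameters.
- SampEn parameters beyond (m = 2, r = 0.2·SD) were not tabulated in the
  source protocol; if a full-cohort reproduction disagrees, m, r and the SD
  convention are the first suspects and are all exposed.
- The entropy of short windows is estimated from as few as 200 samples;
  undefined (A = 0) results are possible at small r and are propagated as
  missing values, not errors.
- Amplitude estimation assumes the sagittal plane dominates; no orientation
  fusion is attempted.
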