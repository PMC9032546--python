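# bendr

Sample-entropy analysis of repeated trunk **bending-and-return** (b and r)
movements recorded by a single sacrum-mounted inertial measurement unit
(IMU).

The package is written for clinical-biomechanics researchers developing
wearable movement tests for low back pain. The b and r test asks a person to
bend forward, touch a target (a stool, or a box on the floor), and return to
standing, 50 times. A 100 Hz IMU on the sacrum records six channels —
accelerations AccX/AccY/AccZ (g) and angular velocities GyrX/GyrY/GyrZ
(°/s) — and the analysis asks two questions: *how complex is the movement*
(the structure of its variability, captured by Sample Entropy), and *how
short can the test be made* while still measuring the same thing.

## What it computes

**Sample Entropy.** For a series of length N, embedding dimension m and
tolerance r,

    SampEn(m, r) = −ln(A / B)

where B counts ordered template pairs (i ≠ j) whose length-m embedding
vectors match within Chebyshev distance r, and A counts the same pairs at
length m + 1; both counts run over the N − m templates that admit an
extension, and self-matches are excluded. Defaults are the standard m = 2,
r = 0.2 × SD (population SD). Low SampEn = regular, predictable movement.
The production implementation (a compiled double loop) is verified
bit-exactly, in the counts A and B, against an exhaustive O(N²) oracle.

**Kinematics.** The sagittal bending amplitude is obtained by trapezoidal
integration of GyrX (linear drift removed), alternating angle minima/maxima
are paired into per-cycle amplitudes A_i = max_i − min_i, and variability
magnitude is summarised by the SDs of the three angular-velocity channels
(SDX/SDY/SDZ).

**Optimal test duration.** SampEn50 (the full 50-cycle series) is compared
with SampEn10I, computed on windows from 10 s after the trim start to
I = 12, 14, …, 70 s (2 s = 200-sample increments). Across participants,
SampEn10I is regressed through the origin on SampEn50
(SampEn10I = k·SampEn50, uncentered R²); the optimal duration is the
smallest I with R² > 0.99 and k > 0.95, and Bland–Altman bias ± 1.96 SD
limits of agreement quantify the residual disagreement.

**Synthetic cohorts.** A first-class generator produces IMU recordings with
the statistical structure the analysis assumes — raised-cosine bending
cycles dominating GyrX, a left–right rotation marker on GyrY, gravity
projection on AccY/AccZ, centripetal coupling from GyrX into AccZ,
pure-noise AccX, truncated-normal cycle-to-cycle variability, and AR(1)
sensor noise whose SD acts as a complexity knob — so every stage has ground
truth without any data download.

## Worked example

```bash
python examples/optimal_test_duration.py
```

builds a 12-participant synthetic cohort and prints:

```
 I (s)       k      R^2  Pearson r
    12   0.928   0.9949      0.897
    20   0.990   0.9975      0.914
    28   0.999   0.9991      0.971
    40   1.004   0.9997      0.988
    70   0.999   0.9998      0.995
optimal duration: I = 14 s (smallest window with R^2 > 0.99 and k > 0.95)
Bland-Altman SampEn1028 vs SampEn50: bias -0.0000, limits of agreement [-0.0075, +0.0074]
```

The slope k and R² of the through-origin fit climb towards 1 as the window
grows: a short window already predicts the full-test entropy almost
perfectly, and the Bland–Altman bias of the 28 s window is a tiny fraction
of a typical SampEn50 (~0.13 nats on this cohort). Other examples:
`simulate_and_segment.py` (generation + automatic trimming),
`sample_entropy_basics.py` (per-channel SampEn with match counts),
`amplitude_and_variability.py` (amplitude and SDX condition contrast).

## Command line

Each analysis stage is also a subcommand of the `bendr` CLI:

```bash
bendr simulate --participants 23 --seed 1 --out cohort/
bendr trim cohort/P00_stool.csv --out trimmed.csv
bendr sampen cohort/P00_stool.csv --channel gyr_x
bendr amplitude cohort/P00_stool.csv
bendr convergence cohort/ --channel gyr_x --out table.csv
bendr agree cohort/ --channel gyr_x --condition stool --out agree.json
bendr run cohort/ --out report.json
```

Recordings are plain CSV (`time,acc_x,...,gyr_z`) with a `# key: value`
metadata header; a `column_map` option accommodates other column
conventions. Analysis parameters live in a flat YAML config (`--config`);
flags override it.

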