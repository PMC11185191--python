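# arcwalk

Walking-behavior analysis for aged-residential-care (ARC) accelerometry.

Residents of aged care walk in short, fragmented bouts, at low volumes that
standard activity-monitor pipelines under-detect. `arcwalk` implements a
full chain from a raw lower-back tri-axial accelerometer recording (100 Hz,
±8 g, long-format text) to cohort statistics:

1. **signal ingestion** — read/validate, resample, rotate to a
   horizontal–vertical frame (upright static vertical = −1 g), flag non-wear;
2. **bout detection** — 17 Hz 2nd-order zero-phase Butterworth filter, then
   upright-posture and movement thresholds; candidate runs become walking
   bouts under the ≥ 3-step minimum and the 2.5 s rest rule;
3. **step detection** — 20 Hz 4th-order Butterworth, then a
   Gaussian-derivative continuous wavelet transform of the integrated
   vertical acceleration; minima mark initial contacts, maxima of the
   re-differentiated transform mark final contacts;
4. **macro-outcomes** per participant over valid wear days — volume
   (walk min/day, steps/day, bouts/day), pattern (mean bout duration and
   the power-law exponent α̂ = 1 + N [Σᵢ ln(xᵢ/x_min)]⁻¹ of bout durations,
   scaled to the participant's shortest bout), variability
   (S² = maximum-likelihood SD of ln duration), and the % of bouts in
   < 10 s / 10–30 s / 30–60 s / > 60 s bins;
5. **cohort statistics** — groups by care level, cognition (MoCA 26/18/10
   cutoffs) or physical function (SPPB 7); ANCOVA controlling age and sex,
   Tukey HSD post hoc, Hedges g = J·(m₁−m₂)/s_p with J = 1 − 3/(4df−1),
   and a 1.5×IQR outlier sensitivity rerun.

A synthetic-data module generates labeled recordings (truncated power-law
bout schedules, per-step acceleration impulses, exact ground truth) and
cohort outcome tables, so every stage is testable without any real data.

## Worked example

Simulate one labeled day of rest-home-level walking, then run the
detection chain on it (by default `simulate` renders the ~14 h active
window, so the config below relaxes the 20 h valid-day wear rule
accordingly):

```bash
arcwalk simulate --profile rest_home --days 1 --seed 3 --out raw/
arcwalk init-config --out arcwalk.yaml
sed -i 's/valid_day_wear_h: 20.0/valid_day_wear_h: 12.0/; s/min_valid_days: 2/min_valid_days: 1/' arcwalk.yaml
arcwalk process --config arcwalk.yaml --input raw/ --out derived/
```

`simulate` prints the ground truth it generated:

```
sim000: 309 bouts, 4846 steps
```

`process` writes `derived/sim000_bouts.tsv` (one detected bout per row:
start/end/duration/steps), a non-wear BED file, a `manifest.json` of
input/config hashes so reruns are verifiably byte-identical, and the
participant-level `macro_outcomes.tsv`:

```
id      walk_time_per_day_min  steps_per_day  bouts_per_day  mean_bout_duration_s  alpha  variability_s2  pct_bouts_lt10 ...
sim000  67.5                   4846           309            13.1                  2.03   0.82            60.5
```

Detection recovered exactly the 309 simulated bouts and all 4846 steps;
60.5 % of bouts were shorter than 10 s, and walking filled 67.5 min of the
day. (The per-participant alpha here uses the conventional closed-form
estimator relative to the shortest detected bout, which reads high on
capped synthetic durations — see `docs/methods.md`.)

In Python, the same library surface:

```python
from arcwalk import PROFILES, hedges_g
from arcwalk.synthetic import simulate_schedule
from arcwalk.macro_metrics import fit_powerlaw_alpha
import numpy as np

truth = simulate_schedule(PROFILES["dementia"], days=7, seed=7)
print(round(float(np.mean(truth.per_day_walk_min)), 1))  # 136.9 min/day
print(round(hedges_g(1.68, 0.08, 117, 1.61, 0.09, 25), 2))  # 0.85
```

The first number is the simulated dementia-care walking volume (the
profile is calibrated to the published 137 min/day group mean); the second
is the effect size separating hospital-level and dementia-care alpha
scores, a large effect (≥ 0.8).

Group comparisons run on any participant table with `id,age,sex` metadata:

```bash
arcwalk compare --outcomes derived/macro_outcomes.tsv \
    --metadata meta.csv --group care_level --adjust age,sex --sensitivity
```

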