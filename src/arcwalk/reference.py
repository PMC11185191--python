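"""Published cohort summary statistics for walking behaviors in aged residential care.

These are group-level means and standard deviations of accelerometry-derived
walking outcomes for a 306-resident aged-residential-care cohort observed over
7 days, split by care level (hospital-level care, rest-home-level care,
dementia-unit care).  They serve two purposes in this package:

* calibration targets for the synthetic-data generator (the simulator's
  default gait profiles are tuned so that a simulated cohort reproduces these
  group moments approximately), and
* inputs for effect-size recomputation: standardized mean differences
  (Hedges g) between care levels are recomputable from these summaries alone.

Units: walk time in min/day, steps and bouts in counts/day, mean bout
duration in seconds, variability (S2) is the log-scale SD of bout duration
(dimensionless), alpha is the power-law exponent of the bout-duration
distribution (dimensionless), bin percentages in % of bouts.
"""

from __future__ import annotations

#: Number of residents per care level.
CARE_LEVEL_N: dict[str, int] = {
    "hospital": 117,
    "rest_home": 164,
    "dementia": 25,
}

#: (mean, sd) per outcome per care level.
CARE_LEVEL_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "hospital": {
        "walk_time_per_day_min": (58.0, 37.0),
        "steps_per_day": (4138.0, 2766.0),
        "bouts_per_day": (256.0, 165.0),
        "mean_bout_duration_s": (13.9, 3.6),
        "variability_s2": (0.81, 0.11),
        "alpha": (1.68, 0.08),
        "pct_bouts_lt10": (65.0, 8.0),
        "pct_bouts_10_30": (25.9, 5.5),
        "pct_bouts_30_60": (5.81, 3.05),
        "pct_bouts_gt60": (3.20, 2.13),
    },
    "rest_home": {
        "walk_time_per_day_min": (74.0, 39.0),
        "steps_per_day": (5216.0, 2925.0),
        "bouts_per_day": (321.0, 160.0),
        "mean_bout_duration_s": (14.1, 3.3),
        "variability_s2": (0.80, 0.09),
        "alpha": (1.67, 0.07),
        "pct_bouts_lt10": (64.0, 8.0),
        "pct_bouts_10_30": (27.6, 5.5),
        "pct_bouts_30_60": (5.51, 2.42),
        "pct_bouts_gt60": (3.15, 2.06),
    },
    "dementia": {
        "walk_time_per_day_min": (137.0, 59.0),
        "steps_per_day": (10886.0, 5453.0),
        "bouts_per_day": (496.0, 238.0),
        "mean_bout_duration_s": (20.1, 20.4),
        "variability_s2": (0.89, 0.18),
        "alpha": (1.61, 0.09),
        "pct_bouts_lt10": (56.0, 10.0),
        "pct_bouts_10_30": (30.8, 5.8),
        "pct_bouts_30_60": (8.64, 3.64),
        "pct_bouts_gt60": (4.82, 4.92),
    },
}

#: Outcome keys in canonical report order.
OUTCOME_ORDER: tuple[str, ...] = (
    "walk_time_per_day_min",
    "steps_per_day",
    "bouts_per_day",
    "mean_bout_duration_s",
    "variability_s2",
    "alpha",
    "pct_bouts_lt10",
    "pct_bouts_10_30",
    "pct_bouts_30_60",
    "pct_bouts_gt60",
)
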