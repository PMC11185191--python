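"""Per-participant macro-outcomes: volume, pattern, and variability of walking.

Detected bouts are aggregated over valid wear days into the standard
macro-gait outcome framework:

* **volume** — walking minutes, steps, and bouts per day;
* **pattern** — mean bout duration and *alpha*, the maximum-likelihood
  power-law exponent of the bout-duration distribution scaled to the
  participant's shortest bout (higher alpha = walking time composed of
  proportionally shorter bouts);
* **variability** — S2, the maximum-likelihood (1/N) standard deviation of
  log bout duration under a lognormal model;
* the percentage of bouts in very short (<10 s), short (10-30 s), medium
  (30-60 s) and prolonged (>60 s) duration bins.

Participants contribute only days with sufficient wear and are excluded
entirely below 2 valid days, the minimum for reliable volume outcomes in
this population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bout_detection import WalkingBout

DAY_S = 86400.0


@dataclass
class MacroOutcomes:
    """One participant's walking-behavior summary (one table row)."""

    walk_time_per_day_min: float
    steps_per_day: float
    bouts_per_day: float
    mean_bout_duration_s: float
    alpha: float  # NaN when undefined (all bouts identical)
    variability_s2: float
    pct_bouts_lt10: float
    pct_bouts_10_30: float
    pct_bouts_30_60: float
    pct_bouts_gt60: float
    n_valid_days: int

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


@dataclass
class BoutSet:
    """All retained bouts for one participant, with per-day wear accounting."""

    participant: str
    bouts: list[WalkingBout]
    wear_hours_per_day: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bouts = sorted(self.bouts, key=lambda b: b.start_s)

    def day_of(self, bout: WalkingBout) -> int:
        return int(bout.start_s // DAY_S)

    def valid_days(self, min_wear_h: float = 20.0) -> list[int]:
        return sorted(d for d, h in self.wear_hours_per_day.items() if h >= min_wear_h)

    def durations(self) -> np.ndarray:
        return np.array([b.duration_s for b in self.bouts], dtype=float)


class ExclusionError(ValueError):
    """Participant does not meet the data-inclusion rules."""


def filter_valid_participants(
    bsets: list[BoutSet], min_days: int = 2, min_wear_h: float = 20.0
) -> tuple[list[BoutSet], list[tuple[str, str]]]:
    """Split participants into retained and excluded (with reasons).

    A participant is retained with at least ``min_days`` valid wear days
    (inclusive: exactly ``min_days`` is retained).  Bouts outside valid days
    are dropped from the retained sets.
    """
    kept: list[BoutSet] = []
    excluded: list[tuple[str, str]] = []
    for bs in bsets:
        days = bs.valid_days(min_wear_h)
        if len(days) < min_days:
            excluded.append((bs.participant, f"insufficient days ({len(days)} < {min_days})"))
            continue
        dayset = set(days)
        kept.append(
            BoutSet(
                bs.participant,
                [b for b in bs.bouts if bs.day_of(b) in dayset],
                {d: bs.wear_hours_per_day[d] for d in days},
            )
        )
    return kept, excluded


def volume_outcomes(
    bset: BoutSet, min_wear_h: float = 20.0
) -> tuple[float, float, float]:
    """(walk minutes/day, steps/day, bouts/day), averaged over valid days."""
    days = bset.valid_days(min_wear_h)
    if not days:
        raise ExclusionError(f"{bset.participant}: no valid days")
    nd = len(days)
    dayset = set(days)
    bouts = [b for b in bset.bouts if bset.day_of(b) in dayset]
    walk_min = sum(b.duration_s for b in bouts) / 60.0 / nd
    steps = sum(b.n_steps for b in bouts) / nd
    return walk_min, steps, len(bouts) / nd


def fit_powerlaw_alpha(
    durations: np.ndarray,
    x_min: float | None = None,
    x_max: float | None = None,
    method: str = "mle",
) -> float:
    """Power-law exponent of bout durations, scaled to the shortest bout.

    ``method="mle"`` (default) is the continuous maximum-likelihood
    estimator.  With no ``x_max`` it is the closed form

        alpha = 1 + N / sum(ln(x_i / x_min)),

    with ``x_min`` the participant's shortest bout.  Passing ``x_max``
    switches to the truncated-support MLE (the likelihood equation is solved
    numerically), appropriate when durations are known to be capped — e.g.
    when validating against the truncated sampler in
    :mod:`arcwalk.synthetic`; the untruncated form is biased upward on
    strongly truncated samples.

    ``method="loglog"`` fits a least-squares line to the log-log survival
    function (sensitivity analysis only).

    Returns NaN when the exponent is undefined (all durations equal).
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 bout durations")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    xm = float(np.min(x)) if x_min is None else float(x_min)
    logs = np.log(x / xm)
    s = float(np.sum(logs))
    if s <= 0:
        return float("nan")

    if method == "loglog":
        xs = np.sort(x)
        surv = 1.0 - np.arange(xs.size) / xs.size  # P(X >= x)
        slope = np.polyfit(np.log(xs), np.log(surv), 1)[0]
        return float(1.0 - slope)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    n = x.size
    if x_max is None:
        return float(1.0 + n / s)

    L = math.log(float(x_max) / xm)
    mean_log = s / n

    def score(alpha: float) -> float:
        a = alpha - 1.0
        # d/dalpha of mean log-likelihood for truncated power law
        return 1.0 / a - L / math.expm1(a * L) - mean_log

    lo, hi = 1.0 + 1e-9, 50.0
    if score(lo) < 0:  # mean log beyond untruncated maximum: alpha -> 1
        return float(lo)
    if score(hi) > 0:
        return float(hi)
    return float(brentq(score, lo, hi, xtol=1e-10))


def pattern_outcomes(bset: BoutSet | np.ndarray) -> tuple[float, float]:
    """(mean bout duration in s, alpha).  Alpha is NaN for identical bouts."""
    x = bset.durations() if isinstance(bset, BoutSet) else np.asarray(bset, float)
    if x.size < 2:
        raise ExclusionError("need at least 2 bouts for pattern outcomes")
    return float(np.mean(x)), fit_powerlaw_alpha(x)


def variability_outcome(bset: BoutSet | np.ndarray) -> float:
    """S2: maximum-likelihood SD of log bout duration (1/N normalization)."""
    x = bset.durations() if isinstance(bset, BoutSet) else np.asarray(bset, float)
    if x.size < 2:
        raise ExclusionError("need at least 2 bouts for variability")
    logs = np.log(x)
    return float(np.sqrt(np.mean((logs - logs.mean()) ** 2)))


def bout_bin_distribution(
    bset: BoutSet | np.ndarray,
    bins_s: tuple[float, float, float] = (10.0, 30.0, 60.0),
) -> tuple[float, float, float, float]:
    """Percentage of bouts per duration bin.

    Convention: <10 s is [0, 10); 10-30 s is [10, 30); 30-60 s is [30, 60]
    (upper edge closed); >60 s is strictly greater than 60.
    """
    x = bset.durations() if isinstance(bset, BoutSet) else np.asarray(bset, float)
    if x.size == 0:
        raise ExclusionError("need at least 1 bout")
    b1, b2, b3 = bins_s
    n = x.size
    p1 = np.count_nonzero(x < b1) / n
    p2 = np.count_nonzero((x >= b1) & (x < b2)) / n
    p3 = np.count_nonzero((x >= b2) & (x <= b3)) / n
    p4 = np.count_nonzero(x > b3) / n
    return tuple(100.0 * p for p in (p1, p2, p3, p4))  # type: ignore[return-value]


def summarize_participant(
    bset: BoutSet,
    min_wear_h: float = 20.0,
    bins_s: tuple[float, float, float] = (10.0, 30.0, 60.0),
) -> MacroOutcomes:
    """Full macro-outcome row for one participant."""
    walk_min, steps, bouts_pd = volume_outcomes(bset, min_wear_h)
    mean_dur, alpha = pattern_outcomes(bset)
    s2 = variability_outcome(bset)
    p1, p2, p3, p4 = bout_bin_distribution(bset, bins_s)
    return MacroOutcomes(
        walk_time_per_day_min=walk_min,
        steps_per_day=steps,
        bouts_per_day=bouts_pd,
        mean_bout_duration_s=mean_dur,
        alpha=alpha,
        variability_s2=s2,
        pct_bouts_lt10=p1,
        pct_bouts_10_30=p2,
        pct_bouts_30_60=p3,
        pct_bouts_gt60=p4,
        n_valid_days=len(bset.valid_days(min_wear_h)),
    )


def participant_table(
    bsets: list[BoutSet],
    min_days: int = 2,
    min_wear_h: float = 20.0,
    bins_s: tuple[float, float, float] = (10.0, 30.0, 60.0),
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply inclusion rules and summarize every retained participant."""
    kept, excluded = filter_valid_participants(bsets, min_days, min_wear_h)
    rows = []
    for bs in kept:
        try:
            row = {"id": bs.participant, **summarize_participant(bs, min_wear_h, bins_s).as_dict()}
        except ExclusionError as exc:
            excluded.append((bs.participant, str(exc)))
            continue
        rows.append(row)
    return pd.DataFrame(rows), excluded
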