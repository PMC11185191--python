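"""Group comparisons of walking outcomes: ANCOVA, Tukey HSD, Hedges g.

Participants are grouped by care level, cognitive status (MoCA cutoffs
26/18/10 for intact / mild / moderate / severe impairment; intact
participants are excluded from comparisons because of small numbers), or
physical function (SPPB >= 7 high-moderate vs < 7 low-very low).  For each
outcome a linear model ``outcome ~ group + age + sex`` is fitted; the group
factor is tested with a partial F test, pairwise differences of adjusted
(least-squares) means with Tukey-Kramer HSD via the studentized-range
distribution, and effect sizes with Hedges g from raw group summaries.  A
sensitivity analysis repeats everything after removing outcome values
outside the 1.5 x IQR fences of the pooled sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .macro_metrics import MacroOutcomes  # noqa: F401  (re-export of row schema)


@dataclass
class ParticipantRecord:
    """Metadata plus derived group labels for one participant."""

    id: str
    age: float
    sex: str  # "female" | "male"
    care_level: str  # "hospital" | "rest_home" | "dementia"
    moca: float | None = None
    sppb: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.id}: sex must be 'female' or 'male'")
        if self.moca is not None and not 0 <= self.moca <= 30:
            raise ValueError(f"{self.id}: MoCA must be in [0, 30]")
        if self.sppb is not None and not 0 <= self.sppb <= 12:
            raise ValueError(f"{self.id}: SPPB must be in [0, 12]")

    @property
    def cognition(self) -> str:
        return categorize_cognition(self.moca)

    @property
    def physical(self) -> str:
        return categorize_physical(self.sppb)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    diff_adjusted: float
    tukey_p: float
    hedges_g: float


@dataclass
class GroupComparisonResult:
    outcome: str
    factor: str
    groups: list[str]
    n_per_group: dict[str, int]
    adjusted_means: dict[str, float]
    f_statistic: float
    p_value: float
    pairwise: list[PairwiseResult]
    residual_normality_p: float
    outliers_removed: int = 0
    dropped_missing_covariates: int = 0

    def pair(self, a: str, b: str) -> PairwiseResult:
        for pw in self.pairwise:
            if set(pw.pair) == {a, b}:
                return pw
        raise KeyError((a, b))


def categorize_cognition(moca: float | None) -> str:
    """MoCA -> {intact, mild, moderate, severe, untested}.

    Cutoffs: >=26 intact, 18-25 mild, 10-17 moderate, <10 severe.  Intact
    participants are excluded from severity comparisons downstream.
    """
    if moca is None or (isinstance(moca, float) and math.isnan(moca)):
        return "untested"
    if not 0 <= moca <= 30:
        raise ValueError(f"MoCA {moca} outside [0, 30]")
    if moca >= 26:
        return "intact"
    if moca >= 18:
        return "mild"
    if moca >= 10:
        return "moderate"
    return "severe"


def categorize_physical(sppb: float | None) -> str:
    """SPPB -> {high_moderate, low_very_low, untested}; cutoff 7 inclusive."""
    if sppb is None or (isinstance(sppb, float) and math.isnan(sppb)):
        return "untested"
    if not 0 <= sppb <= 12:
        raise ValueError(f"SPPB {sppb} outside [0, 12]")
    return "high_moderate" if sppb >= 7 else "low_very_low"


def hedges_g(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    correction: str = "df", signed: bool = False,
) -> float:
    """Hedges g: bias-corrected standardized mean difference.

    g = J * (m1 - m2) / s_p with pooled SD
    s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)) and small-sample
    correction J = 1 - 3 / (4 df - 1), df = n1 + n2 - 2 (``correction="n"``
    uses the J = 1 - 3/(4 N - 9) variant).  Returned as |g| unless
    ``signed``; interpretation bands: 0.2-0.4 small, 0.5-0.7 medium,
    >=0.8 large.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    if sp == 0:
        raise ValueError("pooled SD is zero")
    if correction == "df":
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    elif correction == "n":
        j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    g = j * (m1 - m2) / sp
    return g if signed else abs(g)


def _design(groups: pd.Series, covars: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Full-rank design: intercept + group dummies (first level reference) + covariates."""
    levels = sorted(groups.unique())
    cols = [np.ones(len(groups))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((groups == lev).to_numpy(float))
        names.append(f"group[{lev}]")
    if covars is not None:
        for c in covars.columns:
            col = covars[c]
            if col.dtype == object or str(col.dtype) == "category":
                cats = sorted(col.unique())
                for cat in cats[1:]:
                    cols.append((col == cat).to_numpy(float))
                    names.append(f"{c}[{cat}]")
            else:
                cols.append(col.to_numpy(float))
                names.append(c)
    return np.column_stack(cols), names


def ancova_compare(
    table: pd.DataFrame,
    outcome: str,
    factor: str = "group",
    covariates: tuple[str, ...] = ("age", "sex"),
    hedges_correction: str = "df",
    pairwise: bool = True,
    diagnostics: bool = True,
) -> GroupComparisonResult:
    """ANCOVA of ``outcome`` across ``factor`` levels, controlling covariates.

    Rows with a missing outcome, factor level, or covariate are dropped (and
    counted).  The factor is tested with a partial F test against the
    covariate-only model; Tukey-Kramer HSD compares adjusted means for every
    pair; Hedges g is computed from each pair's raw means/SDs.  With
    ``covariates=()`` this reduces exactly to one-way ANOVA.
    """
    cols = [outcome, factor, *covariates]
    data = table[cols].copy()
    n0 = len(data)
    data = data.dropna()
    dropped = n0 - len(data)

    groups = data[factor].astype(str)
    levels = sorted(groups.unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups too small (<3): {small}")

    y = data[outcome].to_numpy(float)
    covars = data[list(covariates)] if covariates else None
    X_full, names = _design(groups, covars)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(f"singular design matrix; columns: {names}")

    full = sm.OLS(y, X_full).fit()
    # covariate-only (reduced) model for the partial F test of the factor
    X_red, _ = _design(pd.Series(["all"] * len(y), index=groups.index), covars)
    red = sm.OLS(y, X_red).fit()
    df_num = k - 1
    df_den = int(full.df_resid)
    f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_val = float(f_dist.sf(f_stat, df_num, df_den))

    # adjusted (least-squares) means: group effects at mean covariate values
    beta = dict(zip(names, full.params))
    base = beta["intercept"]
    if covars is not None:
        for c in covars.columns:
            col = covars[c]
            if col.dtype == object or str(col.dtype) == "category":
                cats = sorted(col.unique())
                for cat in cats[1:]:
                    base += beta[f"{c}[{cat}]"] * float((col == cat).mean())
            else:
                base += beta[c] * float(col.mean())
    adj = {levels[0]: base}
    for lev in levels[1:]:
        adj[lev] = base + beta[f"group[{lev}]"]

    mse = full.ssr / df_den
    raw = {
        lev: (
            float(y[groups == lev].mean()),
            float(y[groups == lev].std(ddof=1)),
            int((groups == lev).sum()),
        )
        for lev in levels
    }
    pairs: list[PairwiseResult] = []
    if pairwise:
        for a, b in itertools.combinations(levels, 2):
            na, nb = raw[a][2], raw[b][2]
            diff = adj[a] - adj[b]
            se = math.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(diff) / se if se > 0 else math.inf
            tp = float(studentized_range.sf(q, k, df_den))
            g = hedges_g(*raw[a][:2], na, *raw[b][:2], nb, correction=hedges_correction)
            pairs.append(PairwiseResult((a, b), diff, tp, g))

    norm_p = float("nan")
    if diagnostics:
        from scipy.stats import shapiro

        resid = full.resid
        if len(resid) >= 3:
            norm_p = float(shapiro(resid[:5000]).pvalue)

    return GroupComparisonResult(
        outcome=outcome,
        factor=factor,
        groups=levels,
        n_per_group={lev: raw[lev][2] for lev in levels},
        adjusted_means=adj,
        f_statistic=float(f_stat),
        p_value=p_val,
        pairwise=pairs,
        residual_normality_p=norm_p,
        dropped_missing_covariates=dropped,
    )


def iqr_fences(values: np.ndarray, factor: float = 1.5) -> tuple[float, float]:
    """Tukey fences (Q1 - f*IQR, Q3 + f*IQR) with type-7 linear-interpolation quartiles."""
    q1, q3 = np.percentile(np.asarray(values, float), [25, 75])
    iqr = q3 - q1
    return float(q1 - factor * iqr), float(q3 + factor * iqr)


def outlier_sensitivity(
    table: pd.DataFrame,
    outcome: str,
    factor: str = "group",
    covariates: tuple[str, ...] = ("age", "sex"),
    iqr_factor: float = 1.5,
    hedges_correction: str = "df",
) -> GroupComparisonResult:
    """Rerun the ANCOVA after removing pooled-sample IQR outliers of the outcome."""
    data = table.dropna(subset=[outcome, factor, *covariates])
    lo, hi = iqr_fences(data[outcome].to_numpy(float), iqr_factor)
    keep = data[(data[outcome] >= lo) & (data[outcome] <= hi)]
    removed = len(data) - len(keep)
    if keep.empty:
        raise ValueError("all rows removed as outliers")
    res = ancova_compare(keep, outcome, factor, covariates, hedges_correction)
    res.outliers_removed = removed
    return res


def compare_all_outcomes(
    table: pd.DataFrame,
    outcomes: list[str],
    factor: str = "group",
    covariates: tuple[str, ...] = ("age", "sex"),
    sensitivity: bool = False,
) -> pd.DataFrame:
    """Tidy results table (outcome, factor, pair, estimate, tukey_p, hedges_g, overall F/p)."""
    rows = []
    for oc in outcomes:
        fn = outlier_sensitivity if sensitivity else ancova_compare
        res = fn(table, oc, factor, covariates)
        for pw in res.pairwise:
            rows.append(
                {
                    "outcome": oc,
                    "factor": factor,
                    "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                    "estimate": pw.diff_adjusted,
                    "tukey_p": pw.tukey_p,
                    "hedges_g": pw.hedges_g,
                    "overall_F": res.f_statistic,
                    "overall_p": res.p_value,
                    "outliers_removed": res.outliers_removed,
                }
            )
    return pd.DataFrame(rows)
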