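"""Statistical comparisons: two-way ANOVA with Tukey HSD, Šídák-adjusted
pairs, Student's t-test, and significance star coding.

The fold-induction tables are analysed with a fixed-effects two-way ANOVA
(fold ~ population + timepoint + population:timepoint, per-donor folds as
replicates) followed by Tukey HSD pairwise comparisons between populations
within each time point, using the ANOVA residual mean square as the pooled
error and studentized-range p values.  Side-by-side paired comparisons use
the Šídák adjustment 1-(1-p)^m.  Star coding is inclusive: *p<=0.05,
**p<=0.01, ***p<=0.001, ****p<=0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars for a p value; thresholds are inclusive."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p value {p} outside [0, 1]")
    for cut, stars in STAR_LEVELS:
        if p <= cut:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    comparison: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    stars: str
    timepoint_h: float | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_adjusted) and np.isfinite(self.p_raw):
            if self.p_adjusted < self.p_raw - 1e-12:
                raise ValidationError("adjusted p must be >= raw p")


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def sidak_pairs(p_raw) -> np.ndarray:
    """Šídák adjustment for m independent comparisons: 1 - (1-p)^m, capped at 1."""
    p = np.asarray(p_raw, dtype=np.float64)
    if p.size < 1:
        raise ValidationError("need at least one p value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def students_t(a, b, paired: bool = False) -> ComparisonResult:
    """Two-sided Student's t-test (pooled variance; no Welch correction).

    Degenerate zero-variance samples with equal means return statistic 0 and
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need n >= 2 per sample")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired test needs equal sample sizes")
        d = a - b
        df = a.size - 1
        sd = np.std(d, ddof=1)
        if sd == 0:
            stat, p = (0.0, 1.0) if np.mean(d) == 0 else (np.inf * np.sign(np.mean(d)), 0.0)
        else:
            stat = float(np.mean(d) / (sd / np.sqrt(a.size)))
            p = float(2 * sps.t.sf(abs(stat), df))
    else:
        df = a.size + b.size - 2
        sp2 = (np.var(a, ddof=1) * (a.size - 1) + np.var(b, ddof=1) * (b.size - 1)) / df
        if sp2 == 0:
            if np.mean(a) == np.mean(b):
                stat, p = 0.0, 1.0
            else:
                stat, p = np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
        else:
            stat = float((np.mean(a) - np.mean(b))
                         / np.sqrt(sp2 * (1 / a.size + 1 / b.size)))
            p = float(2 * sps.t.sf(abs(stat), df))
    return ComparisonResult(
        comparison="a vs b" + (" (paired)" if paired else ""),
        statistic=stat, df=float(df), p_raw=p, p_adjusted=p, stars=star_code(p))


def _anova_residual(df: pd.DataFrame, value: str, a: str, b: str) -> tuple[float, float]:
    """(MSE, residual df) of the fixed-effects two-way model.

    Factors with a single observed level are dropped from the model; if the
    residual df collapses to zero (one replicate per cell) the additive
    model without interaction is used instead.
    """
    data = df[[value, a, b]].dropna().copy()
    data.columns = ["y", "fa", "fb"]
    terms = []
    if data["fa"].nunique() > 1:
        terms.append("C(fa)")
    if data["fb"].nunique() > 1:
        terms.append("C(fb)")
    if len(terms) == 2:
        formulas = ["y ~ C(fa) * C(fb)", "y ~ C(fa) + C(fb)"]
    elif terms:
        formulas = [f"y ~ {terms[0]}"]
    else:
        formulas = ["y ~ 1"]
    for f in formulas:
        fit = smf.ols(f, data=data).fit()
        if fit.df_resid > 0:
            return float(fit.mse_resid), float(fit.df_resid)
    raise ValidationError("no residual degrees of freedom for the ANOVA error term")


def anova_table(df: pd.DataFrame, value: str = "fold_induction",
                factor_a: str = "population", factor_b: str = "timepoint_h") -> pd.DataFrame:
    """Type-II two-way ANOVA table (for reporting)."""
    data = df[[value, factor_a, factor_b]].dropna().copy()
    data.columns = ["y", "fa", "fb"]
    formula = "y ~ C(fa) * C(fb)" if data["fb"].nunique() > 1 else "y ~ C(fa)"
    fit = smf.ols(formula, data=data).fit()
    return sm.stats.anova_lm(fit, typ=2)


def two_way_anova_tukey(
    df: pd.DataFrame,
    value: str = "fold_induction",
    factor_a: str = "population",
    factor_b: str = "timepoint_h",
    within_timepoint: bool = True,
) -> list[ComparisonResult]:
    """Tukey HSD pairwise comparisons between populations.

    The error term is the residual mean square of the two-way fixed-effects
    ANOVA across all cells.  By default comparisons are made between
    populations within each time point (the way significance is displayed
    per time point in kinetics bar charts); ``within_timepoint=False``
    compares pooled population means.  Empty or single-replicate cells are
    skipped with a flag.
    """
    data = df[[value, factor_a, factor_b]].dropna()
    if data.empty:
        raise ValidationError("no finite values to compare")
    mse, dfe = _anova_residual(data, value, factor_a, factor_b)
    groups = sorted(data[factor_a].unique())
    k = len(groups)
    if k < 2:
        raise ValidationError("need >= 2 populations for pairwise comparisons")
    results: list[ComparisonResult] = []
    blocks = (
        [(t, sub) for t, sub in data.groupby(factor_b)] if within_timepoint
        else [(None, data)]
    )
    for t, sub in blocks:
        stats = sub.groupby(factor_a)[value].agg(["mean", "count"])
        for g1, g2 in itertools.combinations(groups, 2):
            label = f"{g1} vs {g2}"
            if g1 not in stats.index or g2 not in stats.index:
                results.append(ComparisonResult(label, np.nan, dfe, np.nan, np.nan,
                                                "ns", timepoint_h=t, flag="empty cell"))
                continue
            m1, n1 = stats.loc[g1, "mean"], int(stats.loc[g1, "count"])
            m2, n2 = stats.loc[g2, "mean"], int(stats.loc[g2, "count"])
            if min(n1, n2) < 1:
                results.append(ComparisonResult(label, np.nan, dfe, np.nan, np.nan,
                                                "ns", timepoint_h=t, flag="empty cell"))
                continue
            se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
            if se == 0:
                q = 0.0 if m1 == m2 else np.inf
            else:
                q = float(abs(m1 - m2) / se)
            p = float(sps.studentized_range.sf(q, k, dfe)) if np.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            results.append(ComparisonResult(
                comparison=label, statistic=q, df=dfe, p_raw=p, p_adjusted=p,
                stars=star_code(p), timepoint_h=t))
    return results
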