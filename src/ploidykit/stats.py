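"""Reporting statistics: t-test / ANOVA with Bonferroni post-hoc summaries,
population-doubling time and the relative-quantification (delta-delta-Ct)
fold change.

Group results follow the mean ± SEM convention with significance stars
* p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bonferroni(p: float, m: int) -> float:
    """Family-wise adjusted p = min(1, m * p)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p)


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    test: str
    p: float
    p_adjusted: float
    stars: str


def _summaries(groups: dict[str, np.ndarray], test: str, pairwise: dict) -> list[GroupSummary]:
    m = max(len(pairwise), 1)
    out = []
    for name, vals in groups.items():
        ps = [p for pair, p in pairwise.items() if name in pair] or [1.0]
        p = min(ps)
        p_adj = bonferroni(p, m)
        out.append(
            GroupSummary(
                group=name,
                n=len(vals),
                mean=float(np.mean(vals)),
                sem=float(sps.sem(vals)) if len(vals) > 1 else 0.0,
                test=test,
                p=float(p),
                p_adjusted=float(p_adj),
                stars=significance_stars(p_adj),
            )
        )
    return out


def _clean_groups(groups: dict) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def ttest(groups: dict, equal_var: bool = True) -> tuple[float, float, list[GroupSummary]]:
    """Unpaired two-tailed t-test between exactly two groups.

    Returns (t, p, per-group summaries).  Zero variance everywhere yields
    p = 1 with a warning rather than NaN.
    """
    g = _clean_groups(groups)
    if len(g) != 2:
        raise ValueError("t-test requires exactly two groups")
    (na, a), (nb, b) = g.items()
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("zero variance in both groups; p reported as 1")
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        if np.isnan(p):
            warnings.warn("degenerate t-test; p reported as 1")
            t, p = 0.0, 1.0
    summaries = _summaries(g, "t-test", {(na, nb): p})
    return float(t), float(p), summaries


def anova_oneway(groups: dict) -> tuple[float, float, list[GroupSummary]]:
    """One-way ANOVA with Bonferroni-corrected pairwise post-hoc t-tests."""
    g = _clean_groups(groups)
    arrays = list(g.values())
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        warnings.warn("zero variance everywhere; p reported as 1")
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
        if np.isnan(p):
            warnings.warn("degenerate ANOVA; p reported as 1")
            f, p = 0.0, 1.0
    pairwise = {}
    for (na, a), (nb, b) in itertools.combinations(g.items(), 2):
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            pairwise[(na, nb)] = 1.0
        else:
            pairwise[(na, nb)] = float(sps.ttest_ind(a, b).pvalue)
    summaries = _summaries(g, "one-way ANOVA", pairwise)
    return float(f), float(p), summaries


def anova_twoway(table: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction via an OLS fit.

    ``table`` is long-format with a value column and two categorical factor
    columns; returns the classical ANOVA table (sum of squares, F, p per
    effect).
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    counts = table.groupby([factor_a, factor_b], observed=True)[value].count()
    if (counts < 2).any():
        raise ValueError("each factor-level cell needs at least 2 observations")
    model = ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=table
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


def doubling_time(n1: float, n2: float, elapsed_hours: float) -> tuple[float, bool]:
    """Population-doubling time DT = t * ln 2 / ln(n2 / n1), in hours.

    Returns (DT, declined); a shrinking population yields a negative DT
    with ``declined=True``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell counts must be positive")
    if n2 == n1:
        raise ValueError("no net growth: doubling time undefined")
    if elapsed_hours <= 0:
        raise ValueError("elapsed time must be positive")
    dt = elapsed_hours * np.log(2.0) / np.log(n2 / n1)
    return float(dt), bool(dt < 0)


def doubling_time_regression(times_hours, counts) -> float:
    """Doubling time from a log-linear fit of a growth series (robust to
    per-timepoint noise): DT = ln 2 / slope of ln(count) vs time."""
    t = np.asarray(times_hours, dtype=float)
    c = np.asarray(counts, dtype=float)
    if np.any(c <= 0):
        raise ValueError("cell counts must be positive")
    slope = np.polyfit(t, np.log(c), 1)[0]
    if slope == 0:
        raise ValueError("flat series: doubling time undefined")
    return float(np.log(2.0) / slope)


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the delta-delta-Ct method:
    2 ** -((Ct_tgt,trt - Ct_ref,trt) - (Ct_tgt,ctl - Ct_ref,ctl))."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if v is None or np.isnan(v):
            raise ValueError("all four Ct values are required")
    ddct_val = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct_val))


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
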