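"""Statistical comparisons used by the experiment report.

Thin, guarded wrappers around scipy.stats returning a uniform
:class:`StatResult` (statistic, two-tailed p, degrees of freedom):
pooled-variance independent t-test (a Welch switch is provided), one-way
ANOVA, and Pearson correlation with the t-transform p-value. Degenerate
inputs follow explicit conventions instead of propagating NaN: identical
zero-variance samples give t = 0 / F = 0 with p = 1 (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "t_test_independent", "anova_oneway", "pearson_correlation"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: float | tuple[float, float]
    kind: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def t_test_independent(sample_a, sample_b, equal_var: bool = True) -> StatResult:
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            log.info("degenerate t-test: equal constant samples, p = 1 by convention")
            return StatResult(0.0, 1.0, float(len(a) + len(b) - 2), "t-test")
        raise ValueError("both samples constant with different means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(len(a) + len(b) - 2) if equal_var else float(res.df)
    return StatResult(float(res.statistic), float(res.pvalue), df, "t-test")


def anova_oneway(*groups) -> StatResult:
    """One-way ANOVA over two or more groups (upper-tail F p-value)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    df = (float(len(gs) - 1), float(sum(len(g) for g in gs) - len(gs)))
    if all(g.std() == 0 for g in gs) and len({float(g.mean()) for g in gs}) == 1:
        log.info("degenerate ANOVA: identical constant groups, F = 0, p = 1")
        return StatResult(0.0, 1.0, df, "anova")
    res = sps.f_oneway(*gs)
    return StatResult(float(res.statistic), float(res.pvalue), df, "anova")


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with two-tailed p via the t transform on n − 2 df."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need paired samples with n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(xa, ya)
    return StatResult(float(res.statistic), float(res.pvalue), float(len(xa) - 2), "pearson")
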