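"""GxL-adjusted inference for single-lab comparisons.

A conventional two-sample t-test in one laboratory compares two genotype
means against the within-group noise only.  Under the Random Lab Model the
comparison also carries two independent genotype-by-lab interaction terms,
so its true sampling variance is

    Var(xbar - ybar) = sigma^2/n1 + sigma^2/n2 + 2*sigma_gxl^2.

The adjustment plugs in the dimensionless factor gamma = sigma_gxl/sigma
estimated from multi-lab data, inflating the single lab's own pooled SD:

    T = (xbar - ybar) / ( s_p * sqrt(1/n1 + 1/n2 + 2*gamma^2) ).

Because gamma itself was estimated from a finite multi-lab design, T is
referred to a Student t distribution with Satterthwaite degrees of freedom
combining the n1+n2-2 error df with the (n_L-1)(n_S-1) interaction df.  For
a difference of treatment effects between two genotypes (four groups), four
independent three-way interaction terms enter and the inflation is
4*gamma_txgxl^2, with the analogous Satterthwaite df.

gamma is treated as a known plug-in constant; with gamma = 0 every result
reduces exactly to the classical pooled t-test.  Adjustment can only widen
the standard error, so a nonsignificant unadjusted result can never become
significant after adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import GroupStats
from .varcomp import GxLFactor

__all__ = [
    "AdjustedTestResult",
    "pooled_sd",
    "satterthwaite_df",
    "satterthwaite_df_contrast",
    "adjusted_t_test",
    "adjusted_treatment_contrast",
]


@dataclass(frozen=True)
class AdjustedTestResult:
    """One comparison: estimate, inflated SE, T, Satterthwaite df, p, CI."""

    estimate: float
    se: float
    t_stat: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    gamma_used: float = 0.0
    adjusted: bool = True


def pooled_sd(*groups: GroupStats) -> float:
    """Pooled within-group SD: sqrt( sum (n_i-1) s_i^2 / sum (n_i-1) )."""
    if len(groups) < 2:
        raise ValueError("need at least two groups to pool")
    for g in groups:
        if g.n < 2:
            raise ValueError("every group must have n >= 2")
    num = sum((g.n - 1) * g.sd**2 for g in groups)
    den = sum(g.n - 1 for g in groups)
    return math.sqrt(num / den)


def satterthwaite_df(n1: int, n2: int, gamma: float, n_labs: int, n_genotypes: int) -> float:
    """Effective df of the adjusted two-group statistic.

    nu = (1/n1 + 1/n2 + 2 g^2)^2
         / [ (1/n1+1/n2)^2/(n1+n2-2) + 4 g^4/((nL-1)(nS-1)) ]

    (the pooled s_p^4 cancels).  With gamma = 0 this is exactly n1+n2-2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    a = 1.0 / n1 + 1.0 / n2
    if gamma == 0.0:
        return float(n1 + n2 - 2)
    if n_labs < 2 or n_genotypes < 2:
        raise ValueError("interaction df undefined: need n_labs >= 2 and n_genotypes >= 2")
    num = (a + 2.0 * gamma**2) ** 2
    den = a**2 / (n1 + n2 - 2) + 4.0 * gamma**4 / ((n_labs - 1) * (n_genotypes - 1))
    return num / den


def satterthwaite_df_contrast(
    n1t: int, n1c: int, n2t: int, n2c: int, gamma: float, n_labs: int, n_genotypes: int
) -> float:
    """Satterthwaite df for the four-group treatment-difference contrast.

    Generalises the two-group formula: the interaction inflation is
    4 gamma^2 (four independent three-way terms), hence 16 gamma^4 in the
    denominator's interaction term, with pooled error df n1T+n1C+n2T+n2C-4.
    """
    ns = (n1t, n1c, n2t, n2c)
    if any(n < 2 for n in ns):
        raise ValueError("group sizes must be >= 2")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    a = sum(1.0 / n for n in ns)
    df_err = sum(ns) - 4
    if gamma == 0.0:
        return float(df_err)
    if n_labs < 2 or n_genotypes < 2:
        raise ValueError("interaction df undefined: need n_labs >= 2 and n_genotypes >= 2")
    num = (a + 4.0 * gamma**2) ** 2
    den = a**2 / df_err + 16.0 * gamma**4 / ((n_labs - 1) * (n_genotypes - 1))
    return num / den


def _finish(
    estimate: float, se: float, df: float, alpha: float, gamma: float, adjusted: bool
) -> AdjustedTestResult:
    t_stat = estimate / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return AdjustedTestResult(
        estimate=float(estimate),
        se=float(se),
        t_stat=float(t_stat),
        df=float(df),
        p_value=float(min(p, 1.0)),
        ci_low=float(estimate - tcrit * se),
        ci_high=float(estimate + tcrit * se),
        alpha=alpha,
        gamma_used=float(gamma),
        adjusted=adjusted,
    )


def adjusted_t_test(
    gx: GroupStats, gy: GroupStats, factor: GxLFactor | float, alpha: float = 0.05
) -> AdjustedTestResult:
    """GxL-adjusted two-sample t-test for a genotype difference in one lab.

    ``factor`` may be a :class:`GxLFactor` of kind ``gxl`` (carrying the
    multi-lab design sizes for the df) or a bare nonnegative float, in which
    case the df formula needs gamma = 0 or an explicit factor.
    """
    if isinstance(factor, GxLFactor):
        if factor.kind != "gxl":
            raise ValueError("adjusted_t_test requires a factor of kind 'gxl'")
        gamma, nL, nS = factor.gamma, factor.n_labs, factor.n_genotypes
    else:
        gamma, nL, nS = float(factor), 2, 2
        if gamma < 0:
            raise ValueError("gamma must be nonnegative")
    if gx.subpopulation != gy.subpopulation:
        raise ValueError(
            f"groups come from different strata: {gx.subpopulation.label()} vs "
            f"{gy.subpopulation.label()}"
        )
    if gx.lab != gy.lab:
        raise ValueError("groups must come from the same lab")
    sp = pooled_sd(gx, gy)
    se = sp * math.sqrt(1.0 / gx.n + 1.0 / gy.n + 2.0 * gamma**2)
    df = satterthwaite_df(gx.n, gy.n, gamma, nL, nS)
    return _finish(gx.mean - gy.mean, se, df, alpha, gamma, adjusted=gamma > 0)


def adjusted_treatment_contrast(
    x_t: GroupStats,
    x_c: GroupStats,
    y_t: GroupStats,
    y_c: GroupStats,
    factor: GxLFactor | float,
    alpha: float = 0.05,
) -> AdjustedTestResult:
    """Adjusted test of (xT - xC) - (yT - yC): treatment effect difference
    between two genotypes in one lab, inflated by the three-way TxGxL factor.
    """
    if isinstance(factor, GxLFactor):
        if factor.kind != "txgxl":
            raise ValueError("treatment contrast requires a factor of kind 'txgxl'")
        gamma, nL, nS = factor.gamma, factor.n_labs, factor.n_genotypes
    else:
        gamma, nL, nS = float(factor), 2, 2
        if gamma < 0:
            raise ValueError("gamma must be nonnegative")
    groups = (x_t, x_c, y_t, y_c)
    labs = {g.lab for g in groups}
    if len(labs) != 1:
        raise ValueError("all four groups must come from the same lab")
    sp = pooled_sd(*groups)
    a = sum(1.0 / g.n for g in groups)
    se = sp * math.sqrt(a + 4.0 * gamma**2)
    df = satterthwaite_df_contrast(x_t.n, x_c.n, y_t.n, y_c.n, gamma, nL, nS)
    estimate = (x_t.mean - x_c.mean) - (y_t.mean - y_c.mean)
    return _finish(estimate, se, df, alpha, gamma, adjusted=gamma > 0)
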