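"""Replicability calls, A-F classification, and type-I replicability error.

A genotype difference is called *replicable* when it is statistically
significant in a multi-lab experiment analysed under the Random Lab Model,
i.e. against a variance that includes the genotype-by-lab interaction.  Each
comparison is then cross-classified by three binary outcomes -- replicable
across labs, significant in the single-lab analysis, significant after
GxL adjustment -- into six categories:

    A  replicable,     single-lab significant, adjusted significant
    B  replicable,     single-lab significant, adjusted ns
    C  replicable,     single-lab ns           (adjusted necessarily ns)
    D  non-replicable, single-lab significant, adjusted significant
    E  non-replicable, single-lab significant, adjusted ns
    F  non-replicable, single-lab ns

The combination (single-lab ns, adjusted significant) is impossible because
adjustment only widens the standard error.  The headline summaries are the
type-I replicability error -- the proportion of non-replicable comparisons
that were single-lab discoveries, (D+E)/(D+E+F) unadjusted and D/(D+E+F)
adjusted -- and the power to make a replicable discovery, (A+B)/(A+B+C)
unadjusted and A/(A+B+C) adjusted, each with an exact (Clopper-Pearson)
binomial confidence interval computed as if the decisions were independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .data_model import MeasurementTable, Subpopulation, Transform, apply_transform
from .varcomp import VarianceComponents, fit_random_lab_model

__all__ = [
    "ComparisonRecord",
    "ReplicabilityTable",
    "Proportion",
    "ReplicabilitySummary",
    "PairCall",
    "replicability_calls",
    "classify",
    "tabulate",
    "summarize",
    "percent",
]

CATEGORIES = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class ComparisonRecord:
    """One comparison's three outcomes feeding the A-F classification."""

    phenotype: str
    subpopulation: str
    pair: str
    single_lab_p: float
    adjusted_p: float
    replicable: bool

    def __post_init__(self) -> None:
        for name in ("single_lab_p", "adjusted_p"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class ReplicabilityTable:
    """Counts of comparisons in categories A-F at one significance level."""

    A: int
    B: int
    C: int
    D: int
    E: int
    F: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if any(getattr(self, c) < 0 for c in CATEGORIES):
            raise ValueError("category counts must be nonnegative")

    @property
    def n_replicable(self) -> int:
        return self.A + self.B + self.C

    @property
    def n_non_replicable(self) -> int:
        return self.D + self.E + self.F

    @property
    def total(self) -> int:
        return self.n_replicable + self.n_non_replicable


@dataclass(frozen=True)
class Proportion:
    """A ratio k/n as a percentage with an exact binomial 95% CI (percent units)."""

    numerator: int
    denominator: int
    pct: float
    ci_low_pct: float
    ci_high_pct: float


@dataclass(frozen=True)
class ReplicabilitySummary:
    """Type-I replicability error and power, before and after adjustment.

    Entries are ``None`` when their denominator is zero.
    """

    typeI_unadjusted: Proportion | None
    typeI_adjusted: Proportion | None
    power_unadjusted: Proportion | None
    power_adjusted: Proportion | None


@dataclass(frozen=True)
class PairCall:
    """Multi-lab Random-Lab-Model test of one genotype pair."""

    pair: tuple[str, str]
    estimate: float
    se: float
    df: float
    p_value: float
    replicable: bool


def classify(record: ComparisonRecord, alpha: float = 0.05) -> str:
    """Map one comparison to its category A-F."""
    single = record.single_lab_p <= alpha
    adj = record.adjusted_p <= alpha
    if adj and not single:
        raise ValueError(
            "impossible record: adjusted significant but single-lab not "
            "(adjustment can only increase the p-value)"
        )
    if record.replicable:
        return "A" if adj else ("B" if single else "C")
    return "D" if adj else ("E" if single else "F")


def tabulate(records: Iterable[ComparisonRecord], alpha: float = 0.05) -> ReplicabilityTable:
    """Count records per category."""
    records = list(records)
    if not records:
        raise ValueError("no records to tabulate")
    counts = dict.fromkeys(CATEGORIES, 0)
    for r in records:
        counts[classify(r, alpha)] += 1
    return ReplicabilityTable(**counts, alpha=alpha)


def _proportion(k: int, n: int) -> Proportion | None:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return Proportion(k, n, 100.0 * k / n, 100.0 * float(lo), 100.0 * float(hi))


def summarize(table: ReplicabilityTable) -> ReplicabilitySummary:
    """Type-I replicability error and power with Clopper-Pearson 95% CIs."""
    nr = table.n_non_replicable
    rep = table.n_replicable
    return ReplicabilitySummary(
        typeI_unadjusted=_proportion(table.D + table.E, nr),
        typeI_adjusted=_proportion(table.D, nr),
        power_unadjusted=_proportion(table.A + table.B, rep),
        power_adjusted=_proportion(table.A, rep),
    )


def percent(value: float, decimals: int = 0) -> float:
    """Display rounding (round-half-up) of a percentage."""
    q = 10.0**decimals
    return math.floor(value * q + 0.5) / q


def replicability_calls(
    table: MeasurementTable,
    phenotype: str,
    subpop: Subpopulation | None = None,
    transform: Transform = Transform(),
    alpha: float = 0.05,
    vc: VarianceComponents | None = None,
    multiplicity: str = "none",
) -> list[PairCall]:
    """Random-Lab-Model tests of every genotype pair in a multi-lab table.

    The genotype difference is the difference of across-lab genotype means,
    tested against

        se^2 = sigma^2 (1/N1 + 1/N2) + 2 sigma_gxl^2 / n_labs

    with REML plug-in components.  For the Satterthwaite df the variance is
    re-expressed as a combination of the *independent* error and interaction
    mean squares (the two component estimates themselves are negatively
    correlated, so pairing them naively overstates the df); on a balanced
    design the error term's weight vanishes and the df reduce to the exact
    classical (n_L-1)(n_S-1).  Genotypes absent from any lab are skipped
    with a warning.  A pre-computed fit may be passed via ``vc`` to avoid
    refitting.

    ``multiplicity="tukey"`` converts each pairwise p-value to a Tukey-style
    studentized-range family p across the genotypes; the default makes
    per-pair calls at ``alpha`` with no multiplicity adjustment.
    """
    if multiplicity not in ("none", "tukey"):
        raise ValueError("multiplicity must be 'none' or 'tukey'")
    if vc is None:
        vc = fit_random_lab_model(table, phenotype, subpop, transform, method="reml")
    df = table.subset(phenotype=phenotype, subpop=subpop).copy()
    df["value"] = apply_transform(df["value"].to_numpy(), transform)
    labs = df["lab"].nunique()
    per_geno_labs = df.groupby("genotype")["lab"].nunique()
    complete = set(per_geno_labs[per_geno_labs == labs].index)
    skipped = sorted(set(df["genotype"].unique()) - complete)
    if skipped:
        warnings.warn(
            f"genotype(s) missing from some lab, pairs skipped: {', '.join(map(str, skipped))}",
            UserWarning,
            stacklevel=2,
        )
    means = df.groupby("genotype")["value"].mean()
    sizes = df.groupby("genotype")["value"].size()
    df_int = (vc.n_labs - 1) * (vc.n_genotypes - 1)
    out: list[PairCall] = []
    n_labs = vc.n_labs
    for g1, g2 in combinations(sorted(complete), 2):
        n1, n2 = int(sizes[g1]), int(sizes[g2])
        se2 = vc.sigma2_within * (1.0 / n1 + 1.0 / n2) + 2.0 * vc.sigma2_gxl / n_labs
        se = math.sqrt(se2)
        # Satterthwaite on independent mean squares: with mean cell size mbar,
        # se2 = w1 * sigma2 + w2 * (sigma2 + mbar*sigma2_gxl); the second factor
        # is the interaction mean square implied by the fit (df_int), the first
        # the pure-error remainder (df_error); w1 = 0 exactly when balanced.
        mbar = (n1 + n2) / (2.0 * n_labs)
        w2 = 2.0 / (mbar * n_labs)
        w1 = max((1.0 / n1 + 1.0 / n2) - w2, 0.0)
        ms_int = vc.sigma2_within + mbar * vc.sigma2_gxl
        if vc.sigma2_gxl > 0 or w1 > 0:
            nu = se2**2 / (
                (w1 * vc.sigma2_within) ** 2 / vc.df_error + (w2 * ms_int) ** 2 / df_int
            )
        else:
            nu = float(vc.df_error)
        est = float(means[g1] - means[g2])
        t_abs = abs(est) / se
        if multiplicity == "tukey":
            p = float(stats.studentized_range.sf(t_abs * math.sqrt(2.0), len(complete), nu))
        else:
            p = float(2.0 * stats.t.sf(t_abs, nu))
        out.append(
            PairCall(
                pair=(g1, g2),
                estimate=est,
                se=se,
                df=float(nu),
                p_value=p,
                replicable=p <= alpha,
            )
        )
    return out
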