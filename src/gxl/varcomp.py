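"""Random Lab Model fitting: variance components and the dimensionless GxL factor.

The two-way model for one phenotype in one stratum is

    y_{gli} = mu + beta_g + L_l + (GL)_{gl} + e_{gli},

with genotype effects beta_g fixed, lab effects L_l ~ N(0, sigma2_lab),
genotype-by-lab interactions (GL)_{gl} ~ N(0, sigma2_gxl), and residuals
e ~ N(0, sigma2_within), all independent.  The three-way extension adds a
fixed treatment effect (and its fixed interaction with genotype) plus random
treatment-by-lab and treatment-by-genotype-by-lab terms.

The GxL factor is gamma = sqrt(sigma2_gxl / sigma2_within): the ratio of the
interaction SD to the within-group SD.  It is dimensionless, so it transfers
across laboratories that measure the same phenotype on different scales.

Estimation is REML.  Because every random effect is constant within a
(genotype, lab[, treatment]) cell, the likelihood depends on the data only
through the cell means and the pooled within-cell sum of squares, so the
restricted likelihood is evaluated exactly on that reduction (a handful of
cells instead of hundreds of animals) and profiled over the residual
variance; the optimiser works on the variance ratios with a nonnegativity
bound, which implements the usual truncation of negative variance estimates
at zero.  For balanced designs the classical ANOVA expected-mean-squares
(method-of-moments) estimator is provided as an independent cross-check; in
the interior of the parameter space the two coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data_model import MeasurementTable, Subpopulation, Transform, apply_transform

__all__ = [
    "VarianceComponents",
    "VarianceComponents3",
    "GxLFactor",
    "DesignError",
    "fit_random_lab_model",
    "fit_treatment_model",
    "gxl_factor",
    "moments_two_way",
    "moments_three_way",
]


class DesignError(ValueError):
    """The design cannot identify the requested variance components."""


@dataclass(frozen=True)
class VarianceComponents:
    """Two-way Random Lab Model estimates for one phenotype x stratum."""

    sigma2_within: float
    sigma2_lab: float
    sigma2_gxl: float
    n_labs: int
    n_genotypes: int
    phenotype: str
    subpopulation: Subpopulation
    method: str = "reml"
    truncated: tuple[str, ...] = ()
    n_obs: int = 0
    df_error: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_within", "sigma2_lab", "sigma2_gxl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class VarianceComponents3(VarianceComponents):
    """Three-way model estimates: adds treatment-by-lab and treatment-by-genotype-by-lab.

    Treatment and treatment-by-genotype are fixed effects, so no variance is
    attached to them; every lab-involving interaction is random.
    """

    sigma2_txl: float = 0.0
    sigma2_txgxl: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("sigma2_txl", "sigma2_txgxl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class GxLFactor:
    """Dimensionless interaction factor gamma = sigma_interaction / sigma_within."""

    gamma: float
    kind: str  # "gxl" or "txgxl"
    n_labs: int
    n_genotypes: int
    source: str = ""
    phenotype: str = ""
    subpopulation: Subpopulation | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gxl", "txgxl"):
            raise ValueError("kind must be 'gxl' or 'txgxl'")
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma must be finite and nonnegative")


def gxl_factor(vc: VarianceComponents, kind: str = "gxl", source: str = "") -> GxLFactor:
    """gamma = sqrt(interaction variance / within-group variance)."""
    if vc.sigma2_within <= 0:
        raise ValueError("sigma2_within must be positive to form gamma")
    if kind == "gxl":
        s2 = vc.sigma2_gxl
    elif kind == "txgxl":
        if not isinstance(vc, VarianceComponents3):
            raise ValueError("txgxl factor requires a three-way fit")
        s2 = vc.sigma2_txgxl
    else:
        raise ValueError("kind must be 'gxl' or 'txgxl'")
    return GxLFactor(
        gamma=float(np.sqrt(s2 / vc.sigma2_within)),
        kind=kind,
        n_labs=vc.n_labs,
        n_genotypes=vc.n_genotypes,
        source=source,
        phenotype=vc.phenotype,
        subpopulation=vc.subpopulation,
    )


# ---------------------------------------------------------------------------
# Cell-mean reduction and REML core


@dataclass
class _Cells:
    means: np.ndarray          # (C,) cell means on the analysis scale
    sizes: np.ndarray          # (C,) animals per cell
    sse: float                 # pooled within-cell sum of squares
    n_obs: int
    X: np.ndarray              # (C, p) fixed-effect design on cell means
    groups: list[np.ndarray]   # one integer label vector per random term
    names: list[str]           # component name per random term


def _reduce(df: pd.DataFrame, three_way: bool) -> _Cells:
    keys = ["genotype", "lab"] + (["treatment"] if three_way else [])
    g = df.groupby(keys, sort=True)["value"]
    means = g.mean().to_numpy()
    sizes = g.size().to_numpy()
    sse = float((g.var(ddof=1).fillna(0.0) * (g.size() - 1)).sum())
    idx = g.mean().index.to_frame(index=False)
    geno = pd.factorize(idx["genotype"])[0]
    lab = pd.factorize(idx["lab"])[0]
    G, L = geno.max() + 1, lab.max() + 1
    if three_way:
        treat = pd.factorize(idx["treatment"])[0]
        # saturated fixed effects in genotype x treatment
        fixed = geno * (treat.max() + 1) + treat
        X = np.eye(fixed.max() + 1)[fixed]
        groups = [lab, geno * L + lab, treat * L + lab, np.arange(len(means))]
        names = ["lab", "gxl", "txl", "txgxl"]
    else:
        X = np.eye(G)[geno]
        groups = [lab, geno * L + lab]
        names = ["lab", "gxl"]
    return _Cells(means, sizes, sse, len(df), X, groups, names)


def _profiled_neg2_reml(
    theta: np.ndarray, cells: _Cells
) -> tuple[float, np.ndarray]:
    """Profiled -2 restricted log-likelihood (up to a constant) and its gradient.

    The gradient is analytic: for each variance-ratio component with level
    indicator vectors 1_g, d logdet terms reduce to sums of quadratic forms
    in W^-1, and the residual quadratic uses the envelope theorem (the GLS
    beta-hat contribution vanishes).
    """
    k = len(theta)
    grad = np.full(k, np.nan)
    W = np.diag(1.0 / cells.sizes)
    for t, lab in zip(theta, cells.groups):
        W += t * (lab[:, None] == lab[None, :])
    try:
        cf = linalg.cho_factor(W, lower=True)
    except linalg.LinAlgError:
        return np.inf, grad
    logdet_W = 2.0 * np.sum(np.log(np.diag(cf[0])))
    C = len(cells.means)
    Wi = linalg.cho_solve(cf, np.eye(C))
    M = Wi @ cells.X
    A = cells.X.T @ M
    try:
        cA = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:
        return np.inf, grad
    logdet_A = 2.0 * np.sum(np.log(np.diag(cA[0])))
    beta = linalg.cho_solve(cA, cells.X.T @ (Wi @ cells.means))
    r = cells.means - cells.X @ beta
    u = Wi @ r
    Q = float(r @ u)
    p = cells.X.shape[1]
    n = cells.n_obs
    sigma2 = (cells.sse + Q) / (n - p)
    if sigma2 <= 0:
        return np.inf, grad
    f = (n - p) * (np.log(sigma2) + 1.0) + logdet_W + logdet_A
    for j, lab in enumerate(cells.groups):
        t1 = t2 = t3 = 0.0
        for g in np.unique(lab):
            mask = lab == g
            t1 += float(Wi[np.ix_(mask, mask)].sum())          # tr(W^-1 E)
            t2 += float(u[mask].sum()) ** 2                    # r'W^-1 E W^-1 r
            s = M[mask].sum(axis=0)
            t3 += float(s @ linalg.cho_solve(cA, s))           # tr(A^-1 X'W^-1 E W^-1 X)
        grad[j] = -t2 / sigma2 + t1 - t3
    return f, grad


def _reml(cells: _Cells, start: np.ndarray | None = None) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Return (variance ratios, sigma2_within, truncated component names).

    Data are prescaled by a power-of-two magnitude so the optimisation is
    numerically identical across pure changes of measurement unit (the
    variance ratios, and hence gamma, are scale-free quantities).
    """
    wmean = float(np.average(cells.means, weights=cells.sizes))
    ms_total = (
        cells.sse + float(np.sum(cells.sizes * (cells.means - wmean) ** 2))
    ) / max(cells.n_obs - 1, 1)
    scale2 = 2.0 ** round(math.log2(ms_total)) if ms_total > 0 else 1.0
    cells = _Cells(
        means=cells.means / math.sqrt(scale2),
        sizes=cells.sizes,
        sse=cells.sse / scale2,
        n_obs=cells.n_obs,
        X=cells.X,
        groups=cells.groups,
        names=cells.names,
    )
    k = len(cells.groups)
    starts = [np.full(k, 0.1)]
    if start is not None:
        starts.insert(0, np.clip(start, 1e-4, 1e3))
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _profiled_neg2_reml,
            s0,
            args=(cells,),
            method="L-BFGS-B",
            jac=True,
            bounds=[(0.0, 1e6)] * k,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and start is not None:
            break  # moments-informed start converged; skip the generic restart
    theta = np.maximum(best.x, 0.0)
    # recover sigma2 at the optimum
    C = len(cells.means)
    W = np.diag(1.0 / cells.sizes)
    for t, lab in zip(theta, cells.groups):
        W += t * (lab[:, None] == lab[None, :])
    cf = linalg.cho_factor(W, lower=True)
    WiX = linalg.cho_solve(cf, cells.X)
    A = cells.X.T @ WiX
    beta = np.linalg.solve(A, cells.X.T @ linalg.cho_solve(cf, cells.means))
    r = cells.means - cells.X @ beta
    Q = float(r @ linalg.cho_solve(cf, r))
    p = cells.X.shape[1]
    sigma2 = (cells.sse + Q) / (cells.n_obs - p)
    truncated = tuple(
        name for th, name in zip(theta, cells.names) if th <= 1e-8
    )
    return theta, sigma2 * scale2, truncated


# ---------------------------------------------------------------------------
# Public fitting interface


def _prepare(
    table: MeasurementTable,
    phenotype: str,
    subpop: Subpopulation | None,
    transform: Transform,
    sex: str | None = None,
) -> pd.DataFrame:
    df = table.subset(phenotype=phenotype, subpop=subpop)
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no measurements for phenotype {phenotype!r} in the requested stratum")
    df = df.copy()
    df["value"] = apply_transform(df["value"].to_numpy(), transform)
    return df


def _check_two_way(df: pd.DataFrame) -> tuple[int, int]:
    labs = df["lab"].nunique()
    genos = df["genotype"].nunique()
    if labs < 2 or genos < 2:
        raise DesignError(
            f"need >= 2 labs and >= 2 genotypes (found {labs} lab(s), {genos} genotype(s))"
        )
    per = df.groupby("genotype")["lab"].nunique()
    thin = per[per < 2]
    if len(thin):
        raise DesignError(
            f"genotype(s) observed in < 2 labs: {', '.join(map(str, thin.index))}"
        )
    return labs, genos


def fit_random_lab_model(
    table: MeasurementTable,
    phenotype: str,
    subpop: Subpopulation | None = None,
    transform: Transform = Transform(),
    method: str = "reml",
) -> VarianceComponents:
    """Fit the two-way Random Lab Model and return its variance components.

    ``method="reml"`` is the default estimator and handles unbalanced cells;
    ``method="moments"`` is the balanced-design ANOVA expected-mean-squares
    estimator (refuses unbalanced data) retained as an independent oracle.
    """
    df = _prepare(table, phenotype, subpop, transform)
    n_labs, n_genos = _check_two_way(df)
    cells = _reduce(df, three_way=False)
    if cells.n_obs - len(cells.means) < 1:
        raise DesignError("one animal per cell everywhere: residual variance not identifiable")
    if method == "moments":
        s2, s2_lab, s2_gxl, trunc = moments_two_way(df)
    elif method == "reml":
        start = None
        try:
            m_s2, m_lab, m_gxl, _ = moments_two_way(df)
            if m_s2 > 0:
                start = np.array([m_lab / m_s2, m_gxl / m_s2])
        except DesignError:
            pass
        theta, s2, trunc = _reml(cells, start)
        s2_lab, s2_gxl = theta[0] * s2, theta[1] * s2
    else:
        raise ValueError("method must be 'reml' or 'moments'")
    return VarianceComponents(
        sigma2_within=float(s2),
        sigma2_lab=float(s2_lab),
        sigma2_gxl=float(s2_gxl),
        n_labs=n_labs,
        n_genotypes=n_genos,
        phenotype=phenotype,
        subpopulation=subpop if subpop is not None else Subpopulation("any", "any"),
        method=method,
        truncated=trunc,
        n_obs=cells.n_obs,
        df_error=cells.n_obs - len(cells.means),
    )


def fit_treatment_model(
    table: MeasurementTable,
    phenotype: str,
    sex: str,
    transform: Transform = Transform(),
    method: str = "reml",
) -> VarianceComponents3:
    """Fit the three-way model with a fixed treatment arm within one sex.

    Random terms: lab, genotype-by-lab, treatment-by-lab, and
    treatment-by-genotype-by-lab; treatment and treatment-by-genotype are
    fixed.  The TxGxL component is the one relevant for adjusting single-lab
    comparisons of treatment effects between genotypes.
    """
    df = _prepare(table, phenotype, None, transform, sex=sex)
    n_labs, n_genos = _check_two_way(df)
    treatments = df["treatment"].unique()
    if len(treatments) < 2:
        raise DesignError("both treatment levels must be present")
    per_lab = df.groupby("lab")["treatment"].nunique()
    incomplete = per_lab[per_lab < 2]
    if len(incomplete):
        raise DesignError(
            f"treatment level missing entirely in lab(s): {', '.join(map(str, incomplete.index))}"
        )
    cells = _reduce(df, three_way=True)
    if cells.n_obs - len(cells.means) < 1:
        raise DesignError("one animal per cell everywhere: residual variance not identifiable")
    if method == "moments":
        comp = moments_three_way(df)
        s2, s2_lab, s2_gxl, s2_txl, s2_txgxl, trunc = comp
    elif method == "reml":
        start = None
        try:
            m = moments_three_way(df)
            if m[0] > 0:
                start = np.array([m[1], m[2], m[3], m[4]]) / m[0]
        except DesignError:
            pass
        theta, s2, trunc = _reml(cells, start)
        s2_lab, s2_gxl, s2_txl, s2_txgxl = (theta * s2).tolist()
    else:
        raise ValueError("method must be 'reml' or 'moments'")
    return VarianceComponents3(
        sigma2_within=float(s2),
        sigma2_lab=float(s2_lab),
        sigma2_gxl=float(s2_gxl),
        sigma2_txl=float(s2_txl),
        sigma2_txgxl=float(s2_txgxl),
        n_labs=n_labs,
        n_genotypes=n_genos,
        phenotype=phenotype,
        subpopulation=Subpopulation(sex, "any"),
        method=method,
        truncated=trunc,
        n_obs=cells.n_obs,
        df_error=cells.n_obs - len(cells.means),
    )


# ---------------------------------------------------------------------------
# Balanced ANOVA (expected mean squares) estimators — the moments oracle


def _require_balanced(sizes: np.ndarray) -> int:
    if len(np.unique(sizes)) != 1:
        raise DesignError("moments estimator requires a balanced design")
    return int(sizes[0])


def moments_two_way(df: pd.DataFrame) -> tuple[float, float, float, tuple[str, ...]]:
    """Balanced two-way EMS estimator: (sigma2, sigma2_lab, sigma2_gxl, truncated)."""
    piv = df.pivot_table(index="genotype", columns="lab", values="value", aggfunc="mean")
    sizes = df.groupby(["genotype", "lab"]).size().to_numpy()
    if piv.isna().any().any():
        raise DesignError("moments estimator requires every genotype in every lab")
    m = _require_balanced(sizes)
    if m < 2:
        raise DesignError("moments estimator needs >= 2 animals per cell")
    G, L = piv.shape
    cellm = piv.to_numpy()
    grand = cellm.mean()
    gm = cellm.mean(axis=1, keepdims=True)
    lm = cellm.mean(axis=0, keepdims=True)
    inter = cellm - gm - lm + grand
    ms_gxl = m * float((inter**2).sum()) / ((G - 1) * (L - 1))
    ms_lab = G * m * float(((lm - grand) ** 2).sum()) / (L - 1)
    grp = df.groupby(["genotype", "lab"])["value"]
    sse = float((grp.var(ddof=1) * (grp.size() - 1)).sum())
    ms_err = sse / (len(df) - G * L)
    s2_gxl = (ms_gxl - ms_err) / m
    s2_lab = (ms_lab - ms_gxl) / (G * m)
    trunc = tuple(
        n for n, v in (("gxl", s2_gxl), ("lab", s2_lab)) if v < 0
    )
    return ms_err, max(s2_lab, 0.0), max(s2_gxl, 0.0), trunc


def moments_three_way(
    df: pd.DataFrame,
) -> tuple[float, float, float, float, float, tuple[str, ...]]:
    """Balanced three-way EMS estimator (unrestricted mixed-model convention).

    Returns (sigma2, sigma2_lab, sigma2_gxl, sigma2_txl, sigma2_txgxl, truncated).
    """
    grp = df.groupby(["genotype", "lab", "treatment"])["value"]
    sizes = grp.size().to_numpy()
    m = _require_balanced(sizes)
    if m < 2:
        raise DesignError("moments estimator needs >= 2 animals per cell")
    arr = grp.mean()
    idx = arr.index.to_frame(index=False)
    G = idx["genotype"].nunique()
    L = idx["lab"].nunique()
    T = idx["treatment"].nunique()
    if len(arr) != G * L * T:
        raise DesignError("moments estimator requires a fully crossed design")
    y = arr.to_numpy().reshape(G, L, T)
    grand = y.mean()
    a_g = y.mean(axis=(1, 2)) - grand
    a_l = y.mean(axis=(0, 2)) - grand
    a_t = y.mean(axis=(0, 1)) - grand
    gl = y.mean(axis=2) - grand - a_g[:, None] - a_l[None, :]
    tl = y.mean(axis=0) - grand - a_l[:, None] - a_t[None, :]
    gt = y.mean(axis=1) - grand - a_g[:, None] - a_t[None, :]
    tgl = (
        y
        - grand
        - a_g[:, None, None]
        - a_l[None, :, None]
        - a_t[None, None, :]
        - gl[:, :, None]
        - tl[None, :, :]
        - gt[:, None, :]
    )
    sse = float((grp.var(ddof=1) * (grp.size() - 1)).sum())
    ms_err = sse / (len(df) - G * L * T)
    ms_tgl = m * float((tgl**2).sum()) / ((G - 1) * (L - 1) * (T - 1))
    ms_gl = m * T * float((gl**2).sum()) / ((G - 1) * (L - 1))
    ms_tl = m * G * float((tl**2).sum()) / ((T - 1) * (L - 1))
    ms_l = m * G * T * float((a_l**2).sum()) / (L - 1)
    s2_tgl = (ms_tgl - ms_err) / m
    s2_gl = (ms_gl - ms_tgl) / (m * T)
    s2_tl = (ms_tl - ms_tgl) / (m * G)
    s2_l = (ms_l - ms_tl - ms_gl + ms_tgl) / (m * G * T)
    trunc = tuple(
        n
        for n, v in (
            ("txgxl", s2_tgl),
            ("gxl", s2_gl),
            ("txl", s2_tl),
            ("lab", s2_l),
        )
        if v < 0
    )
    return (
        ms_err,
        max(s2_l, 0.0),
        max(s2_gl, 0.0),
        max(s2_tl, 0.0),
        max(s2_tgl, 0.0),
        trunc,
    )
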