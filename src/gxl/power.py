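"""Power and sample size for two-group designs under GxL inflation.

The adjusted two-sided t-test of a mean difference ``effect`` at within-group
SD ``sigma`` has standard error sigma*sqrt(2/n + 2 gamma^2) for n animals
per group: the first term shrinks with n but the interaction term does not.
Power is therefore bounded above by the limit n -> infinity, where the
noncentrality is effect/(sigma*sqrt(2)*gamma) and the Satterthwaite df tend
to the interaction df (n_L-1)(n_S-1).  Targets above that ceiling are
unattainable at any sample size.

Sample size uses the iterative plug-in scheme: solve the classical problem
at SD sigma, inflate to sigma_1 = sigma*sqrt(1 + n*gamma^2) (so that
sigma_1^2 * 2/n reproduces the Random Lab Model variance), re-solve, and
repeat to a fixed point; the result is then polished against the exact
adjusted power so that n is the smallest integer meeting the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

from .adjust import satterthwaite_df

__all__ = ["PowerDesign", "SampleSizeResult", "power_of_design", "required_n", "power_limit"]


@dataclass(frozen=True)
class PowerDesign:
    """A two-group comparison to be powered (effect and sigma on the analysis scale)."""

    effect: float
    sigma: float
    gamma: float = 0.0
    alpha: float = 0.05
    n_per_group: int = 10
    n_labs: int = 3
    n_genotypes: int = 6

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search; ``n`` is None when the target is unattainable."""

    n: int | None
    attainable: bool
    asymptotic_power: float
    target_power: float
    iterations: int = 0
    oscillated: bool = False


def _noncentral_power(ncp: float, df: float, alpha: float) -> float:
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    p = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if not math.isfinite(p):  # nct underflows for very large df; Gaussian limit
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        p = float(stats.norm.sf(zcrit - ncp) + stats.norm.cdf(-zcrit - ncp))
    return p


def power_of_design(d: PowerDesign) -> float:
    """Exact power of the two-sided adjusted t-test for the given design."""
    se = d.sigma * math.sqrt(2.0 / d.n_per_group + 2.0 * d.gamma**2)
    ncp = d.effect / se
    df = satterthwaite_df(d.n_per_group, d.n_per_group, d.gamma, d.n_labs, d.n_genotypes)
    return _noncentral_power(ncp, df, d.alpha)


def power_limit(
    effect: float,
    sigma: float,
    gamma: float,
    alpha: float = 0.05,
    n_labs: int = 3,
    n_genotypes: int = 6,
) -> float:
    """Power ceiling as n -> infinity.

    With gamma > 0 the standard error floors at sigma*sqrt(2)*gamma and the
    Satterthwaite df tend to (n_L-1)(n_S-1); with gamma = 0 any nonzero
    effect is eventually detected (limit 1.0), and a zero effect rejects at
    the nominal level.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if effect == 0.0:
        return alpha
    if gamma == 0.0:
        return 1.0
    ncp = effect / (sigma * math.sqrt(2.0) * gamma)
    df = float((n_labs - 1) * (n_genotypes - 1))
    return _noncentral_power(ncp, df, alpha)


def _classical_n(effect: float, sigma: float, alpha: float, target: float) -> int:
    """Smallest equal n per group for a classical two-sample two-sided t-test."""
    def pw(n: int) -> float:
        return _noncentral_power(effect / (sigma * math.sqrt(2.0 / n)), 2 * n - 2, alpha)

    n = 2
    while pw(n) < target:
        n = min(n * 2, 10**7)
        if n >= 10**7:
            raise ValueError("classical sample size exceeds 1e7; check effect/sigma")
    lo = max(2, n // 2)
    while lo < n:
        mid = (lo + n) // 2
        if pw(mid) >= target:
            n = mid
        else:
            lo = mid + 1
    return n


def required_n(
    effect: float,
    sigma: float,
    gamma: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    n_labs: int = 3,
    n_genotypes: int = 6,
    literal_sigma: bool = False,
    max_iter: int = 100,
) -> SampleSizeResult:
    """Animals per group for the adjusted test via the iterative sigma scheme.

    ``literal_sigma=True`` uses the inflation sigma_1 = sqrt(sigma^2 + n*gamma^2)
    exactly as sometimes written; the default sigma_1 = sigma*sqrt(1 + n*gamma^2)
    is the dimensionally consistent reading that reproduces the model variance
    sigma^2*(2/n) + 2*sigma^2*gamma^2.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    if effect == 0.0:
        raise ValueError("effect must be nonzero")
    limit = power_limit(effect, sigma, gamma, alpha, n_labs, n_genotypes)
    if gamma > 0 and target_power >= limit:
        return SampleSizeResult(
            n=None, attainable=False, asymptotic_power=limit, target_power=target_power
        )

    def inflate(n: int) -> float:
        if literal_sigma:
            return math.sqrt(sigma**2 + n * gamma**2)
        return sigma * math.sqrt(1.0 + n * gamma**2)

    n = _classical_n(effect, sigma, alpha, target_power)
    seen: list[int] = [n]
    oscillated = False
    it = 0
    for it in range(1, max_iter + 1):
        n_new = _classical_n(effect, inflate(n), alpha, target_power)
        if n_new == n:
            break
        if n_new in seen:  # 2-cycle: keep the conservative (larger) point
            n = max(n, n_new)
            oscillated = True
            break
        seen.append(n_new)
        n = n_new

    def adjusted_power(k: int) -> float:
        return power_of_design(
            PowerDesign(effect, sigma, gamma, alpha, k, n_labs, n_genotypes)
        )

    # polish against the exact adjusted power so n inverts power_of_design
    while adjusted_power(n) < target_power:
        n += 1
    while n > 2 and adjusted_power(n - 1) >= target_power:
        n -= 1
    return SampleSizeResult(
        n=n,
        attainable=True,
        asymptotic_power=limit,
        target_power=target_power,
        iterations=it,
        oscillated=oscillated,
    )
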