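"""Synthetic multi-lab phenotyping data under the Random Lab Model.

The generator draws fully crossed, balanced designs

    y_{gl(t)i} = mu_g (+ tau * treated) + L_l + GL_{gl} (+ TL_{tl} + TGL_{tgl}) + e_i

with every random term independent Gaussian at its configured SD.  The
defaults emulate the reference multi-lab design: 3 laboratories, 6 inbred
genotypes, about 10 animals per group, within-group SD 1 on the analysis
scale, a lab SD of the same order as the within-group SD, and an interaction
SD chosen so that gamma = sigma_gxl/sigma falls in the 0.3-1.0 range
observed for rodent behavioural and physiological phenotypes.

A single root seed determines the whole table; per-component substreams are
spawned deterministically so that, e.g., enlarging one SD does not reshuffle
the other draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import MeasurementTable, Transform

__all__ = ["SimConfig", "simulate_multilab", "simulate_single_lab", "drop_out"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic multi-lab draw (SDs on the analysis scale)."""

    n_labs: int = 3
    n_genotypes: int = 6
    n_per_group: int = 10
    genotype_effects: tuple[float, ...] | None = None  # default: all zero
    sigma_within: float = 1.0
    sigma_lab: float = 1.0
    sigma_gxl: float = 0.5
    with_treatment: bool = False
    treatment_effect: float = 0.0
    sigma_txl: float = 0.0
    sigma_txgxl: float = 0.0
    phenotype: str = "synthetic"
    sex: str = "male"
    transform_scale: Transform = Transform()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labs < 1 or self.n_genotypes < 1 or self.n_per_group < 1:
            raise ValueError("design counts must be positive")
        for name in ("sigma_within", "sigma_lab", "sigma_gxl", "sigma_txl", "sigma_txgxl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.genotype_effects is not None and len(self.genotype_effects) != self.n_genotypes:
            raise ValueError("genotype_effects length must equal n_genotypes")

    @property
    def effects(self) -> np.ndarray:
        if self.genotype_effects is None:
            return np.zeros(self.n_genotypes)
        return np.asarray(self.genotype_effects, dtype=float)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_multilab(cfg: SimConfig) -> MeasurementTable:
    """Draw one balanced multi-lab dataset under the configured model.

    The table is returned on the *native* scale: random effects are additive
    on the analysis scale, and the inverse of ``cfg.transform_scale`` is
    applied at the end, so that re-applying the transform downstream recovers
    an exactly additive model.
    """
    G, L, m = cfg.n_genotypes, cfg.n_labs, cfg.n_per_group
    arms = ("control", "treated") if cfg.with_treatment else ("control",)
    T = len(arms)
    rng_lab, rng_gxl, rng_txl, rng_tgxl, rng_eps = _streams(cfg.seed, 5)
    lab_eff = rng_lab.normal(0.0, cfg.sigma_lab, size=L)
    gxl_eff = rng_gxl.normal(0.0, cfg.sigma_gxl, size=(G, L))
    txl_eff = rng_txl.normal(0.0, cfg.sigma_txl, size=(T, L)) if cfg.with_treatment else None
    tgxl_eff = (
        rng_tgxl.normal(0.0, cfg.sigma_txgxl, size=(G, T, L)) if cfg.with_treatment else None
    )
    effects = cfg.effects
    # cell grid in (genotype, lab, treatment) order, m animals per cell
    g_idx, l_idx, t_idx = np.meshgrid(np.arange(G), np.arange(L), np.arange(T), indexing="ij")
    g_idx, l_idx, t_idx = g_idx.ravel(), l_idx.ravel(), t_idx.ravel()
    base = effects[g_idx] + lab_eff[l_idx] + gxl_eff[g_idx, l_idx]
    if cfg.with_treatment:
        base = base + txl_eff[t_idx, l_idx] + tgxl_eff[g_idx, t_idx, l_idx]
        base = base + cfg.treatment_effect * (t_idx == 1)
    n = len(base) * m
    values = np.repeat(base, m) + rng_eps.normal(0.0, cfg.sigma_within, size=n)
    df = pd.DataFrame(
        {
            "animal_id": np.char.add("a", np.arange(n).astype(str)),
            "lab": np.char.add("lab", np.repeat(l_idx + 1, m).astype(str)),
            "genotype": np.char.add("g", np.repeat(g_idx + 1, m).astype(str)),
            "sex": cfg.sex,
            "treatment": np.asarray(arms)[np.repeat(t_idx, m)],
            "phenotype": cfg.phenotype,
            "value": cfg.transform_scale.inverse(values),
        }
    )
    return MeasurementTable(df)


def simulate_single_lab(cfg: SimConfig, lab_index: int = 0) -> MeasurementTable:
    """One lab's slice of the multi-lab draw for ``cfg``.

    Because the slice comes from the same realisation as
    :func:`simulate_multilab`, the across-lab truth for every genotype
    difference is known to the caller, which is what a replicability test
    harness needs.
    """
    if not 0 <= lab_index < cfg.n_labs:
        raise ValueError(f"lab_index must be in [0, {cfg.n_labs})")
    full = simulate_multilab(cfg)
    return MeasurementTable(full.subset(lab=f"lab{lab_index + 1}"))


def drop_out(table: MeasurementTable, rate: float, seed: int = 0) -> MeasurementTable:
    """Delete each animal independently with probability ``rate`` (unbalances the design)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(table)) >= rate
    return MeasurementTable(table.df[keep])
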