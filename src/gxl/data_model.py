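"""Tidy per-animal phenotype records, variance-stabilising transforms, and group summaries.

The universal input to every stage is a long-format table with one row per
animal per phenotype: lab, genotype, sex, treatment, phenotype name, and the
measured value on its native scale.  Phenotypes whose raw distributions are
far from Gaussian (percentages such as centre time or immobility time, or
right-skewed grip strength) are analysed on a transformed scale; the
transform is applied once, before any variance estimation, and carried
through the whole pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_COLUMNS",
    "MeasurementTable",
    "Subpopulation",
    "Transform",
    "GroupStats",
    "read_measurements",
    "apply_transform",
    "group_summaries",
    "load_transform_config",
    "SchemaError",
    "IntegrityError",
]

CANONICAL_COLUMNS = (
    "animal_id",
    "lab",
    "genotype",
    "sex",
    "treatment",
    "phenotype",
    "value",
)


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class IntegrityError(ValueError):
    """The table violates a structural invariant (duplicates, missing values)."""


@dataclass(frozen=True)
class Subpopulation:
    """An analysis stratum: a sex crossed with a treatment arm.

    The three strata of the reference design are untreated females,
    untreated males, and fluoxetine-treated males, but any (sex, treatment)
    pair is accepted.
    """

    sex: str
    treatment: str = "control"

    def label(self) -> str:
        return f"{self.sex}-{self.treatment}"

    def mask(self, df: pd.DataFrame) -> pd.Series:
        return (df["sex"] == self.sex) & (df["treatment"] == self.treatment)


FEMALE_CONTROL = Subpopulation("female", "control")
MALE_CONTROL = Subpopulation("male", "control")
MALE_TREATED = Subpopulation("male", "treated")


@dataclass(frozen=True)
class Transform:
    """Monotone rescaling applied before analysis.

    ``logit_percent`` maps a percentage v in [0, 100] to log(p/(1-p)) with
    p = clip(v/100, epsilon, 1-epsilon); ``cube_root`` maps v >= 0 to v**(1/3);
    ``log`` requires v > 0.  All are strictly monotone on their domains, so
    group orderings are preserved.
    """

    name: str = "identity"
    epsilon: float = 1e-3

    _NAMES = ("identity", "logit_percent", "cube_root", "log")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown transform {self.name!r}; expected one of {self._NAMES}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")

    def __call__(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        return apply_transform(values, self)

    def inverse(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        y = np.asarray(values, dtype=float)
        if self.name == "identity":
            return y
        if self.name == "logit_percent":
            return 100.0 / (1.0 + np.exp(-y))
        if self.name == "cube_root":
            return y**3
        return np.exp(y)


def apply_transform(values: Sequence[float] | np.ndarray, t: Transform) -> np.ndarray:
    """Apply ``t`` elementwise; raises ``ValueError`` on out-of-domain input."""
    v = np.asarray(values, dtype=float)
    if t.name == "identity":
        return v.copy()
    if t.name == "logit_percent":
        if np.any((v < 0) | (v > 100)):
            raise ValueError("logit_percent requires values in [0, 100]")
        p = np.clip(v / 100.0, t.epsilon, 1.0 - t.epsilon)
        return np.log(p / (1.0 - p))
    if t.name == "cube_root":
        if np.any(v < 0):
            raise ValueError("cube_root requires values >= 0")
        return np.cbrt(v)
    if np.any(v <= 0):
        raise ValueError("log requires values > 0")
    return np.log(v)


@dataclass(frozen=True)
class GroupStats:
    """Per-(lab, genotype, stratum) sample size, mean and SD on the analysis scale."""

    lab: str
    genotype: str
    subpopulation: Subpopulation
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be positive")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


class MeasurementTable:
    """Validated long-format phenotype measurements.

    Wraps a :class:`pandas.DataFrame` with the canonical columns and enforces
    the structural invariants at construction: unique (animal_id, phenotype)
    pairs, no missing lab/genotype/phenotype labels, finite numeric values.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
        for col in ("lab", "genotype", "phenotype"):
            blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
            if blank.any():
                raise IntegrityError(f"missing values in column {col!r}")
        vals = pd.to_numeric(df["value"], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise IntegrityError(f"non-numeric or non-finite value at row(s) {rows}")
        df["value"] = vals.astype(float)
        dup = df.duplicated(subset=["animal_id", "phenotype"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise IntegrityError(f"duplicate (animal_id, phenotype) at row(s) {rows}")
        self._df = df.reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self._df.sort_values(["animal_id", "phenotype"]).reset_index(drop=True)
        b = other._df.sort_values(["animal_id", "phenotype"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def labs(self) -> list[str]:
        return sorted(self._df["lab"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self._df["genotype"].unique())

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self._df["phenotype"].unique())

    def subset(
        self,
        phenotype: str | None = None,
        subpop: Subpopulation | None = None,
        lab: str | None = None,
    ) -> pd.DataFrame:
        """Filtered copy of the underlying frame (not re-validated)."""
        df = self._df
        if phenotype is not None:
            df = df[df["phenotype"] == phenotype]
        if subpop is not None:
            df = df[subpop.mask(df)]
        if lab is not None:
            df = df[df["lab"] == lab]
        return df.copy()

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(list(records)))


def read_measurements(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> MeasurementTable:
    """Read a CSV of per-animal measurements.

    Parameters
    ----------
    path
        CSV file with a header row (comma-separated, UTF-8).
    schema
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"lab": "site"}``.  Unmapped columns must already carry
        their canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep_default_na so tokens like "NA" surface verbatim in the parse error
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(df.index[bad][0])
        raise IntegrityError(
            f"could not parse value {df.loc[row, 'value']!r} as a number at row {row}"
        )
    df["value"] = vals
    return MeasurementTable(df)


def group_summaries(
    table: MeasurementTable,
    phenotype: str,
    transform: Transform = Transform(),
    subpop: Subpopulation | None = None,
) -> list[GroupStats]:
    """Per-(lab, genotype, stratum) n / mean / SD on the transformed scale.

    Groups with fewer than two animals carry no within-group variance and are
    excluded with a warning.  SDs use the n-1 denominator.
    """
    df = table.subset(phenotype=phenotype, subpop=subpop)
    if df.empty:
        raise ValueError(f"no measurements for phenotype {phenotype!r}")
    df = df.assign(value=apply_transform(df["value"].to_numpy(), transform))
    out: list[GroupStats] = []
    for (lab, genotype, sex, treatment), g in df.groupby(
        ["lab", "genotype", "sex", "treatment"], sort=True
    ):
        sp = Subpopulation(sex, treatment)
        n = len(g)
        if n < 2:
            warnings.warn(
                f"group (lab={lab}, genotype={genotype}, {sp.label()}) has n={n} < 2; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        out.append(
            GroupStats(
                lab=str(lab),
                genotype=str(genotype),
                subpopulation=sp,
                n=n,
                mean=float(g["value"].mean()),
                sd=float(g["value"].std(ddof=1)),
            )
        )
    return out


def load_transform_config(path: str | Path) -> dict[str, Transform]:
    """Read a YAML/JSON mapping phenotype -> transform name (or {name, epsilon})."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, Transform] = {}
    for phen, spec in (raw or {}).items():
        if isinstance(spec, str):
            out[phen] = Transform(spec)
        else:
            out[phen] = Transform(spec["name"], float(spec.get("epsilon", 1e-3)))
    return out
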