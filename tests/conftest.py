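import pandas as pd
import pytest

from gxl import GroupStats, MeasurementTable, Subpopulation

MALE = Subpopulation("male")


@pytest.fixture
def male() -> Subpopulation:
    return MALE


def make_table(rows) -> MeasurementTable:
    """Rows of (animal_id, lab, genotype, sex, treatment, phenotype, value)."""
    return MeasurementTable(
        pd.DataFrame(
            rows,
            columns=["animal_id", "lab", "genotype", "sex", "treatment", "phenotype", "value"],
        )
    )


def group(lab="lab1", genotype="g1", n=10, mean=0.0, sd=1.0, subpop=MALE) -> GroupStats:
    return GroupStats(lab=lab, genotype=genotype, subpopulation=subpop, n=n, mean=mean, sd=sd)


@pytest.fixture
def tiny_table() -> MeasurementTable:
    rows = []
    k = 0
    for lab in ("lab1", "lab2"):
        for geno in ("g1", "g2"):
            for v in (1.0, 2.0, 3.0):
                rows.append((f"a{k}", lab, geno, "male", "control", "bw", v + (geno == "g2")))
                k += 1
    return make_table(rows)
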