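import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxl import (
    MeasurementTable,
    SimConfig,
    Subpopulation,
    fit_random_lab_model,
    fit_treatment_model,
    gxl_factor,
    simulate_multilab,
)
from gxl.varcomp import DesignError, VarianceComponents, VarianceComponents3

from conftest import MALE, make_table


def _vc(s2, s2_gxl, s2_lab=0.1):
    return VarianceComponents(
        sigma2_within=s2, sigma2_lab=s2_lab, sigma2_gxl=s2_gxl,
        n_labs=3, n_genotypes=6, phenotype="bw", subpopulation=MALE,
    )


class TestGxLFactor:
    def test_body_weight_worked_example(self):
        # sigma_gxl = 0.8, sigma = 1.4 for female body weight
        f = gxl_factor(_vc(1.4**2, 0.8**2))
        assert round(f.gamma, 2) == 0.57

    def test_zero_interaction_gives_zero(self):
        assert gxl_factor(_vc(2.0, 0.0)).gamma == 0.0

    def test_equal_variances_give_one(self):
        assert gxl_factor(_vc(1.7, 1.7)).gamma == pytest.approx(1.0)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            gxl_factor(_vc(0.0, 0.0))

    def test_txgxl_requires_three_way_fit(self):
        with pytest.raises(ValueError):
            gxl_factor(_vc(1.0, 0.5), kind="txgxl")


class TestTwoWayFit:
    def test_reml_matches_moments_on_balanced_interior(self):
        for seed in (1, 3, 11):
            tab = simulate_multilab(SimConfig(sigma_lab=1.0, sigma_gxl=0.6, seed=seed))
            reml = fit_random_lab_model(tab, "synthetic", MALE, method="reml")
            mom = fit_random_lab_model(tab, "synthetic", MALE, method="moments")
            if reml.truncated or mom.truncated:
                continue
            assert reml.sigma2_within == pytest.approx(mom.sigma2_within, abs=1e-6)
            assert reml.sigma2_lab == pytest.approx(mom.sigma2_lab, abs=1e-6)
            assert reml.sigma2_gxl == pytest.approx(mom.sigma2_gxl, abs=1e-6)

    def test_null_model_recovers_small_gamma(self):
        # no lab effect, no interaction, large n: estimated factor near zero
        for seed in (0, 1):
            tab = simulate_multilab(
                SimConfig(sigma_lab=0.0, sigma_gxl=0.0, n_per_group=200, seed=seed)
            )
            vc = fit_random_lab_model(tab, "synthetic", MALE)
            assert gxl_factor(vc).gamma < 0.1

    def test_monte_carlo_gamma_recovery(self):
        gammas = []
        for seed in range(500):
            tab = simulate_multilab(SimConfig(sigma_gxl=0.57, sigma_lab=1.0, seed=seed))
            gammas.append(gxl_factor(fit_random_lab_model(tab, "synthetic", MALE)).gamma)
        assert abs(np.median(gammas) - 0.57) < 0.15

    def test_truncation_flagged(self):
        tab = simulate_multilab(
            SimConfig(sigma_gxl=0.0, sigma_lab=0.5, n_per_group=4, seed=5)
        )
        mom = fit_random_lab_model(tab, "synthetic", MALE, method="moments")
        assert "gxl" in mom.truncated
        assert mom.sigma2_gxl == 0.0

    def test_single_lab_rejected(self):
        rows = [(f"a{i}", "lab1", f"g{1 + i % 2}", "male", "control", "bw", float(i))
                for i in range(8)]
        with pytest.raises(DesignError):
            fit_random_lab_model(make_table(rows), "bw")

    def test_moments_refuses_unbalanced(self):
        tab = simulate_multilab(SimConfig(seed=0))
        df = tab.df.drop(index=[0]).reset_index(drop=True)
        with pytest.raises(DesignError):
            fit_random_lab_model(MeasurementTable(df), "synthetic", MALE, method="moments")

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_gamma_scale_invariance(self, c):
        # measuring in inches vs centimetres must not move the factor
        tab = simulate_multilab(SimConfig(sigma_gxl=0.5, seed=7))
        base = gxl_factor(fit_random_lab_model(tab, "synthetic", MALE)).gamma
        df = tab.df.assign(value=tab.df["value"] * c)
        scaled = gxl_factor(fit_random_lab_model(MeasurementTable(df), "synthetic", MALE)).gamma
        assert scaled == pytest.approx(base, abs=1e-8)

    def test_lab_shift_leaves_interaction_and_error(self):
        tab = simulate_multilab(SimConfig(sigma_gxl=0.5, seed=2))
        base = fit_random_lab_model(tab, "synthetic", MALE)
        shift = tab.df["lab"].map({"lab1": 0.0, "lab2": 5.0, "lab3": -3.0})
        shifted = fit_random_lab_model(
            MeasurementTable(tab.df.assign(value=tab.df["value"] + shift)), "synthetic", MALE
        )
        assert shifted.sigma2_gxl == pytest.approx(base.sigma2_gxl, abs=1e-6)
        assert shifted.sigma2_within == pytest.approx(base.sigma2_within, abs=1e-6)
        assert shifted.sigma2_lab != pytest.approx(base.sigma2_lab, abs=1e-3)


class TestThreeWayFit:
    def test_null_txgxl_recovered_near_zero(self):
        gammas = []
        for seed in range(200):
            tab = simulate_multilab(
                SimConfig(with_treatment=True, sigma_txgxl=0.0, sigma_txl=0.2, seed=seed)
            )
            vc3 = fit_treatment_model(tab, "synthetic", "male")
            gammas.append(gxl_factor(vc3, "txgxl").gamma)
        assert np.median(gammas) < 0.1

    def test_monte_carlo_txgxl_recovery(self):
        gammas = []
        for seed in range(200):
            tab = simulate_multilab(
                SimConfig(with_treatment=True, sigma_txgxl=0.3, sigma_txl=0.2,
                          treatment_effect=1.0, seed=seed)
            )
            vc3 = fit_treatment_model(tab, "synthetic", "male")
            gammas.append(gxl_factor(vc3, "txgxl").gamma)
        assert abs(np.median(gammas) - 0.3) < 0.15

    def test_treatment_in_one_lab_only_names_lab(self):
        rows = []
        k = 0
        for lab in ("lab1", "lab2"):
            for geno in ("g1", "g2"):
                for arm in ("control", "treated"):
                    if lab == "lab2" and arm == "treated":
                        continue
                    for v in (1.0, 2.0):
                        rows.append((f"a{k}", lab, geno, "male", arm, "bw", v))
                        k += 1
        with pytest.raises(DesignError, match="lab2"):
            fit_treatment_model(make_table(rows), "bw", "male")

    def test_components_nonnegative(self):
        tab = simulate_multilab(
            SimConfig(with_treatment=True, sigma_txgxl=0.3, sigma_txl=0.1, seed=4)
        )
        vc3 = fit_treatment_model(tab, "synthetic", "male")
        assert isinstance(vc3, VarianceComponents3)
        for name in ("sigma2_within", "sigma2_lab", "sigma2_gxl", "sigma2_txl", "sigma2_txgxl"):
            assert getattr(vc3, name) >= 0
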