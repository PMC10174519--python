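import numpy as np
import pytest

from gxl import (
    ComparisonRecord,
    GxLFactor,
    MeasurementTable,
    ReplicabilityTable,
    SimConfig,
    adjusted_t_test,
    classify,
    group_summaries,
    percent,
    replicability_calls,
    simulate_multilab,
    summarize,
    tabulate,
)

from conftest import MALE


def record(replicable, p, p_adj, pair="g1-g2"):
    return ComparisonRecord("bw", "male", pair, p, p_adj, replicable)


class TestClassify:
    @pytest.mark.parametrize(
        "replicable,p,p_adj,cat",
        [
            (True, 0.01, 0.03, "A"),
            (True, 0.01, 0.20, "B"),
            (True, 0.30, 0.40, "C"),
            (False, 0.01, 0.03, "D"),
            (False, 0.01, 0.20, "E"),
            (False, 0.30, 0.40, "F"),
        ],
    )
    def test_definitions(self, replicable, p, p_adj, cat):
        assert classify(record(replicable, p, p_adj)) == cat

    def test_impossible_combination_rejected(self):
        # adjusted significant but single-lab not: violates monotonicity
        with pytest.raises(ValueError, match="impossible"):
            classify(record(True, 0.30, 0.01))

    def test_partition_exhaustive(self):
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(200):
            p = float(rng.uniform(0.001, 1.0))
            p_adj = float(min(1.0, p * rng.uniform(1.0, 5.0)))
            recs.append(record(bool(rng.integers(2)), p, p_adj))
        table = tabulate(recs)
        assert table.total == 200
        assert table.n_replicable + table.n_non_replicable == 200


class TestTabulate:
    def test_one_record_per_category(self):
        recs = [
            record(True, 0.01, 0.03),
            record(True, 0.01, 0.20),
            record(True, 0.30, 0.40),
            record(False, 0.01, 0.03),
            record(False, 0.01, 0.20),
            record(False, 0.30, 0.40),
        ]
        t = tabulate(recs)
        assert (t.A, t.B, t.C, t.D, t.E, t.F) == (1, 1, 1, 1, 1, 1)

    def test_all_replicable(self):
        t = tabulate([record(True, 0.01, 0.02) for _ in range(5)])
        assert (t.D, t.E, t.F) == (0, 0, 0) and t.A == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tabulate([])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        recs = [record(bool(rng.integers(2)), 0.04, 0.06, pair=f"p{i}") for i in range(20)]
        a = summarize(tabulate(recs))
        b = summarize(tabulate(list(reversed(recs))))
        assert a == b


class TestSummarize:
    def test_zero_denominators_undefined_not_raised(self):
        t = ReplicabilityTable(A=0, B=0, C=0, D=2, E=3, F=5)
        s = summarize(t)
        assert s.power_unadjusted is None and s.power_adjusted is None
        assert s.typeI_unadjusted.pct == pytest.approx(50.0)
        assert s.typeI_adjusted.pct == pytest.approx(20.0)

    def test_monotone_orderings(self):
        t = ReplicabilityTable(A=35, B=11, C=7, D=12, E=47, F=40)
        s = summarize(t)
        assert s.typeI_adjusted.pct <= s.typeI_unadjusted.pct
        assert s.power_adjusted.pct <= s.power_unadjusted.pct

    def test_percent_rounding_half_up(self):
        assert percent(59.5959, 1) == 59.6
        assert percent(86.7924) == 87.0
        assert percent(50.847) == 51.0
        assert percent(23.728) == 24.0


class TestReplicabilityCalls:
    def test_missing_genotype_skipped_with_warning(self):
        tab = simulate_multilab(SimConfig(seed=0))
        df = tab.df[~((tab.df["lab"] == "lab3") & (tab.df["genotype"] == "g6"))]
        with pytest.warns(UserWarning, match="g6"):
            calls = replicability_calls(MeasurementTable(df), "synthetic", MALE)
        pairs = {c.pair for c in calls}
        assert all("g6" not in p for p in pairs)
        assert len(calls) == 10  # 5 complete genotypes -> C(5,2)

    def test_strong_effect_called_replicable(self):
        """A 3-sigma genotype effect at gamma=0.3 is declared replicable in
        essentially every multi-lab replicate."""
        hits = 0
        n_rep = 300
        effects = (3.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        for seed in range(n_rep):
            tab = simulate_multilab(
                SimConfig(sigma_gxl=0.3, genotype_effects=effects, seed=50_000 + seed)
            )
            calls = {c.pair: c for c in replicability_calls(tab, "synthetic", MALE)}
            hits += calls[("g1", "g2")].replicable
        assert hits / n_rep >= 0.95

    def test_tukey_option_is_more_conservative(self):
        tab = simulate_multilab(SimConfig(sigma_gxl=0.4, seed=12))
        plain = {c.pair: c.p_value for c in replicability_calls(tab, "synthetic", MALE)}
        tukey = {c.pair: c.p_value
                 for c in replicability_calls(tab, "synthetic", MALE, multiplicity="tukey")}
        assert all(tukey[p] >= plain[p] - 1e-12 for p in plain)

    def test_null_call_rate_near_nominal(self):
        """With no genotype effect the Random-Lab-Model call fires at about
        the nominal 5% despite gamma=0.5."""
        rej = 0
        n_rep = 1000
        for seed in range(n_rep):
            tab = simulate_multilab(SimConfig(sigma_gxl=0.5, seed=40_000 + seed))
            rej += replicability_calls(tab, "synthetic", MALE)[0].replicable
        assert 0.03 <= rej / n_rep <= 0.07


class TestEndToEnd:
    def test_adjustment_reduces_type_one_replicability_error(self):
        """Full pipeline on simulated universes with mixed effect sizes at
        gamma=0.7: the adjusted type-I replicability error is below the
        unadjusted one in >= 95% of meta-replicates."""
        wins = 0
        n_meta = 30
        effects = (0.0, 0.0, 0.0, 1.5, 1.5, 3.0)
        factor = GxLFactor(0.7, "gxl", 3, 6)
        for meta in range(n_meta):
            records = []
            for ph in range(4):
                name = f"p{ph}"
                cfg = SimConfig(
                    sigma_gxl=0.7, genotype_effects=effects,
                    seed=70_000 + meta * 17 + ph, phenotype=name,
                )
                tab = simulate_multilab(cfg)
                calls = {c.pair: c for c in replicability_calls(tab, name, MALE)}
                lab1 = {g.genotype: g for g in group_summaries(tab, name, subpop=MALE)
                        if g.lab == "lab1"}
                for (g1, g2), call in calls.items():
                    raw = adjusted_t_test(lab1[g1], lab1[g2], 0.0)
                    adj = adjusted_t_test(lab1[g1], lab1[g2], factor)
                    records.append(
                        ComparisonRecord(
                            name, "male", f"{g1}-{g2}",
                            max(raw.p_value, 1e-300), max(adj.p_value, 1e-300),
                            call.replicable,
                        )
                    )
            summary = summarize(tabulate(records))
            wins += summary.typeI_adjusted.pct < summary.typeI_unadjusted.pct
        assert wins / n_meta >= 0.95
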