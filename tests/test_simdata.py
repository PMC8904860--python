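"""Synthetic cohort generator: dynamics, determinism, and truth fidelity."""

import math

import numpy as np
import pandas as pd
import pytest

from xenotrial import trial
from xenotrial.simdata import (ARCHETYPES, SimClone, SimConfig,
                               archetype_clones, clone_tree, simulate_case,
                               simulate_cohort, simulate_dose_matrix,
                               simulate_expression, simulate_variant_tables,
                               simulate_volume_series, twice_weekly)

ARCHETYPE_OUTCOME = {
    "sensitive": "sensitive",
    "intrinsic": "intrinsic_resistance",
    "acquired": "acquired_resistance",
    "dtp": "dtp",
    "individual_differences": "individual_differences",
    "unevaluable": "unevaluable",
}


class TestVolumeSeries:
    def test_exponential_limit_without_drug_or_capacity(self):
        clone = SimClone("c0", growth_rate=0.1)
        cfg = SimConfig(v0=100.0, vmax=1e12, measurement_cv=0.0)
        res = simulate_volume_series([clone], "vehicle", [0, 5, 10], cfg)
        assert res["true_total"][-1] == pytest.approx(100.0 * math.e, rel=1e-6)

    def test_fully_sensitive_clone_regresses_completely(self):
        clone = SimClone("c0", growth_rate=0.08, kill_rate=0.5)
        cfg = SimConfig(measurement_cv=0.0)
        res = simulate_volume_series([clone], "treatment", twice_weekly(21), cfg)
        assert res["true_total"][-1] == 0.0  # below extinction threshold
        vols = res["true_total"]
        assert all(b <= a for a, b in zip(vols, vols[1:]))  # monotone decline

    def test_resistant_minor_clone_drives_relapse_and_acquired_call(self):
        cfg = SimConfig(measurement_cv=0.02, seed=0)
        rng = np.random.default_rng(3)
        record, truth, _ = simulate_case("acquired", "A", cfg, rng)
        call = trial.classify_case(record)
        assert call.outcome == "acquired_resistance"
        assert truth.relapse_day is not None and truth.relapse_day <= 45

    def test_empty_clone_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_volume_series([], "vehicle", [0, 7], SimConfig())

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimClone("c0", growth_rate=-0.1)

    def test_series_non_negative_with_noise(self):
        clones = archetype_clones("acquired", "X")
        cfg = SimConfig(measurement_cv=0.2)
        res = simulate_volume_series(clones, "treatment", twice_weekly(90), cfg,
                                     seed=5)
        assert np.all(res["observed"] >= 0)


class TestCohort:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_cases=6, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ca, cb in zip(a.cases, b.cases):
            for sa, sb in zip(ca.series, cb.series):
                assert [m.width for m in sa.measurements] == \
                       [m.width for m in sb.measurements]

    def test_archetype_mix_apportionment(self):
        cfg = SimConfig(n_cases=49, seed=1)
        cohort = simulate_cohort(cfg)
        counts = pd.Series([t.archetype for t in cohort.truth.values()]
                           ).value_counts()
        assert counts["intrinsic"] == 21 and counts["sensitive"] == 9
        assert counts["acquired"] == 8 and counts["dtp"] == 3

    def test_clone_fractions_sum_to_at_most_one(self):
        cfg = SimConfig(n_cases=8, seed=3)
        cohort = simulate_cohort(cfg)
        for t in cohort.truth.values():
            for tp, fracs in t.clone_fractions.items():
                assert sum(fracs.values()) <= 1.0 + 1e-9

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(archetype_mix={"sensitive": 0.5})


class TestVariantTables:
    def test_clonal_het_expected_vaf(self):
        clones = [SimClone("c0", driver_events=(("TP53", "SNV"),))]
        cfg = SimConfig(seq_depth=100000, purity=1.0)
        rng = np.random.default_rng(0)
        tab = simulate_variant_tables(clones, {"pre": {"c0": 1.0}}, cfg, rng,
                                      n_passengers=0)
        assert tab["alt_reads"].iloc[0] / tab["depth"].iloc[0] == \
               pytest.approx(0.5, abs=0.01)

    def test_subclonal_impure_vaf_within_3se(self):
        clones = [SimClone("c0", driver_events=(("X", "SNV"),))]
        depth = 100000
        cfg = SimConfig(seq_depth=depth, purity=0.8)
        rng = np.random.default_rng(1)
        tab = simulate_variant_tables(clones, {"pre": {"c0": 0.26}}, cfg, rng,
                                      n_passengers=0)
        vaf = tab["alt_reads"].iloc[0] / depth
        se = math.sqrt(0.104 * (1 - 0.104) / depth)
        assert abs(vaf - 0.104) <= 3 * se

    def test_mutations_inherited_by_subclones(self):
        clones = [SimClone("c0", driver_events=(("A", "SNV"),)),
                  SimClone("c1", parent_id="c0", birth_ccf=0.3,
                           driver_events=(("B", "SNV"),))]
        cfg = SimConfig(seq_depth=50000, purity=1.0)
        rng = np.random.default_rng(2)
        tab = simulate_variant_tables(
            clones, {"pre": {"c0": 0.5, "c1": 0.3}}, cfg, rng, n_passengers=0)
        by_gene = tab.set_index("gene")
        # trunk mutation A is carried by c0 and its child c1
        assert by_gene.loc["A", "true_ccf"] == pytest.approx(0.8)
        assert by_gene.loc["B", "true_ccf"] == pytest.approx(0.3)

    def test_ccf_outside_unit_interval_rejected(self):
        clones = [SimClone("c0", driver_events=(("A", "SNV"),))]
        with pytest.raises(ValueError, match="CCF"):
            simulate_variant_tables(clones, {"pre": {"c0": 1.4}}, SimConfig(),
                                    np.random.default_rng(0))

    def test_every_driver_appears(self):
        clones = archetype_clones("acquired", "X")
        rng = np.random.default_rng(3)
        tab = simulate_variant_tables(
            clones, {"pre": {c.clone_id: c.birth_ccf for c in clones}},
            SimConfig(), rng)
        genes = set(tab["gene"])
        for c in clones:
            for g, _k in c.driver_events:
                assert g in genes


class TestExpression:
    def test_null_effect_auc_near_half(self):
        labels = {f"R{i}": "resistant" for i in range(8)} | \
                 {f"S{i}": "sensitive" for i in range(7)}
        rng = np.random.default_rng(0)
        expr, truth = simulate_expression(labels, ["M"], 0.0, rng, n_genes=100)
        from xenotrial.biomarkers import auc
        res = [s for s in expr.columns if labels[s] == "resistant"]
        sen = [s for s in expr.columns if labels[s] == "sensitive"]
        aucs = [auc(expr.loc[g, res], expr.loc[g, sen]) for g in expr.index]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression({"a": "resistant", "b": "resistant",
                                 "c": "sensitive", "d": "sensitive"},
                                [], -1.0, np.random.default_rng(0))

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression({"a": "resistant", "c": "sensitive",
                                 "d": "sensitive"}, [], 1.0,
                                np.random.default_rng(0))


class TestDoseMatrix:
    def test_zero_dose_well_is_full_viability(self):
        grid = simulate_dose_matrix((20, 1.0), (30, 1.0),
                                    [0, 1, 2, 4, 8], [0, 1, 2, 4, 8])
        assert grid.iloc[0, 0] == 100.0

    def test_margins_follow_hill_exactly_despite_synergy(self):
        doses = [0, 2, 4, 8, 16, 32]
        add = simulate_dose_matrix((10, 1.0), (10, 1.0), doses, doses)
        syn = simulate_dose_matrix((10, 1.0), (10, 1.0), doses, doses,
                                   interaction="synergy_factor",
                                   synergy_factor=0.3)
        np.testing.assert_allclose(add.iloc[:, 0], syn.iloc[:, 0], rtol=1e-6)
        assert syn.iloc[3, 3] < add.iloc[3, 3]  # interior pulled down

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_matrix((10, 1.0), (10, 1.0), [0, 4, 2], [0, 1, 2])


class TestCloneTreeExport:
    def test_pruned_tree_keeps_ancestors(self):
        clones = archetype_clones("acquired", "X")
        t = clone_tree(clones, "X", "post", present={"X_c1": 0.9, "X_c0": 0.0})
        assert "X_c0" in t.parent  # ancestor of the resistant clone retained
        assert t.parent["X_c1"] == "X_c0"
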