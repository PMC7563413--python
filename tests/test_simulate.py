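import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from navsig import (OmicsSimConfig, SimConfig, load_builtin_sets,
                    simulate_drug_panel, simulate_methylome_cnv_qpcr,
                    simulate_receptor_expression, simulate_sc_counts)


class TestSimulateScCounts:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_cells=150, n_genes=800, phase_set_size=40, seed=7)
        a, ta, _ = simulate_sc_counts(cfg)
        b, tb, _ = simulate_sc_counts(cfg)
        assert (a.counts != b.counts).nnz == 0
        assert a.cells == b.cells and a.genes == b.genes
        np.testing.assert_array_equal(ta.cell_class, tb.cell_class)
        np.testing.assert_array_equal(ta.cell_phase, tb.cell_phase)

    def test_null_effect_is_indistinguishable(self):
        """effect_log2=0: resistance-set expression does not differ between
        planted classes (two-sample t-test non-significant)."""
        for seed in (0, 1, 2):
            cfg = SimConfig(n_cells=400, n_genes=800, phase_set_size=40,
                            effect_log2=0.0, seed=seed)
            counts, truth, sets = simulate_sc_counts(cfg)
            dense = np.asarray(counts.counts.todense(), dtype=float)
            idx = [counts.genes.index(g)
                   for g in sets["navitoclax_resistance"]]
            per_cell = dense[:, idx].mean(axis=1)
            res = per_cell[truth.cell_class == "resistant"]
            oth = per_cell[truth.cell_class == "other"]
            assert st.ttest_ind(res, oth).pvalue > 0.01

    def test_planted_mean_ratio(self):
        """effect_log2=2 at 3000 cells: the resistant/other mean-count
        ratio on resistance-set genes is within 10% of 4."""
        cfg = SimConfig(n_cells=3000, effect_log2=2.0, seed=13)
        counts, truth, sets = simulate_sc_counts(cfg)
        dense = np.asarray(counts.counts.todense(), dtype=float)
        idx = [counts.genes.index(g) for g in sets["navitoclax_resistance"]]
        res = dense[truth.cell_class == "resistant"][:, idx].mean()
        oth = dense[truth.cell_class == "other"][:, idx].mean()
        assert res / oth == pytest.approx(4.0, rel=0.10)

    def test_mito_genes_prefixed(self):
        counts, truth, _ = simulate_sc_counts(
            SimConfig(n_cells=50, n_genes=800, phase_set_size=40, seed=1))
        mito = truth.gene_sets["mitochondrial"]
        assert mito and all(g.startswith("MT-") for g in mito)

    def test_class_proportions(self):
        cfg = SimConfig(n_cells=1000, n_genes=800, phase_set_size=40,
                        fraction_resistant=0.2, fraction_sensitive=0.3,
                        seed=2)
        _, truth, _ = simulate_sc_counts(cfg)
        counts = pd.Series(truth.cell_class).value_counts()
        assert counts["resistant"] == 200
        assert counts["sensitive"] == 300
        assert counts["other"] == 500

    def test_oversized_sets_raise(self):
        with pytest.raises(ValueError, match="gene sets need"):
            SimConfig(n_genes=100)

    def test_overlapping_sets_raise(self):
        cfg = SimConfig(n_cells=20, n_genes=800, phase_set_size=40, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_sc_counts(cfg, resistance_genes=["TGT-0001"],
                               target_genes=["TGT-0001", "TGT-0002"])

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError, match="sum to <= 1"):
            SimConfig(fraction_resistant=0.7, fraction_sensitive=0.6)


class TestSimulateDrugPanel:
    GENES = [f"S{i}" for i in range(10)]

    def test_noiseless_monotone(self):
        panel, truth = simulate_drug_panel({"a": 20, "b": 20}, self.GENES,
                                           beta=2.0, sigma_noise=0.0,
                                           seed=0)
        r = st.spearmanr(truth["true_score"],
                         panel.response["log_ic50"]).statistic
        assert r == pytest.approx(1.0)

    def test_zero_beta_near_null_correlation(self):
        for seed in (0, 1, 2):
            panel, truth = simulate_drug_panel({"a": 50, "b": 50},
                                               self.GENES, beta=0.0,
                                               sigma_noise=0.5, seed=seed)
            r = st.spearmanr(truth["true_score"],
                             panel.response["log_ic50"]).statistic
            assert abs(r) < 0.2

    def test_deterministic(self):
        a, _ = simulate_drug_panel({"a": 10, "b": 10}, self.GENES, seed=5)
        b, _ = simulate_drug_panel({"a": 10, "b": 10}, self.GENES, seed=5)
        pd.testing.assert_frame_equal(a.response, b.response)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_tissue_sizes_respected(self):
        panel, _ = simulate_drug_panel({"a": 7, "b": 12}, self.GENES,
                                       seed=1)
        sizes = panel.response["tissue"].value_counts()
        assert sizes["a"] == 7 and sizes["b"] == 12

    def test_bad_arguments_raise(self):
        with pytest.raises(ValueError, match="2 tissues"):
            simulate_drug_panel({"a": 10}, self.GENES)
        with pytest.raises(ValueError, match="positive"):
            simulate_drug_panel({"a": 10, "b": 0}, self.GENES)
        with pytest.raises(ValueError, match="finite"):
            simulate_drug_panel({"a": 5, "b": 5}, self.GENES,
                                beta=np.inf)


class TestSimulateReceptor:
    def test_weight_one_collapses_to_negative_component(self):
        values, labels = simulate_receptor_expression(
            500, 1.0, 0.0, 4.0, 1.0, 1.0, seed=0)
        assert (labels == 0).all()
        assert abs(values.mean()) < 0.2

    def test_analytic_mixture_mean(self):
        values, _ = simulate_receptor_expression(10000, 0.5, 0.0, 4.0,
                                                 1.0, 1.0, seed=1)
        assert values.mean() == pytest.approx(2.0, abs=0.1)

    def test_same_seed_identical(self):
        a, la = simulate_receptor_expression(100, 0.3, 0, 3, 1, 1, seed=2)
        b, lb = simulate_receptor_expression(100, 0.3, 0, 3, 1, 1, seed=2)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(la, lb)

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_receptor_expression(10, 0.5, 4.0, 0.0, 1, 1)
        with pytest.raises(ValueError):
            simulate_receptor_expression(10, 0.5, 0.0, 4.0, -1, 1)
        with pytest.raises(ValueError):
            simulate_receptor_expression(10, 1.5, 0.0, 4.0, 1, 1)


class TestSimulateOmics:
    def test_zero_cpgs_gives_empty_schema_valid_table(self):
        om = simulate_methylome_cnv_qpcr(OmicsSimConfig(
            n_cpgs=0, n_unmethylated=0, n_fully_methylated=0,
            n_low_coverage=0, seed=0))
        assert om.cpgs.empty
        assert {"chrom", "pos", "frac_s1", "cov_s1"} <= set(om.cpgs.columns)

    def test_deterministic(self):
        a = simulate_methylome_cnv_qpcr(OmicsSimConfig(seed=4))
        b = simulate_methylome_cnv_qpcr(OmicsSimConfig(seed=4))
        pd.testing.assert_frame_equal(a.cpgs, b.cpgs)
        pd.testing.assert_frame_equal(a.cnvs, b.cnvs)
        pd.testing.assert_frame_equal(a.qpcr, b.qpcr)

    def test_schema_round_trip(self, tmp_path):
        om = simulate_methylome_cnv_qpcr(OmicsSimConfig(seed=6))
        for name, df in (("cpgs", om.cpgs), ("cnvs", om.cnvs),
                         ("qpcr", om.qpcr)):
            path = tmp_path / f"{name}.csv"
            df.to_csv(path, index=False)
            back = pd.read_csv(path)
            pd.testing.assert_frame_equal(back, df, check_dtype=False)


class TestBuiltinSets:
    def test_cardinalities_match_study(self):
        sets = load_builtin_sets()
        assert len(sets["navitoclax_targets"]) == 81
        assert len(sets["navitoclax_resistance"]) == 61
        for phase in ("G1/S", "S", "G2", "G2/M", "M/G1"):
            assert len(sets[phase]) == 108

    def test_names_match_simulated_genes(self):
        counts, _, sim_sets = simulate_sc_counts(
            SimConfig(n_cells=20, seed=0))
        builtin = load_builtin_sets()
        assert builtin["navitoclax_resistance"] == \
            sim_sets["navitoclax_resistance"]
        assert builtin["G1/S"] == sim_sets["G1/S"]
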