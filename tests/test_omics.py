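import numpy as np
import pandas as pd
import pytest

from navsig import (delta_correlation, filter_cnvs, filter_cpgs,
                    filter_peaks, link_intervals_to_genes,
                    modality_overlap, promoter_methylation,
                    simulate_methylome_cnv_qpcr)
from navsig.omics import tss
from navsig.simulate import OmicsSimConfig


def cpg_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "frac_s1", "cov_s1",
                                       "frac_s2", "cov_s2"])


class TestFilterCpgs:
    def test_unmethylated_everywhere_removed(self):
        df = cpg_table([("chr1", 10, 0.0, 20, 0.0, 20)])
        assert filter_cpgs(df).empty

    def test_fully_methylated_everywhere_removed(self):
        df = cpg_table([("chr1", 10, 1.0, 20, 1.0, 20)])
        assert filter_cpgs(df).empty

    def test_hand_enumerated_mixed_fixture(self):
        """8 rows: 0 all-zero, 1 all-one, 2 low coverage in one sample,
        3 coverage exactly 10 (kept), 4-7 ordinary survivors."""
        df = cpg_table([
            ("chr1", 1, 0.0, 30, 0.0, 30),
            ("chr1", 2, 1.0, 30, 1.0, 30),
            ("chr1", 3, 0.5, 9, 0.4, 30),
            ("chr1", 4, 0.5, 10, 0.4, 10),
            ("chr1", 5, 0.2, 15, 0.3, 25),
            ("chr1", 6, 0.9, 40, 0.8, 12),
            ("chr1", 7, 1.0, 30, 0.0, 30),   # variable across samples: kept
            ("chr1", 8, 0.5, 30, 0.5, 9),
        ])
        out = filter_cpgs(df)
        assert out["pos"].tolist() == [4, 5, 6, 7]

    def test_any_rule_keeps_partially_covered(self):
        df = cpg_table([("chr1", 3, 0.5, 9, 0.4, 30)])
        assert len(filter_cpgs(df, coverage_rule="any")) == 1


class TestPromoterMethylation:
    def genes(self, start, end, strand):
        return pd.DataFrame(dict(chrom=["chr1"], start=[start], end=[end],
                                 strand=[strand], name=["GENE"]))

    def test_coverage_weighted_average(self):
        cpgs = cpg_table([("chr1", 5100, 0.2, 10, 0.5, 1),
                          ("chr1", 5200, 0.6, 30, 0.5, 1)])
        out = promoter_methylation(cpgs, self.genes(5000, 9000, "+"))
        assert out.loc["GENE", "s1"] == pytest.approx(0.5)

    def test_single_cpg_ignores_coverage(self):
        cpgs = cpg_table([("chr1", 5100, 0.37, 999, 0.5, 10)])
        out = promoter_methylation(cpgs, self.genes(5000, 9000, "+"))
        assert out.loc["GENE", "s1"] == pytest.approx(0.37)

    def test_window_boundary_inclusive(self):
        """TSS-1000 included, TSS-1001 excluded."""
        cpgs = cpg_table([("chr1", 4000, 0.8, 10, 0.8, 10),
                          ("chr1", 3999, 0.2, 10, 0.2, 10)])
        out = promoter_methylation(cpgs, self.genes(5000, 9000, "+"))
        assert out.loc["GENE", "s1"] == pytest.approx(0.8)

    def test_minus_strand_tss_at_end(self):
        """TSS of a '-' gene is end-1; only nearby CpGs count."""
        cpgs = cpg_table([("chr1", 8950, 0.6, 10, 0.6, 10),
                          ("chr1", 5100, 0.1, 10, 0.1, 10)])
        out = promoter_methylation(cpgs, self.genes(5000, 9000, "-"))
        assert out.loc["GENE", "s1"] == pytest.approx(0.6)

    def test_no_cpg_gives_missing(self):
        out = promoter_methylation(cpg_table([]),
                                   self.genes(5000, 9000, "+"))
        assert np.isnan(out.loc["GENE", "s1"])

    def test_coverage_scaling_and_row_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(p), float(f1), int(c1), float(f2), int(c2))
                for p, f1, c1, f2, c2 in zip(
                    rng.integers(4000, 6000, 20),
                    rng.uniform(0, 1, 20), rng.integers(10, 50, 20),
                    rng.uniform(0, 1, 20), rng.integers(10, 50, 20))]
        cpgs = cpg_table(rows)
        genes = self.genes(5000, 9000, "+")
        base = promoter_methylation(cpgs, genes)
        doubled = cpgs.copy()
        doubled[["cov_s1", "cov_s2"]] *= 2
        pd.testing.assert_frame_equal(
            base, promoter_methylation(doubled, genes))
        shuffled = cpgs.sample(frac=1, random_state=1)
        pd.testing.assert_frame_equal(
            base, promoter_methylation(shuffled, genes))


def brute_force_links(intervals, genes, extension):
    pairs = set()
    for j, iv in intervals.iterrows():
        for i, g in genes.iterrows():
            lo = max(g["start"] - extension, 0)
            hi = g["end"] + extension
            if g["chrom"] == iv["chrom"] \
                    and max(iv["start"], lo) < min(iv["end"], hi):
                pairs.add((j, g["name"]))
    return pairs


class TestLinkIntervals:
    def genes3(self):
        return pd.DataFrame(dict(
            chrom=["chr1", "chr1", "chr2"],
            start=[5000, 20000, 100], end=[9000, 30000, 500],
            strand=["+", "-", "+"], name=["A", "B", "C"]))

    def test_peak_inside_gene_body_links(self):
        peaks = pd.DataFrame(dict(chrom=["chr1"], start=[6000],
                                  end=[6500], name=["p"]))
        out = link_intervals_to_genes(peaks, self.genes3())
        assert out["gene"].tolist() == ["A"]

    def test_half_open_boundary(self):
        """Peak ending exactly at start-ext does not link; one base more
        does."""
        peaks = pd.DataFrame(dict(chrom=["chr1", "chr1"],
                                  start=[3000, 3000], end=[4000, 4001],
                                  name=["out", "in"]))
        out = link_intervals_to_genes(peaks, self.genes3(), extension=1000)
        assert out["interval_name"].tolist() == ["in"]

    def test_hand_enumerated_pairs(self):
        """5 peaks / 3 genes enumerated by hand: p0 in A; p1 spans A and
        its extension; p2 between A and B links neither; p3 in B; p4 on
        chr2 in C."""
        peaks = pd.DataFrame(dict(
            chrom=["chr1"] * 4 + ["chr2"],
            start=[6000, 3500, 12000, 29500, 50],
            end=[6200, 5200, 13000, 31500, 200],
            name=[f"p{i}" for i in range(5)]))
        out = link_intervals_to_genes(peaks, self.genes3())
        got = set(zip(out["interval_name"], out["gene"]))
        assert got == {("p0", "A"), ("p1", "A"), ("p3", "B"), ("p4", "C")}

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame(dict(
            chrom=rng.choice(["chr1", "chr2"], 80),
            start=rng.integers(0, 200000, 80)))
        genes["end"] = genes["start"] + rng.integers(500, 5000, 80)
        genes["strand"] = "+"
        genes["name"] = [f"g{i}" for i in range(80)]
        peaks = pd.DataFrame(dict(
            chrom=rng.choice(["chr1", "chr2"], 120),
            start=rng.integers(0, 200000, 120)))
        peaks["end"] = peaks["start"] + rng.integers(100, 3000, 120)
        peaks["name"] = [f"p{i}" for i in range(120)]
        out = link_intervals_to_genes(peaks, genes)
        got = set(zip(out["interval_index"], out["gene"]))
        assert got == brute_force_links(peaks, genes, 1000)

    def test_containment_flag(self):
        peaks = pd.DataFrame(dict(chrom=["chr1"], start=[3500],
                                  end=[10500], name=["p"]))
        assert len(link_intervals_to_genes(peaks, self.genes3())) == 1
        assert link_intervals_to_genes(peaks, self.genes3(),
                                       containment=True).empty


class TestFilterCnvsAndPeaks:
    def test_length_and_q0_boundaries_are_strict(self):
        cnvs = pd.DataFrame(dict(
            chrom=["chr1"] * 4, start=[0, 0, 0, 0],
            end=[1000, 1001, 5000, 5000],
            type=["deletion"] * 4, q0=[0.0, 0.0, 0.15, 0.1499]))
        out = filter_cnvs(cnvs)
        assert out["end"].tolist() == [1001, 5000]
        assert out["q0"].tolist() == [0.0, 0.1499]

    def test_planted_records_removed(self):
        om = simulate_methylome_cnv_qpcr(OmicsSimConfig(seed=9))
        kept = filter_cnvs(om.cnvs)
        assert len(kept) == (~om.cnvs["planted_fails_filter"]).sum()
        assert not kept["planted_fails_filter"].any()

    def test_peak_stats_filter(self):
        stats = pd.DataFrame(dict(fdr=[0.04, 0.06, 0.01, 0.01],
                                  log2fc=[1.5, 2.0, 1.0, -1.2]))
        out = filter_peaks(stats)
        assert out["log2fc"].tolist() == [1.5, -1.2]


class TestModalityOverlap:
    def test_identical_lists(self):
        out = modality_overlap({"a": ["x", "y"], "b": ["x", "y"]})
        assert out.set_index("region")["n"].to_dict() == \
            {"a": 0, "b": 0, "a&b": 2}

    def test_disjoint_lists(self):
        out = modality_overlap({"a": ["x"], "b": ["y"]})
        assert out.set_index("region")["n"].to_dict() == \
            {"a": 1, "b": 1, "a&b": 0}

    def test_three_list_hand_counts(self):
        """Exclusive Venn regions enumerated by hand."""
        out = modality_overlap({
            "rna": ["g1", "g2", "g3", "g4"],
            "meth": ["g3", "g4", "g5"],
            "atac": ["g4", "g5", "g6"]})
        expect = {"rna": 2, "meth": 0, "atac": 1, "rna&meth": 1,
                  "rna&atac": 0, "meth&atac": 1, "rna&meth&atac": 1}
        assert out.set_index("region")["n"].to_dict() == expect


class TestDeltaCorrelation:
    def test_exact_negative_coupling(self):
        d = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        out = delta_correlation(d, -d)
        assert out["r"] == pytest.approx(-1.0)

    def test_noisy_negative_coupling_is_negative(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            de = pd.Series(rng.normal(size=200))
            dm = -0.5 * de + rng.normal(0, 0.3, 200)
            assert delta_correlation(de, dm)["r"] < 0

    def test_significant_subset_sharper_than_all(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        de = pd.Series(rng.normal(size=100), index=genes)
        dm = pd.Series(rng.normal(size=100), index=genes)
        sig = genes[:30]
        dm[sig] = -de[sig]  # only 'significant' genes are coupled
        r_all = delta_correlation(de, dm)["r"]
        r_sig = delta_correlation(de, dm, significant=sig)["r"]
        assert abs(r_sig) > abs(r_all)

    def test_too_few_pairs_raise(self):
        d = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="complete gene pairs"):
            delta_correlation(d, d)


class TestTss:
    def test_strand_aware(self):
        genes = pd.DataFrame(dict(chrom=["chr1", "chr1"],
                                  start=[100, 100], end=[200, 200],
                                  strand=["+", "-"], name=["a", "b"]))
        assert tss(genes).tolist() == [100, 199]

    def test_invalid_strand_raises(self):
        genes = pd.DataFrame(dict(chrom=["chr1"], start=[100], end=[200],
                                  strand=["."], name=["a"]))
        with pytest.raises(ValueError, match="strand"):
            tss(genes)
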