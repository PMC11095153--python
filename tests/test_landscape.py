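import numpy as np
import pandas as pd
import pytest
from conftest import genes_from, peakset

from chromreprog import landscape as ls
from chromreprog.core import SignalTrack


class TestPeakDynamics:
    def test_identical_sets_all_conserved(self):
        p = peakset([("chr1", 10, 50), ("chr1", 100, 200), ("chr2", 5, 25)])
        dyn = ls.classify_peak_dynamics(p, p)
        assert dyn.counts == (3, 0, 0)

    def test_disjoint_sets(self):
        p1 = peakset([("chr1", 10, 50), ("chr1", 100, 200)])
        p2 = peakset([("chr1", 60, 90), ("chr2", 0, 10), ("chr2", 20, 30)])
        dyn = ls.classify_peak_dynamics(p1, p2)
        assert dyn.counts == (0, 2, 3)

    def test_5v5_fixture_hand_swept(self):
        # overlaps by hand: A-B pairs (10,50)x(40,80), (100,150)x(120,130),
        # (300,350)x(340,400); condition-1 only: (500,550), (700,750);
        # condition-2 only: (600,640), (900,950)
        p1 = peakset([("chr1", 10, 50), ("chr1", 100, 150), ("chr1", 300, 350),
                      ("chr1", 500, 550), ("chr1", 700, 750)])
        p2 = peakset([("chr1", 40, 80), ("chr1", 120, 130), ("chr1", 340, 400),
                      ("chr1", 600, 640), ("chr1", 900, 950)])
        dyn = ls.classify_peak_dynamics(p1, p2)
        assert dyn.counts == (3, 2, 2)

    def test_partition_and_condition_swap(self):
        rng = np.random.default_rng(17)
        def random_peaks():
            starts = np.sort(rng.choice(10_000, size=30, replace=False)) * 10
            return peakset([("chr1", int(s), int(s + rng.integers(20, 200)))
                            for s in starts])
        p1, p2 = random_peaks(), random_peaks()
        d12 = ls.classify_peak_dynamics(p1, p2)
        d21 = ls.classify_peak_dynamics(p2, p1)
        c, l, g = d12.counts
        assert c + l == len(p1)           # categories partition input 1
        assert d21.counts[1] == g         # lost <-> gained swap exactly
        assert d21.counts[2] == l

    def test_min_overlap_threshold(self):
        p1 = peakset([("chr1", 0, 100)])
        p2 = peakset([("chr1", 95, 200)])     # 5 bp overlap
        assert ls.classify_peak_dynamics(p1, p2, min_overlap_bp=1).counts[0] == 1
        assert ls.classify_peak_dynamics(p1, p2, min_overlap_bp=10).counts[0] == 0


class TestAnnotateRegions:
    @pytest.fixture()
    def toy_annotation(self):
        genes = genes_from([("gA", "chr1", "+", 10_000, 10_000, 20_000),
                            ("gB", "chr2", "+", 5_000, 5_000, 15_000)])
        exons = peakset([("chr1", 13_000, 14_000), ("chr1", 16_000, 17_000),
                         ("chr2", 8_000, 9_000)])
        return genes, exons

    def test_hand_annotated_fixture(self, toy_annotation):
        genes, exons = toy_annotation
        peaks = peakset([
            ("chr1", 8_000, 9_000),       # promoter (window 7500-12500)
            ("chr1", 11_000, 12_000),     # promoter
            ("chr2", 3_000, 4_000),       # promoter (window 2500-7500)
            ("chr1", 13_200, 13_800),     # exon
            ("chr2", 8_100, 8_900),       # exon
            ("chr1", 18_000, 19_000),     # intron (body, not exon)
            ("chr1", 30_000, 31_000),     # distal
            ("chr1", 25_000, 26_000),     # distal
            ("chr2", 20_000, 21_000),     # distal
            ("chr3", 100, 1_000),         # distal (gene-free chromosome)
        ])
        _, counts = ls.annotate_regions(peaks, genes, exons=exons)
        assert counts == {"promoter": 3, "exon": 2, "intron": 1, "distal": 4}

    def test_promoter_precedence_over_exon(self, toy_annotation):
        genes, _ = toy_annotation
        exons = peakset([("chr1", 9_000, 12_000)])  # overlaps promoter window
        peaks = peakset([("chr1", 10_500, 11_500)])
        cats, _ = ls.annotate_regions(peaks, genes, exons=exons)
        assert cats.iloc[0] == "promoter"

    def test_gene_free_chromosome_is_distal(self, toy_annotation):
        genes, exons = toy_annotation
        peaks = peakset([("chrZ", 0, 500)])
        _, counts = ls.annotate_regions(peaks, genes, exons=exons)
        assert counts["distal"] == 1


class TestPromoterState:
    def test_truth_table(self):
        genes = genes_from([("g1", "chr1", "+", 10_000),
                            ("g2", "chr1", "+", 50_000),
                            ("g3", "chr1", "+", 90_000),
                            ("g4", "chr1", "+", 130_000)])
        k4 = peakset([("chr1", 9_000, 11_000), ("chr1", 49_000, 51_000)])
        k27 = peakset([("chr1", 9_500, 10_500), ("chr1", 89_000, 91_000)])
        st = ls.promoter_state(k4, k27, genes)
        assert st["g1"] == "bivalent"
        assert st["g2"] == "K4_only"
        assert st["g3"] == "K27_only"
        assert st["g4"] == "none"

    def test_window_is_half_open(self):
        genes = genes_from([("g1", "chr1", "+", 10_000)])
        # promoter window [7500, 12500): a peak starting at 12500 misses
        assert ls.promoter_state(
            peakset([("chr1", 12_500, 13_000)]), peakset([("chr1", 1, 2)]),
            genes)["g1"] == "none"
        assert ls.promoter_state(
            peakset([("chr1", 12_499, 13_000)]), peakset([("chr1", 1, 2)]),
            genes)["g1"] == "K4_only"


class TestBivalentTransitions:
    def test_no_significant_genes_empty_table(self):
        states = pd.Series({"g1": "bivalent"})
        diff = pd.DataFrame({"log2fc": [2.0], "significant": [False]},
                            index=["g1"])
        table = ls.bivalent_transition_table(states, states, diff)
        assert table.to_numpy().sum() == 0

    def test_constructed_56_gene_fixture(self):
        # 13 up (4 lose the repressive mark), 43 down (2 lose the active mark)
        genes = [f"g{i}" for i in range(56)]
        states1 = pd.Series("bivalent", index=genes)
        s2 = {}
        lfc = {}
        for i, g in enumerate(genes):
            if i < 13:
                lfc[g] = 1.0
                s2[g] = "K4_only" if i < 4 else "bivalent"
            else:
                lfc[g] = -1.0
                s2[g] = "K27_only" if i < 15 else "bivalent"
        diff = pd.DataFrame({"log2fc": pd.Series(lfc),
                             "significant": True})
        table = ls.bivalent_transition_table(states1, pd.Series(s2), diff)
        assert table.loc["up", "lost_K27"] == 4
        assert table.loc["up", "stable"] == 9
        assert table.loc["down", "lost_K4"] == 2
        assert table.loc["down", "stable"] == 41
        assert table.to_numpy().sum() == 56

    def test_non_bivalent_gene_excluded(self):
        states1 = pd.Series({"g1": "K4_only"})
        states2 = pd.Series({"g1": "none"})
        diff = pd.DataFrame({"log2fc": [1.0], "significant": [True]},
                            index=["g1"])
        table = ls.bivalent_transition_table(states1, states2, diff)
        assert table.to_numpy().sum() == 0


class TestPromoterSignal:
    def test_constant_track(self):
        genes = genes_from([("g1", "chr1", "+", 50_000)])
        track = SignalTrack(values={"chr1": np.full(200, 3.0)}, bin_size=500)
        sig = ls.promoter_signal(track, genes)
        assert sig["g1"] == pytest.approx(3.0)

    def test_length_weighted_half_window(self):
        # window [47500, 52500); bins below 50000 at 0, above at 4
        genes = genes_from([("g1", "chr1", "+", 50_000)])
        vals = np.zeros(200)
        vals[100:] = 4.0
        track = SignalTrack(values={"chr1": vals}, bin_size=500)
        assert ls.promoter_signal(track, genes)["g1"] == pytest.approx(2.0)

    def test_clipped_at_chromosome_start(self):
        genes = genes_from([("g1", "chr1", "+", 500)])
        track = SignalTrack(values={"chr1": np.full(100, 5.0)}, bin_size=500)
        assert ls.promoter_signal(track, genes)["g1"] == pytest.approx(5.0)


class TestCorrelation:
    def test_perfect_positive(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        r, p, n = ls.modification_expression_correlation(2 * x, x)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_perfect_negative(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        r, _, _ = ls.modification_expression_correlation(-x, x)
        assert r == pytest.approx(-1.0)

    def test_hand_covariance(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        y = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0})
        r, _, _ = ls.modification_expression_correlation(x, y)
        assert r == pytest.approx(0.5)

    def test_too_few_genes_errors(self):
        x = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            ls.modification_expression_correlation(x, x)


class TestEnhancers:
    def test_all_promoter_peaks_gives_empty_set(self):
        genes = genes_from([("g1", "chr1", "+", 10_000)])
        k27ac = peakset([("chr1", 9_000, 11_000), ("chr1", 8_000, 8_500)])
        assert len(ls.define_enhancers(k27ac, genes)) == 0

    def test_gene_free_chromosome_keeps_all(self):
        genes = genes_from([("g1", "chr1", "+", 10_000)])
        k27ac = peakset([("chr2", 0, 1_000), ("chr2", 5_000, 6_000)])
        assert len(ls.define_enhancers(k27ac, genes)) == 2

    def test_constructed_overlap_fixture(self):
        genes = genes_from([("g1", "chr1", "+", 10_000),
                            ("g2", "chr1", "+", 100_000)])
        inside = [("chr1", 8_000, 9_000), ("chr1", 11_000, 12_000),
                  ("chr1", 98_000, 99_000), ("chr1", 102_000, 102_400)]
        outside = [("chr1", 20_000, 21_000), ("chr1", 30_000, 31_000),
                   ("chr1", 40_000, 41_000), ("chr1", 50_000, 51_000),
                   ("chr1", 60_000, 61_000), ("chr1", 70_000, 71_000)]
        enh = ls.define_enhancers(peakset(inside + outside), genes)
        assert len(enh) == 6

    def test_no_promoter_overlap_invariant(self, small_genes, marks_dataset):
        k27ac = marks_dataset["marks"][("H3K27ac", "cond1")][0]
        enh = ls.define_enhancers(k27ac, small_genes)
        prom = small_genes.promoter_windows()
        for e in enh.peaks.df.itertuples(index=False):
            w = prom[prom["chrom"] == e.chrom]
            overlap = ((w["start"] < e.end) & (e.start < w["end"])).any()
            assert not overlap


class TestSignalAtRegions:
    def test_constant_track_flat_profile(self):
        track = SignalTrack(values={"chr1": np.full(100, 2.5)}, bin_size=100)
        prof = ls.signal_at_regions(track, [("chr1", 5_000)], flank_bins=3)
        np.testing.assert_allclose(prof, 2.5)

    def test_delta_peaks_at_center(self):
        vals = np.zeros(100)
        vals[50] = 7.0
        track = SignalTrack(values={"chr1": vals}, bin_size=100)
        prof = ls.signal_at_regions(track, [("chr1", 5_050)], flank_bins=2)
        assert prof[2] == 7.0
        assert prof[0] == prof[4] == 0.0

    def test_mean_across_regions(self):
        vals = np.zeros(100)
        vals[20], vals[80] = 2.0, 4.0
        track = SignalTrack(values={"chr1": vals}, bin_size=100)
        prof = ls.signal_at_regions(track, [("chr1", 2_000), ("chr1", 8_000)],
                                    flank_bins=1)
        assert prof[1] == pytest.approx(3.0)
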