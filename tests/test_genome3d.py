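import numpy as np
import pytest

from chromreprog import genome3d as g3
from chromreprog import synthetic as syn
from chromreprog.core import ContactMap


def symmetric_random(n, seed, low=0, high=10):
    rng = np.random.default_rng(seed)
    m = rng.integers(low, high, size=(n, n)).astype(float)
    return (m + m.T) / 2


class TestExpectedAndOE:
    def test_constant_matrix(self):
        m = np.full((6, 6), 3.0)
        np.testing.assert_allclose(g3.expected_by_distance(m), 3.0)
        np.testing.assert_allclose(g3.oe_matrix(m), 1.0)

    def test_diagonal_only(self):
        m = np.diag([5.0] * 6)
        exp = g3.expected_by_distance(m)
        assert exp[0] == 5.0
        assert np.all(exp[1:] == 0.0)

    def test_matches_bruteforce_loop(self):
        m = symmetric_random(20, seed=1)
        exp = g3.expected_by_distance(m)
        for d in range(20):
            vals = [m[i, i + d] for i in range(20 - d)]
            assert exp[d] == pytest.approx(np.mean(vals))

    def test_doubled_entry_oe_algebra(self):
        # constant 4-bin matrix, one off-diagonal entry doubled: on that
        # diagonal (length 3) the mean is 4c/3, so O/E there is 2c/(4c/3) = 1.5
        m = np.full((4, 4), 2.0)
        m[0, 1] = m[1, 0] = 4.0
        oe = g3.oe_matrix(m)
        assert oe[0, 1] == pytest.approx(2 * 3 / (3 + 1))

    def test_zero_expected_masked(self):
        m = np.diag([5.0] * 6)
        oe = g3.oe_matrix(m)
        assert np.isnan(oe[0, 3])
        assert oe[2, 2] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def planted():
    g = syn.make_genome(1, 10_000_000, 25_000, seed=1)
    labels = {"chr1": syn.checkerboard_labels(400, 10)}
    maps, _ = syn.simulate_contacts(g, {"c": labels}, delta=1.0,
                                    total_reads=5e6, seed=2)
    return g, labels["chr1"], maps["c"].cis["chr1"]


class TestCompartmentPC1:

    def test_planted_checkerboard_sign_agreement(self, planted):
        g, labels, cis = planted
        pc1 = g3.compartment_pc1(cis, g.gc["chr1"])
        agreement = np.mean(np.sign(pc1) == labels)
        assert agreement >= 0.95

    def test_orientation_fix_is_idempotent(self, planted):
        g, _, cis = planted
        pc1 = g3.compartment_pc1(cis, g.gc["chr1"])
        # orientation anchored to GC: flipping GC flips the track
        pc1_neg = g3.compartment_pc1(cis, 1.0 - g.gc["chr1"])
        np.testing.assert_allclose(pc1, -pc1_neg, atol=1e-9)

    def test_no_signal_raises(self):
        g = syn.make_genome(1, 10_000_000, 25_000, seed=3)
        labels = {"chr1": syn.checkerboard_labels(400, 10)}
        maps, _ = syn.simulate_contacts(g, {"c": labels}, delta=0.0,
                                        total_reads=5e6, seed=4)
        with pytest.raises(ValueError, match="no compartment signal"):
            g3.compartment_pc1(maps["c"].cis["chr1"], g.gc["chr1"])

    def test_too_few_bins_raises(self):
        m = symmetric_random(30, seed=5)
        with pytest.raises(ValueError):
            g3.compartment_pc1(m, np.full(30, 0.5), min_unmasked=50)


class TestChangeClassifier:
    @pytest.mark.parametrize("c1,c2,expected", [
        (0.3, 0.6, "A_to_strongerA"),
        (-0.3, 0.1, "B_to_A"),
        (-0.5, -0.25, "B_to_weakerB"),
        (-0.3, -0.6, "B_to_strongerB"),
        (0.1, -0.1, "A_to_B"),
        (0.5, 0.25, "A_to_weakerA"),
        (0.1, 0.15, "stable"),
        # both A_to_B and A_to_weakerA match; listed order wins
        (0.3, -0.3, "A_to_B"),
        # both A_to_strongerA and B_to_A match; listed order wins
        (-0.3, 0.3, "B_to_A"),
    ])
    def test_rules_and_precedence(self, c1, c2, expected):
        out = g3.classify_compartment_change(np.array([c1]), np.array([c2]))
        assert out[0] == expected

    def test_masked_bins_unlabelled(self):
        out = g3.classify_compartment_change(np.array([np.nan, 0.3]),
                                             np.array([0.5, 0.6]))
        assert out[0] == ""
        assert out[1] == "A_to_strongerA"

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            g3.classify_compartment_change(np.zeros(3), np.zeros(4))

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        c1 = rng.uniform(-1, 1, 500)
        c2 = rng.uniform(-1, 1, 500)
        labels = g3.classify_compartment_change(c1, c2)
        fr = g3.change_fractions(labels)
        assert fr.sum() == pytest.approx(1.0)


class TestSaddle:
    def test_homogeneous_oe_all_ones(self):
        oe = {"chr1": np.ones((200, 200))}
        rng = np.random.default_rng(7)
        pc1 = g3.CompartmentTrack(values={"chr1": rng.normal(0, 1, 200)},
                                  bin_size=25_000)
        sad = g3.saddle(oe, pc1, n_bins=20)
        assert np.nanmax(np.abs(sad.matrix - 1.0)) < 1e-12
        assert sad.strength == pytest.approx(1.0)

    def test_bin_permutation_invariance(self):
        rng = np.random.default_rng(8)
        oe_m = np.exp(rng.normal(0, 0.3, (100, 100)))
        oe_m = (oe_m + oe_m.T) / 2
        v = rng.normal(0, 1, 100)
        track = g3.CompartmentTrack(values={"chr1": v}, bin_size=25_000)
        sad1 = g3.saddle({"chr1": oe_m}, track, n_bins=10)
        perm = rng.permutation(100)
        track_p = g3.CompartmentTrack(values={"chr1": v[perm]}, bin_size=25_000)
        sad2 = g3.saddle({"chr1": oe_m[np.ix_(perm, perm)]}, track_p, n_bins=10)
        np.testing.assert_allclose(sad1.matrix, sad2.matrix, atol=1e-12)

    def test_too_few_bins_suggests_smaller(self):
        oe = {"chr1": np.ones((10, 10))}
        track = g3.CompartmentTrack(values={"chr1": np.arange(10.0)},
                                    bin_size=25_000)
        with pytest.raises(ValueError, match="n_bins"):
            g3.saddle(oe, track, n_bins=50)


class TestPsCurve:
    def make_map(self, seed=9, n=300, reads=2e5):
        g = syn.make_genome(1, n * 25_000, 25_000, seed=seed)
        labels = {"chr1": syn.checkerboard_labels(n, 10)}
        maps, _ = syn.simulate_contacts(g, {"c": labels}, total_reads=reads,
                                        seed=seed)
        return maps["c"]

    def test_global_scale_invariance(self):
        cmap = self.make_map()
        c1 = g3.ps_curve(cmap)
        c2 = g3.ps_curve(cmap.scaled(3.0))
        np.testing.assert_allclose(c1.frequency, c2.frequency, rtol=1e-12)
        ratio, crossings = g3.ps_log2fc(c1, c2)
        np.testing.assert_allclose(ratio[~np.isnan(ratio)], 0.0, atol=1e-12)
        assert crossings == []

    def test_single_distance_matrix(self):
        n = 100
        m = np.zeros((n, n))
        for i in range(n - 5):
            m[i, i + 5] = m[i + 5, i] = 2.0
        cmap = ContactMap(bin_size=25_000, cis={"chr1": m})
        curve = g3.ps_curve(cmap)
        assert np.sum(curve.frequency > 0) == 1

    def test_constructed_single_crossing(self):
        edges = np.geomspace(25_000, 25_000_000, 16)
        centers = np.sqrt(edges[:-1] * edges[1:])
        f1 = np.full(len(centers), 1e-6)
        f2 = np.where(centers < 1_500_000, 0.5e-6, 2e-6)
        # sign change occurs between the last bin below 1 Mb and the first
        # above 2 Mb in this grid; plant it inside (1, 2) Mb
        c1 = g3.PsCurve(edges=edges, frequency=f1)
        c2 = g3.PsCurve(edges=edges, frequency=f2)
        _, crossings = g3.ps_log2fc(c1, c2)
        assert len(crossings) == 1
        assert 1_000_000 < crossings[0] < 2_000_000

    def test_planted_decay_exponent_recovered(self):
        g = syn.make_genome(1, 10_000_000, 25_000, seed=10)
        labels = {"chr1": syn.checkerboard_labels(400, 10)}
        maps, _ = syn.simulate_contacts(g, {"c": labels}, decay_exponent=-1.0,
                                        total_reads=5e6, seed=10)
        slope = g3.ps_slope(g3.ps_curve(maps["c"]))
        assert abs(slope - (-1.0)) <= 0.1

    def test_disjoint_support_errors(self):
        edges = np.geomspace(25_000, 2_500_000, 6)
        f1 = np.array([1e-6, 1e-6, 0, 0, 0])
        f2 = np.array([0, 0, 0, 1e-6, 1e-6])
        with pytest.raises(ValueError, match="disjoint"):
            g3.ps_log2fc(g3.PsCurve(edges=edges, frequency=f1),
                         g3.PsCurve(edges=edges, frequency=f2))


class TestInteractionFoldChanges:
    def make_pair(self, seed=11):
        g = syn.make_genome(2, 3_000_000, 25_000, seed=seed)
        labels = {c: syn.checkerboard_labels(120, 10) for c in g.chrom_names}
        maps, _ = syn.simulate_contacts(g, {"a": labels, "b": labels},
                                        total_reads=4e5, seed=seed)
        return maps["a"], maps["b"]

    def test_identical_maps_zero(self):
        m, _ = self.make_pair()
        cis_fc, trans_fc = g3.interaction_fold_changes(m, m)
        np.testing.assert_allclose(cis_fc.to_numpy(), 0.0, atol=1e-12)
        vals = trans_fc.to_numpy()
        np.testing.assert_allclose(vals[~np.isnan(vals)], 0.0, atol=1e-12)

    def test_global_scaling_zero(self):
        m, _ = self.make_pair()
        cis_fc, _ = g3.interaction_fold_changes(m, m.scaled(3.0))
        np.testing.assert_allclose(cis_fc.to_numpy(), 0.0, atol=1e-12)

    def test_chr1_doubling_sign_pattern(self):
        m, _ = self.make_pair()
        cis2 = {c: (v * 2 if c == "chr1" else v.copy())
                for c, v in m.cis.items()}
        m2 = ContactMap(bin_size=m.bin_size, cis=cis2,
                        trans={k: v.copy() for k, v in m.trans.items()})
        cis_fc, trans_fc = g3.interaction_fold_changes(m, m2)
        assert cis_fc["chr1"] > 0
        assert cis_fc["chr2"] < 0                       # renormalization
        assert trans_fc.loc["chr1", "chr2"] < 0


class TestTopTransRegions:
    def make_maps(self, fc_block=None, seed=12):
        g = syn.make_genome(2, 4_000_000, 25_000, seed=seed)
        n = 160
        rng = np.random.default_rng(seed)
        cis = {c: np.eye(n) * 100 for c in g.chrom_names}
        t1 = rng.poisson(5.0, size=(n, n)).astype(float)
        t2 = rng.poisson(5.0, size=(n, n)).astype(float)
        if fc_block:
            (alo, ahi), (blo, bhi) = fc_block
            t2[alo:ahi, blo:bhi] *= 6.0
        m1 = ContactMap(bin_size=25_000, cis=cis,
                        trans={("chr1", "chr2"): t1})
        m2 = ContactMap(bin_size=25_000,
                        cis={c: v.copy() for c, v in cis.items()},
                        trans={("chr1", "chr2"): t2})
        return m1, m2

    def test_fraction_one_returns_all(self):
        m1, m2 = self.make_maps()
        out = g3.top_trans_regions(m1, m2, ("chr1", "chr2"), fraction=1.0,
                                   coarse_bin=500_000)
        assert out["n_pairs"].sum() == 64          # 8x8 coarse grid

    def test_planted_block_recovered(self):
        m1, m2 = self.make_maps(fc_block=((40, 80), (80, 120)))
        out = g3.top_trans_regions(m1, m2, ("chr1", "chr2"), fraction=0.05,
                                   coarse_bin=500_000)
        top = out.iloc[0]
        # planted block spans bins 40-80 x 80-120 (1-2 Mb x 2-3 Mb)
        assert top.startA < 2_000_000 and top.endA > 1_000_000
        assert top.startB < 3_000_000 and top.endB > 2_000_000

    def test_uniform_fc_selects_stated_fraction(self):
        m1, _ = self.make_maps()
        out = g3.top_trans_regions(m1, m1, ("chr1", "chr2"), fraction=0.25,
                                   coarse_bin=500_000)
        assert out["n_pairs"].sum() == 16          # ceil(0.25 * 64)


class TestInsulation:
    def test_uniform_matrix_all_zero(self):
        m = np.full((60, 60), 4.0)
        s = g3.insulation_scores(m, window_bins=10)
        valid = s[~np.isnan(s)]
        np.testing.assert_allclose(valid, 0.0, atol=1e-12)

    def test_matches_nested_loop_oracle(self):
        m = symmetric_random(30, seed=13, low=1, high=20)
        w = 5
        s = g3.insulation_scores(m, window_bins=w)
        # independent nested-loop oracle
        diamonds = np.full(30, np.nan)
        for i in range(w, 30 - w):
            vals = []
            for a in range(i - w, i):
                for b in range(i + 1, i + 1 + w):
                    vals.append(m[a, b])
            diamonds[i] = np.mean(vals)
        ref = np.log2(diamonds / np.nanmean(diamonds))
        np.testing.assert_allclose(s[~np.isnan(s)], ref[~np.isnan(ref)],
                                   atol=1e-10)

    def test_two_block_junction_is_global_minimum(self):
        n = 100
        m = np.ones((n, n))
        m[:50, :50] = 10.0
        m[50:, 50:] = 10.0
        s = g3.insulation_scores(m, window_bins=10)
        argmin = np.nanargmin(s)
        assert abs(argmin - 50) <= 1           # plateau tie at the junction

    def test_three_block_boundaries_and_domains(self):
        n = 150
        m = np.ones((n, n))
        for lo in (0, 50, 100):
            m[lo:lo + 50, lo:lo + 50] = 10.0
        cmap = ContactMap(bin_size=25_000, cis={"chr1": m})
        track = g3.insulation(cmap, window_bins=10)
        boundaries, domains, sizes = g3.boundaries_and_domains(
            track, prominence=0.1, min_sep=3)
        assert len(boundaries["chr1"]) == 2
        assert all(abs(b - j) <= 1 for b, j in zip(boundaries["chr1"], (50, 100)))
        assert len(domains["chr1"]) == 3
        assert len(sizes) == 3

    def test_merging_blocks_removes_boundary(self):
        n = 150
        m = np.ones((n, n))
        m[:100, :100] = 10.0               # first two blocks merged
        m[100:, 100:] = 10.0
        cmap = ContactMap(bin_size=25_000, cis={"chr1": m})
        boundaries, domains, _ = g3.boundaries_and_domains(
            g3.insulation(cmap, window_bins=10), prominence=0.1)
        assert len(boundaries["chr1"]) == 1

    def test_flat_track_one_domain(self):
        cmap = ContactMap(bin_size=25_000, cis={"chr1": np.full((80, 80), 2.0)})
        boundaries, domains, _ = g3.boundaries_and_domains(
            g3.insulation(cmap, window_bins=10))
        assert boundaries["chr1"] == []
        assert len(domains["chr1"]) == 1


class TestBoundaryComparison:
    def test_identical_tracks_zero_delta(self):
        s = {"chr1": np.array([np.nan, -0.5, 0.1, -0.6, 0.2])}
        t = g3.InsulationTrack(scores=s, window_bins=1)
        table, summary = g3.compare_boundary_insulation(
            t, t, {"chr1": [1, 3]})
        np.testing.assert_allclose(table["delta"], 0.0)

    def test_constant_shift(self):
        s1 = {"chr1": np.linspace(-1, 0, 10)}
        s2 = {"chr1": np.linspace(-1, 0, 10) + 0.5}
        t1 = g3.InsulationTrack(scores=s1, window_bins=1)
        t2 = g3.InsulationTrack(scores=s2, window_bins=1)
        table, summary = g3.compare_boundary_insulation(t1, t2,
                                                        {"chr1": [2, 5, 8]})
        np.testing.assert_allclose(table["delta"], 0.5)
        assert summary["mean_delta"] == pytest.approx(0.5)

    def test_constructed_mean_delta(self):
        s1 = {"chr1": np.zeros(10)}
        s2v = np.zeros(10)
        s2v[[2, 5, 8]] = [0.2, -0.1, 0.3]
        t1 = g3.InsulationTrack(scores=s1, window_bins=1)
        t2 = g3.InsulationTrack(scores={"chr1": s2v}, window_bins=1)
        _, summary = g3.compare_boundary_insulation(t1, t2, {"chr1": [2, 5, 8]})
        assert summary["mean_delta"] == pytest.approx(0.13333, abs=1e-4)

    def test_empty_union_errors(self):
        t = g3.InsulationTrack(scores={"chr1": np.zeros(5)}, window_bins=1)
        with pytest.raises(ValueError, match="empty"):
            g3.compare_boundary_insulation(t, t, {"chr1": []})

    def test_merge_boundaries_collapses_within_tolerance(self):
        merged = g3.merge_boundaries({"chr1": [10, 30]}, {"chr1": [11, 50]})
        assert merged["chr1"] == [10, 30, 50]


class TestSignalByCategory:
    def test_all_zero_lfc(self):
        labels = np.array(["stable", "B_to_A", "stable"], dtype=object)
        out = g3.signal_change_by_category(labels, np.zeros(3))
        assert out.loc["stable", "median"] == 0.0
        assert out.loc["B_to_A", "median"] == 0.0

    def test_planted_category_shift(self):
        rng = np.random.default_rng(14)
        labels = np.array(rng.choice(["B_to_A", "stable"], size=200),
                          dtype=object)
        lfc = np.where(labels == "B_to_A", 1.0, 0.0)
        out = g3.signal_change_by_category(labels, lfc)
        assert out.loc["B_to_A", "median"] == 1.0
        assert out.loc["stable", "median"] == 0.0

    def test_empty_category_reported(self):
        labels = np.array(["stable"] * 5, dtype=object)
        out = g3.signal_change_by_category(labels, np.ones(5))
        assert out.loc["A_to_B", "n"] == 0
        assert np.isnan(out.loc["A_to_B", "median"])

    def test_nan_coverage_excluded_and_counted(self):
        labels = np.array(["stable"] * 4, dtype=object)
        lfc = np.array([1.0, np.nan, 3.0, np.nan])
        out = g3.signal_change_by_category(labels, lfc)
        assert out.loc["stable", "n"] == 2
        assert out.loc["stable", "n_excluded"] == 2
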