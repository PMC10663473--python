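import numpy as np
import pytest
from scipy.stats import kendalltau

import rilforge as rf
from rilforge.genotype_core import GenotypeCall as GC
from rilforge.threadmapper import cluster_linkage_groups, order_along_curve, project


def _abs_tau(order, truth_order):
    rank = {m: i for i, m in enumerate(truth_order)}
    return abs(kendalltau([rank[m] for m in order], range(len(order))).statistic)


class TestProject:
    def test_identical_markers_get_identical_coordinates(self, f6_population):
        g = f6_population.genotypes
        dup = rf.GenotypeMatrix(
            g.markers[:20] + ["dup"], g.lines,
            np.vstack([g.calls[:20], g.calls[19:20]]),
        )
        proj = project(rf.encode_signed(dup))
        assert np.allclose(proj.coords[19], proj.coords[20])

    def test_mirror_markers_are_antipodal(self, f6_population):
        """In a matrix balanced with each marker's A<->B mirror, the mirror
        pair projects to exactly opposite coordinates."""
        g = f6_population.genotypes
        flipped = g.calls[:20].copy()
        a, b = flipped == GC.A, flipped == GC.B
        flipped[a], flipped[b] = GC.B, GC.A
        dup = rf.GenotypeMatrix(
            g.markers[:20] + [m + "_mirror" for m in g.markers[:20]], g.lines,
            np.vstack([g.calls[:20], flipped]),
        )
        proj = project(rf.encode_signed(dup))
        assert np.allclose(proj.coords[:20], -proj.coords[20:], atol=1e-8)

    def test_k_exceeding_rank_rejected(self):
        g = rf.GenotypeMatrix(["m1", "m2", "m3"], ["a", "b", "c"],
                              np.full((3, 3), GC.A, dtype=np.int8))
        with pytest.raises(ValueError, match="rank"):
            project(rf.encode_signed(g), k=3)

    def test_linkage_groups_separate_in_projection(self, seven_lg_population):
        proj = project(rf.encode_signed(seven_lg_population.genotypes))
        truth = {m: lg for lg, ms in seven_lg_population.truth_order.items() for m in ms}
        labels = np.array([truth[m] for m in proj.markers])
        # silhouette-style check: mean within-LG distance < mean cross-LG distance
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(proj.coords))
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        assert D[same].mean() < 0.5 * D[~same & (D > 0)].mean()


class TestClusterLinkageGroups:
    def test_block_structure_recovered(self, seven_lg_population):
        pr = rf.pairwise_R(seven_lg_population.genotypes)
        groups = cluster_linkage_groups(pr)
        truth = {m: lg for lg, ms in seven_lg_population.truth_order.items() for m in ms}
        assert groups.nunique() == 7
        # adjusted Rand index 1.0 <=> each recovered group maps to one truth LG
        for lg in groups.unique():
            members = groups.index[groups == lg]
            assert len({truth[m] for m in members}) == 1

    def test_threshold_bounds_enforced(self, seven_lg_population):
        pr = rf.pairwise_R(seven_lg_population.genotypes)
        for bad in (0.0, 0.5, 0.7):
            with pytest.raises(ValueError):
                cluster_linkage_groups(pr, link_threshold=bad)

    def test_labels_ordered_largest_first(self, seven_lg_population):
        g = seven_lg_population.genotypes.subset_markers(
            seven_lg_population.genotypes.markers[: 29 + 10]  # LG1 whole, LG2 partial
        )
        groups = cluster_linkage_groups(rf.pairwise_R(g))
        sizes = groups.value_counts()
        assert sizes.loc["LG1"] == 29 and sizes.loc["LG2"] == 10


class TestOrderAlongCurve:
    def test_middle_of_three_ordered_between_ends(self):
        genome = rf.uniform_genome(1, 3, 40.0)
        pop = rf.simulate_ssd(rf.SimConfig(genome=genome, n_lines=500, final_generation=6, seed=21))
        proj = project(rf.encode_signed(pop.genotypes), k=2)
        res = order_along_curve(pop.genotypes.markers, proj, rf.pairwise_R(pop.genotypes))
        assert res.order[1] == pop.genotypes.markers[1]

    def test_off_curve_distance_flags_low_quality_marker(self, f6_population):
        """A marker with heavy call error drifts off the thread; clean
        interior markers hug it."""
        g = f6_population.genotypes
        rng = np.random.default_rng(12)
        bad = g.calls[30].copy()
        flip = rng.uniform(size=bad.size) < 0.25
        bad[flip & (bad == GC.A)] = GC.B
        g2 = rf.GenotypeMatrix(list(g.markers), list(g.lines),
                               np.vstack([g.calls[:30], bad[None], g.calls[31:]]))
        proj = project(rf.encode_signed(g2))
        res = order_along_curve(g2.markers, proj, rf.pairwise_R(g2))
        off = res.off_curve_distance
        others = np.median([off[m] for m in g2.markers if m != g.markers[30]])
        assert off[g.markers[30]] > 3 * others

    def test_duplicate_markers_end_up_adjacent(self, f6_population):
        g = f6_population.genotypes
        dup = rf.GenotypeMatrix(g.markers + ["dup"], g.lines,
                                np.vstack([g.calls, g.calls[30:31]]))
        proj = project(rf.encode_signed(dup))
        pr = rf.pairwise_R(dup)
        res = order_along_curve(dup.markers, proj, pr)
        i, j = res.order.index("dup"), res.order.index(g.markers[30])
        assert abs(i - j) == 1

    def test_exact_recovery_noiseless(self, f6_population):
        res = rf.threadmap(f6_population.genotypes)
        truth = f6_population.truth_order["LG1"]
        assert len(res.orders) == 1
        assert _abs_tau(next(iter(res.orders.values())).order, truth) == 1.0

    def test_error_degrades_order_quality_monotonically(self):
        genome = rf.uniform_genome(1, 40, 80.0)
        base = rf.simulate_ssd(rf.SimConfig(genome=genome, n_lines=250, final_generation=6, seed=17))
        medians = []
        for err in (0.0, 0.05, 0.15):
            taus = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                noisy = rf.apply_noise(base, err, 0.0, rng)
                res = rf.threadmap(noisy.genotypes)
                big = max(res.orders.values(), key=lambda o: len(o.order))
                truth = [m for m in genome.linkage_groups[0].marker_ids if m in set(big.order)]
                taus.append(_abs_tau(big.order, truth))
            medians.append(np.median(taus))
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[0] > medians[2]


class TestExport3d:
    def test_file_contains_labels_and_no_external_fetches(self, seven_lg_population, tmp_path):
        proj = project(rf.encode_signed(seven_lg_population.genotypes))
        truth = {m: lg for lg, ms in seven_lg_population.truth_order.items() for m in ms}
        out = rf.export_3d(proj, truth, tmp_path / "proj.html")
        html = out.read_text()
        for lg in seven_lg_population.truth_order:
            assert lg in html
        for token in ("http://", "https://", "src=", "fetch("):
            assert token not in html

    def test_label_subset_filters_serialized_markers(self, seven_lg_population, tmp_path):
        proj = project(rf.encode_signed(seven_lg_population.genotypes))
        truth = {m: lg for lg, ms in seven_lg_population.truth_order.items() for m in ms}
        out = rf.export_3d(proj, truth, tmp_path / "sub.html", labels_subset=["LG2", "LG4"])
        html = out.read_text()
        assert "M2_0001" in html and "M4_0001" in html
        assert "M1_0001" not in html

    def test_two_components_rejected(self, seven_lg_population, tmp_path):
        s = rf.encode_signed(seven_lg_population.genotypes)
        proj = project(s, k=2)
        with pytest.raises(ValueError, match="k >= 3"):
            rf.export_3d(proj, {}, tmp_path / "x.html")


class TestInvariances:
    def test_line_permutation_leaves_ordering_unchanged(self, f6_population):
        g = f6_population.genotypes
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(g.lines))
        res_a = rf.threadmap(g)
        res_b = rf.threadmap(g.subset_lines(perm))
        assert next(iter(res_a.orders.values())).order == next(iter(res_b.orders.values())).order

    def test_global_relabel_negates_coords_keeps_order(self, f6_population):
        g = f6_population.genotypes
        flipped = g.calls.copy()
        a, b = flipped == GC.A, flipped == GC.B
        flipped[a], flipped[b] = GC.B, GC.A
        g2 = rf.GenotypeMatrix(list(g.markers), list(g.lines), flipped)
        res_a, res_b = rf.threadmap(g), rf.threadmap(g2)
        # sign convention may flip components, but geometry is mirrored
        assert np.allclose(np.abs(res_a.projection.coords), np.abs(res_b.projection.coords),
                           atol=1e-8)
        assert next(iter(res_a.orders.values())).order == next(iter(res_b.orders.values())).order
        assert res_a.groups.tolist() == res_b.groups.tolist()
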