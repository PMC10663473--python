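from dataclasses import replace

import numpy as np
import pytest

import rilforge as rf
from rilforge.genotype_core import GenotypeCall as GC
from rilforge.scaffold_order import (
    find_inconsistent_markers,
    graphical_genotype,
    initial_physical_order,
    reinsert_marker,
    scaffold_map_pipeline,
    total_events,
)


def _chrom_info(genome, assembly="sim"):
    """Annotation with chromosome-style sequence names (chrLG1, ...)."""
    return [replace(m, sequence_name="chr" + m.sequence_name)
            for m in genome.marker_info(assembly)]


class TestInitialPhysicalOrder:
    def test_sorted_by_bp(self):
        info = [rf.MarkerInfo("a", "v1", "chr1", 10),
                rf.MarkerInfo("b", "v1", "chr1", 5),
                rf.MarkerInfo("c", "v1", "chr1", 20)]
        order, unplaced = initial_physical_order(info, "v1")
        assert order == {"chr1": ["b", "a", "c"]} and unplaced == []

    def test_tie_broken_by_marker_id(self):
        info = [rf.MarkerInfo("z", "v1", "chr1", 7), rf.MarkerInfo("a", "v1", "chr1", 7)]
        order, _ = initial_physical_order(info, "v1")
        assert order["chr1"] == ["a", "z"]

    def test_scaffold_marker_reported_unplaced(self):
        info = [rf.MarkerInfo("a", "v1", "chr1", 5),
                rf.MarkerInfo("s", "v1", "scaffold0042", 37077)]
        order, unplaced = initial_physical_order(info, "v1")
        assert unplaced == ["s"]

    def test_unknown_assembly_is_error(self):
        info = [rf.MarkerInfo("a", "v1", "chr1", 5)]
        with pytest.raises(ValueError, match="v2"):
            initial_physical_order(info, "v2")


class TestFindInconsistentMarkers:
    def test_marker_identical_to_neighbors_scores_zero(self):
        calls = np.vstack([np.resize([GC.A, GC.B], 12)] * 3).astype(np.int8)
        g = rf.GenotypeMatrix(["m1", "m2", "m3"], [f"L{i}" for i in range(12)], calls)
        flags = find_inconsistent_markers(g, {"chr1": g.markers})
        assert (flags["excess"] == 0.0).all() and not flags["flagged"].any()

    def test_flipped_marker_row_flagged_with_hand_counted_excess(self):
        """One marker A<->B-flipped inside a uniform block of 10 identical lines."""
        calls = np.full((5, 10), GC.A, dtype=np.int8)
        calls[2] = GC.B  # the flipped marker forces 2 events in all 10 lines
        g = rf.GenotypeMatrix([f"m{i}" for i in range(5)], [f"L{i}" for i in range(10)], calls)
        flags = find_inconsistent_markers(g, {"chr1": g.markers})
        row = flags.set_index("marker_id").loc["m2"]
        assert row["excess"] == 20.0 and row["flagged"]

    def test_relocated_markers_detected(self, seven_lg_population):
        pop = seven_lg_population
        order = {lg: list(ms) for lg, ms in pop.truth_order.items()}
        moved = order["LG1"].pop(14)
        order["LG4"].insert(3, moved)  # relocate one marker onto another group
        flags = find_inconsistent_markers(pop.genotypes, order)
        assert flags.iloc[0]["marker_id"] == moved and flags.iloc[0]["flagged"]


class TestReinsertMarker:
    def test_identical_row_inserted_adjacent(self, f6_population):
        g = f6_population.genotypes
        order = {"chr1": [m for m in g.markers if m != g.markers[30]]}
        res = reinsert_marker(g, order, g.markers[30])
        # true position: between indices 29 and 30 of the reduced order
        assert res.sequence == "chr1" and abs(res.index - 30) <= 1

    def test_all_missing_marker_flagged_uninformative(self, f6_population):
        g = f6_population.genotypes
        calls = np.vstack([g.calls, np.full((1, g.n_lines), GC.MISSING, dtype=np.int8)])
        g2 = rf.GenotypeMatrix(g.markers + ["void"], g.lines, calls)
        res = reinsert_marker(g2, {"chr1": g.markers}, "void")
        assert res.uninformative

    def test_remove_reinsert_round_trip(self, seven_lg_population):
        """A removed marker returns to (or adjacent to) its slot, genome-wide scan."""
        pop = seven_lg_population
        for lg, pos in [("LG3", 10), ("LG6", 20)]:
            order = {k: list(v) for k, v in pop.truth_order.items()}
            marker = order[lg].pop(pos)
            res = reinsert_marker(pop.genotypes, order, marker)
            assert res.sequence == lg and abs(res.index - pos) <= 1


class TestGraphicalGenotype:
    def test_matrix_written_with_conserved_calls(self, tiny_matrix, tmp_path):
        out = tmp_path / "gg.png"
        reordered = graphical_genotype(tiny_matrix, {"c": ["m3", "m1", "m2"]}, out)
        assert out.exists() and out.with_suffix(".tsv").exists()
        for call in GC:
            assert (reordered.calls == call).sum() == (tiny_matrix.calls == call).sum()

    def test_single_crossover_line_switches_once(self, f6_population):
        counts = f6_population.visible_crossover_counts()[:, 0]
        one_xo = np.nonzero(counts == 1.0)[0]
        assert one_xo.size  # 100 cM group: plenty of single-crossover lines
        line = f6_population.genotypes.lines[one_xo[0]]
        reordered = graphical_genotype(
            f6_population.genotypes, f6_population.truth_order, path=None
        )
        col = reordered.calls[:, reordered.line_index(line)]
        informative = col[col != GC.MISSING]
        assert (np.diff(informative.astype(int)) != 0).sum() >= 1


class TestPipeline:
    def test_monotone_improvement_and_recovery(self, seven_lg_population):
        """Shuffled annotations: pipeline recovers nearly all true adjacencies."""
        pop = seven_lg_population
        info = _chrom_info(pop.genome)
        rng = np.random.default_rng(5)
        idx = rng.choice(len(info), 5, replace=False)
        for i in idx:
            j = int(rng.integers(len(info)))
            info[i] = replace(info[i], sequence_name=info[j].sequence_name,
                              position_bp=info[j].position_bp + 1)
        res = scaffold_map_pipeline(pop.genotypes, info, "sim")
        initial, _ = initial_physical_order(info, "sim")
        assert total_events(pop.genotypes, res.order) <= total_events(pop.genotypes, initial)
        true_adj = {frozenset(p) for ms in pop.truth_order.values() for p in zip(ms, ms[1:])}
        got_adj = {frozenset(p) for ms in res.order.values() for p in zip(ms, ms[1:])}
        assert len(true_adj & got_adj) / len(true_adj) >= 0.95

    def test_scaffold_only_marker_placed_by_recombination(self, f6_population):
        pop = f6_population
        info = _chrom_info(pop.genome)
        # claim one marker sits on an unanchored scaffold
        k = 25
        info[k] = replace(info[k], sequence_name="scaffold777")
        res = scaffold_map_pipeline(pop.genotypes, info, "sim")
        assert info[k].marker_id in res.unplaced_input
        placed = res.order["chrLG1"]
        assert abs(placed.index(info[k].marker_id) - k) <= 1
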