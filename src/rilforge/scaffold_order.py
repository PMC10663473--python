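"""Physical-scaffold map construction.

Map order is seeded from the markers' predicted physical positions on a
genome assembly (a "graphical genotype" order).  Markers sitting at a
position inconsistent with the minimum number of recombination events —
recurrent double-crossover signatures concentrated on one marker — are
removed, a scaffold map is built from the rest, and each removed marker is
reinserted at the position that minimises the total number of
recombination events, scanning every gap genome-wide so that markers from
misassembled scaffolds can move to another chromosome.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_core import GenotypeCall, GenotypeMatrix, MarkerInfo
from .recombination import _counts_for_block


def _placement_calls(calls: np.ndarray) -> np.ndarray:
    """Calls used for placement scoring: heterozygotes are uninformative.

    A residual H between two identical homozygous flanks would otherwise
    score a full spurious double-event against the marker, so placement
    evidence is restricted to the homozygous classes.
    """
    out = calls.copy()
    out[out == GenotypeCall.H] = GenotypeCall.MISSING
    return out

__all__ = [
    "ReinsertionResult",
    "ScaffoldPipelineResult",
    "initial_physical_order",
    "total_events",
    "find_inconsistent_markers",
    "reinsert_marker",
    "graphical_genotype",
    "scaffold_map_pipeline",
]


def initial_physical_order(
    markers: Sequence[MarkerInfo],
    assembly: str,
    chromosome_pattern: str = r"^chr",
) -> tuple[dict[str, list[str]], list[str]]:
    """Group markers by sequence and sort by bp on the named assembly.

    Returns (per-sequence ordered marker ids, unplaced marker ids).
    Sequences not matching ``chromosome_pattern`` (scaffolds, unanchored
    contigs) are reported as unplaced rather than ordered.  Ties in bp are
    broken by marker id so the order is deterministic.
    """
    on_assembly = [m for m in markers if m.assembly == assembly]
    if not on_assembly:
        known = sorted({m.assembly for m in markers})
        raise ValueError(f"assembly {assembly!r} absent from annotation (have {known})")
    pat = re.compile(chromosome_pattern)
    placed: dict[str, list[tuple[int, str]]] = {}
    unplaced: list[str] = []
    for m in on_assembly:
        if pat.search(m.sequence_name):
            placed.setdefault(m.sequence_name, []).append((m.position_bp, m.marker_id))
        else:
            unplaced.append(m.marker_id)
    order = {
        seq: [mid for _, mid in sorted(entries)] for seq, entries in sorted(placed.items())
    }
    return order, sorted(unplaced)


def total_events(g: GenotypeMatrix, order: Mapping[str, Sequence[str]]) -> float:
    """Total crossover events over all lines and all ordered blocks."""
    total = 0.0
    for markers in order.values():
        if len(markers) >= 2:
            calls = _placement_calls(g.subset_markers(list(markers)).calls)
            total += _counts_for_block(calls).sum()
    return float(total)


def find_inconsistent_markers(
    g: GenotypeMatrix,
    order: Mapping[str, Sequence[str]],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Score each ordered marker by the recombination events it forces.

    ``excess`` is the drop in total events when the marker is removed from
    its block.  A marker whose placement repeatedly forces double
    crossovers accumulates a large excess; markers with excess above the
    threshold (default 2 events — a single genuine double crossover is
    possible, recurrent ones at one marker are not) are flagged.
    Returns a frame (marker_id, sequence, excess, flagged) sorted by excess
    descending.
    """
    rows = []
    for seq, markers in order.items():
        markers = list(markers)
        if len(markers) < 2:
            for m in markers:
                rows.append((m, seq, 0.0))
            continue
        block_calls = _placement_calls(g.subset_markers(markers).calls)
        base = _counts_for_block(block_calls).sum()
        for i, m in enumerate(markers):
            if len(markers) == 2:
                rows.append((m, seq, 0.0))
                continue
            reduced = np.delete(block_calls, i, axis=0)
            rows.append((m, seq, float(base - _counts_for_block(reduced).sum())))
    df = pd.DataFrame(rows, columns=["marker_id", "sequence", "excess"])
    df["flagged"] = df["excess"] > threshold
    return df.sort_values(["excess", "marker_id"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class ReinsertionResult:
    sequence: str
    index: int  # gap index: insert before this position in the block
    added_events: float
    uninformative: bool = False


def reinsert_marker(
    g: GenotypeMatrix,
    scaffold_order: Mapping[str, Sequence[str]],
    marker: str,
    info: Mapping[str, MarkerInfo] | None = None,
) -> ReinsertionResult:
    """Find the recombination-minimising position for one marker.

    Every gap of every block is evaluated (the marker may belong on another
    chromosome than its annotation claims).  Ties are broken by proximity
    to the marker's claimed physical position when annotation is supplied,
    then by smallest (sequence, index).  A marker with no informative calls
    ties everywhere and is flagged uninformative.
    """
    marker_calls = _placement_calls(g.marker_calls(marker)[None, :])[0]
    if (marker_calls == GenotypeCall.MISSING).all():
        first_seq = next(iter(scaffold_order))
        return ReinsertionResult(first_seq, 0, 0.0, uninformative=True)

    best: tuple[float, float, str, int] | None = None  # (added, phys_dist, seq, gap)
    claimed = info.get(marker) if info else None
    for seq, markers in scaffold_order.items():
        markers = list(markers)
        block_calls = _placement_calls(g.subset_markers(markers).calls)
        base = _counts_for_block(block_calls).sum()
        for gap in range(len(markers) + 1):
            trial = np.insert(block_calls, gap, marker_calls, axis=0)
            added = float(_counts_for_block(trial).sum() - base)
            phys = np.inf
            if claimed is not None and claimed.sequence_name == seq:
                neighbors = []
                if gap > 0 and info and markers[gap - 1] in info:
                    neighbors.append(info[markers[gap - 1]].position_bp)
                if gap < len(markers) and info and markers[gap] in info:
                    neighbors.append(info[markers[gap]].position_bp)
                if neighbors:
                    phys = min(abs(claimed.position_bp - b) for b in neighbors)
            key = (added, phys, seq, gap)
            if best is None or key < best:
                best = key
    added, _, seq, gap = best
    return ReinsertionResult(seq, gap, added)


_CALL_COLORS = {
    GenotypeCall.A: "#2c7fb8",  # parent 1
    GenotypeCall.B: "#d95f0e",  # parent 2
    GenotypeCall.H: "#74c476",
    GenotypeCall.MISSING: "#d9d9d9",
}


def graphical_genotype(
    g: GenotypeMatrix,
    order: Mapping[str, Sequence[str]],
    path: str | Path | None = None,
) -> GenotypeMatrix:
    """Render lines x ordered-markers as a color-coded block image.

    Writes the image to ``path`` (suffix selects the format) and the
    reordered call matrix as a delimited text file alongside it
    (same stem, ``.tsv``).  Returns the reordered matrix.
    """
    flat = [m for markers in order.values() for m in markers]
    reordered = g.subset_markers(flat)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        cmap = ListedColormap([_CALL_COLORS[c] for c in GenotypeCall])
        fig, ax = plt.subplots(
            figsize=(max(4, len(flat) / 25), max(2, reordered.n_lines / 12))
        )
        ax.imshow(
            reordered.calls.T, aspect="auto", interpolation="nearest", cmap=cmap,
            vmin=-0.5, vmax=3.5,
        )
        ax.set_xlabel("markers (map order)")
        ax.set_ylabel("lines")
        fig.tight_layout()
        out = Path(path)
        fig.savefig(out, dpi=120)
        plt.close(fig)
        from .genotype_core import write_genotypes

        write_genotypes(reordered, out.with_suffix(".tsv"))
    return reordered


@dataclass
class ScaffoldPipelineResult:
    """Outcome of the flag -> scaffold -> reinsert pipeline."""

    order: dict[str, list[str]]
    flagged: pd.DataFrame  # all rounds' excess tables, concatenated
    reinserted: list[str] = field(default_factory=list)
    unplaced_input: list[str] = field(default_factory=list)
    rounds: int = 0


def scaffold_map_pipeline(
    g: GenotypeMatrix,
    markers: Sequence[MarkerInfo],
    assembly: str,
    threshold: float = 2.0,
    max_rounds: int = 5,
    chromosome_pattern: str = r"^chr",
) -> ScaffoldPipelineResult:
    """Physical order -> flag inconsistent markers -> reinsert, to a fixed point.

    Markers without a chromosome-level position (scaffold-only) are treated
    like flagged markers and placed purely by recombination evidence.  The
    loop terminates when a round flags nothing, or after ``max_rounds``.
    """
    order, unplaced = initial_physical_order(markers, assembly, chromosome_pattern)
    genotyped = set(g.markers)
    order = {seq: [m for m in ms if m in genotyped] for seq, ms in order.items()}
    order = {seq: ms for seq, ms in order.items() if ms}
    if not order:
        raise ValueError("no annotated chromosome-placed markers present in the genotypes")
    to_place = [m for m in unplaced if m in genotyped]
    info = {m.marker_id: m for m in markers if m.assembly == assembly}

    all_flags = []
    reinserted: list[str] = []
    rounds = 0
    pending = list(to_place)
    prev_order: dict[str, list[str]] | None = None
    for rounds in range(1, max_rounds + 1):
        flags = find_inconsistent_markers(g, order, threshold)
        flags["round"] = rounds
        all_flags.append(flags)
        bad = list(flags.loc[flags["flagged"], "marker_id"])
        if (not bad and not pending) or order == prev_order:
            break
        prev_order = {seq: list(ms) for seq, ms in order.items()}
        for m in bad:
            for seq in order:
                if m in order[seq]:
                    order[seq].remove(m)
        # worst offenders first, then markers with no physical home
        for m in bad + pending:
            res = reinsert_marker(g, order, m, info=info)
            order[res.sequence].insert(res.index, m)
            reinserted.append(m)
            if res.uninformative:
                warnings.warn(f"marker {m!r} is uninformative; placed arbitrarily")
        pending = []
    flagged = pd.concat(all_flags, ignore_index=True) if all_flags else pd.DataFrame()
    return ScaffoldPipelineResult(
        order=order,
        flagged=flagged,
        reinserted=reinserted,
        unplaced_input=to_place,
        rounds=rounds,
    )
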