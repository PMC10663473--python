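"""Crossover counting along an ordered map and F(n) vs F(n+1) comparison.

The counting rule treats each change between the two homozygous classes as
one recombination event and each change between homozygosity and
heterozygosity as half an event, so a line's total estimates the expected
crossover count per transmitted gamete.  Missing calls are skipped and the
flanking informative calls compared, which yields the minimum-event count
at marker resolution.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_core import SIGNED_LUT, GenotypeCall, GenotypeMatrix, PedigreePair
from .mapdist import LinkageMap

__all__ = [
    "CrossoverSummary",
    "PairComparison",
    "count_crossovers",
    "crossover_table",
    "compare_generations",
]

# breakpoint fate classes used by compare_generations
HOMHOM_PRESERVED = "homhom_preserved"
HOMHOM_LOST = "homhom_lost"
HOMHET_RETAINED = "homhet_retained"
HOMHET_TO_RECOMBINANT = "homhet_to_recombinant"
HOMHET_TO_NONRECOMBINANT = "homhet_to_nonrecombinant"
UNRESOLVED = "unresolved"
NEW = "new"


@dataclass
class CrossoverSummary:
    """Per-line, per-linkage-group crossover counts with Poisson summaries.

    ``per_line`` is a lines x LGs table of half-integer event counts.
    ``per_lg`` carries the mean, the sample variance (their equality is the
    Poisson expectation), and the non-recombinant line count per group.
    """

    per_line: pd.DataFrame
    per_lg: pd.DataFrame

    @property
    def genome_counts(self) -> pd.Series:
        return self.per_line.sum(axis=1)


@dataclass
class PairComparison:
    """Fate of one early-generation line's breakpoints in its descendant."""

    pair: PedigreePair
    differing_fraction: float
    breakpoint_classes: Counter


def count_crossovers(calls: Sequence[int] | np.ndarray) -> float:
    """Minimum recombination events along one line on one linkage group.

    Successive non-missing calls are compared: A<->B counts 1, a change
    between a homozygous class and H counts 1/2, equal calls count 0.  A run
    of H contributes only its flanking transitions.  With fewer than two
    informative calls the count is 0 (with a warning).
    """
    codes = np.asarray([int(c) for c in calls], dtype=np.int8)
    informative = codes != GenotypeCall.MISSING
    if informative.sum() < 2:
        warnings.warn("fewer than 2 informative calls; crossover count is 0", stacklevel=2)
        return 0.0
    signed = SIGNED_LUT[codes[informative]].astype(np.int16)
    return float(np.abs(np.diff(signed)).sum()) / 2.0


def _counts_for_block(calls: np.ndarray) -> np.ndarray:
    """Per-line counts for an ordered marker block (markers x lines)."""
    n_lines = calls.shape[1]
    out = np.zeros(n_lines)
    signed = SIGNED_LUT[calls].astype(np.int16)
    missing = calls == GenotypeCall.MISSING
    any_missing = missing.any(axis=0)
    clean = ~any_missing
    if clean.any() and calls.shape[0] >= 2:
        out[clean] = np.abs(np.diff(signed[:, clean], axis=0)).sum(axis=0) / 2.0
    for j in np.nonzero(any_missing)[0]:
        s = signed[~missing[:, j], j]
        if len(s) >= 2:
            out[j] = np.abs(np.diff(s)).sum() / 2.0
    return out


def crossover_table(g: GenotypeMatrix, lmap: LinkageMap) -> CrossoverSummary:
    """Count events for every line on every linkage group of ``lmap``."""
    per_lg_counts = {}
    for lg in lmap.lg_labels:
        markers = lmap.markers_of(lg)
        absent = [m for m in markers if m not in set(g.markers)]
        if absent:
            raise ValueError(f"map markers absent from genotype matrix: {absent[:5]}")
        sub = g.subset_markers(markers)
        per_lg_counts[lg] = _counts_for_block(sub.calls)
    per_line = pd.DataFrame(per_lg_counts, index=g.lines)
    per_lg = pd.DataFrame(
        {
            "mean": per_line.mean(),
            "var": per_line.var(ddof=1),
            "nonrecombinant_count": (per_line == 0).sum(),
            "nonrecombinant_fraction": (per_line == 0).mean(),
        }
    )
    return CrossoverSummary(per_line=per_line, per_lg=per_lg)


def _classify_breakpoints(
    early: np.ndarray, late: np.ndarray, classes: Counter
) -> None:
    """Classify breakpoints of one line on one ordered marker block."""
    A, B, H, MISS = (
        GenotypeCall.A,
        GenotypeCall.B,
        GenotypeCall.H,
        GenotypeCall.MISSING,
    )
    e_idx = np.nonzero(early != MISS)[0]
    early_bp_intervals: set[tuple[int, int]] = set()
    for i, j in zip(e_idx[:-1], e_idx[1:]):
        ei, ej = early[i], early[j]
        if ei == ej:
            continue
        early_bp_intervals.add((i, j))
        li, lj = late[i], late[j]
        if li == MISS or lj == MISS:
            classes[UNRESOLVED] += 1
            continue
        if {ei, ej} == {A, B}:
            classes[HOMHOM_PRESERVED if li != lj and MISS not in (li, lj) else HOMHOM_LOST] += 1
            continue
        # hom-het breakpoint: one flank homozygous, the other H
        if H in (ei, ej):
            if ei == H and ej == H:
                continue  # equal handled above; defensive
            hom_side, het_side = (i, j) if ej == H else (j, i)
            hom_call = early[hom_side]
            if late[hom_side] != hom_call:
                classes[UNRESOLVED] += 1
                continue
            fate = late[het_side]
            if fate == H:
                classes[HOMHET_RETAINED] += 1
            elif fate == hom_call:
                classes[HOMHET_TO_NONRECOMBINANT] += 1
            else:
                classes[HOMHET_TO_RECOMBINANT] += 1
    # new breakpoints: late transitions in intervals with no early breakpoint
    l_idx = np.nonzero(late != MISS)[0]
    for i, j in zip(l_idx[:-1], l_idx[1:]):
        if late[i] == late[j]:
            continue
        # an early breakpoint interval overlaps if it intersects (i, j)
        if not any(ei < j and ej > i for ei, ej in early_bp_intervals):
            classes[NEW] += 1


def compare_generations(
    g_early: GenotypeMatrix,
    g_late: GenotypeMatrix,
    pairs: Sequence[PedigreePair],
    lmap: LinkageMap,
) -> list[PairComparison]:
    """Track each early-generation breakpoint into the matched descendant.

    Breakpoints between two homozygous classes are fixed and must be
    preserved; breakpoints against a heterozygous segment are retained with
    probability 1/2 and otherwise resolve to the recombinant or the
    non-recombinant homozygous configuration with probability 1/4 each.
    """
    early_markers = set(g_early.markers)
    late_markers = set(g_late.markers)
    blocks = []
    for lg in lmap.lg_labels:
        shared = [m for m in lmap.markers_of(lg) if m in early_markers and m in late_markers]
        if len(shared) >= 2:
            blocks.append((g_early.subset_markers(shared), g_late.subset_markers(shared)))
    if not blocks:
        raise ValueError("no shared ordered markers between the two generations")

    out = []
    for pair in pairs:
        pair = pair if isinstance(pair, PedigreePair) else PedigreePair(*pair)
        try:
            ei = g_early.line_index(pair.early_line_id)
            li = g_late.line_index(pair.late_line_id)
        except KeyError as exc:
            raise ValueError(f"unknown line id in pedigree pair: {exc}") from exc
        classes: Counter = Counter()
        n_both = 0
        n_diff = 0
        for eb, lb in blocks:
            e = eb.calls[:, ei]
            l = lb.calls[:, li]
            both = (e != GenotypeCall.MISSING) & (l != GenotypeCall.MISSING)
            n_both += int(both.sum())
            n_diff += int((e[both] != l[both]).sum())
            _classify_breakpoints(e, l, classes)
        frac = n_diff / n_both if n_both else 0.0
        out.append(PairComparison(pair=pair, differing_fraction=frac, breakpoint_classes=classes))
    return out
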