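"""Discrete-trait placement on a RIL linkage map.

A two-state Mendelian trait behaves as a pseudo-marker: for every mapped
marker the fraction of lines whose phenotype-implied parental allele
disagrees with the marker call is the trait-marker recombinant fraction
estimate.  The scan's global minimum marks the major determinant; the
flanking markers with discordance above the minimum delimit the placement
interval, and markers tied at the minimum co-segregate with the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_core import GenotypeCall, GenotypeMatrix
from .mapdist import LinkageMap

__all__ = [
    "P1",
    "P2",
    "UNKNOWN",
    "TraitVector",
    "FlankingInterval",
    "read_trait",
    "trait_scan",
    "flanking_interval",
    "discordant_lines",
]

P1 = "parent1"
P2 = "parent2"
UNKNOWN = "unknown"
_STATES = {P1, P2, UNKNOWN}


@dataclass
class TraitVector:
    """Line -> phenotype state for one two-state character.

    With ``dominant`` set, heterozygous genotypes are scored concordant
    with ``dominant_class``; otherwise heterozygous genotypes are
    uninformative for the trait and skipped.
    """

    states: dict[str, str]
    dominant: bool = False
    dominant_class: str | None = None

    def __post_init__(self) -> None:
        bad = {s for s in self.states.values() if s not in _STATES}
        if bad:
            raise ValueError(f"trait states must be in {_STATES}, got {bad}")
        if self.dominant and self.dominant_class not in (P1, P2):
            raise ValueError("dominant traits need dominant_class of parent1/parent2")

    def swapped(self) -> "TraitVector":
        flip = {P1: P2, P2: P1, UNKNOWN: UNKNOWN}
        return TraitVector(
            {k: flip[v] for k, v in self.states.items()},
            dominant=self.dominant,
            dominant_class=flip[self.dominant_class] if self.dominant_class else None,
        )


def read_trait(
    path: str | Path,
    dominant: bool = False,
    dominant_class: str | None = None,
    token_map: Mapping[str, str] | None = None,
) -> TraitVector:
    """Read a two-column (line_id, state) table.

    Default tokens: ``P1``/``parent1``/``1`` and ``P2``/``parent2``/``2``;
    anything else (``NA``, ``?``, empty) is unknown.
    """
    tokens = {
        "P1": P1, "parent1": P1, "1": P1,
        "P2": P2, "parent2": P2, "2": P2,
    }
    if token_map:
        tokens.update(token_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("trait file needs two columns: line_id, state")
    lid, st = df.columns[:2]
    states = {str(r[lid]): tokens.get(str(r[st]).strip(), UNKNOWN) for _, r in df.iterrows()}
    return TraitVector(states, dominant=dominant, dominant_class=dominant_class)


def _implied_allele_match(
    calls: np.ndarray, phen: np.ndarray, t: TraitVector
) -> tuple[np.ndarray, np.ndarray]:
    """(informative mask, concordant mask) for one marker across lines."""
    known = phen != UNKNOWN
    hom_a = calls == GenotypeCall.A
    hom_b = calls == GenotypeCall.B
    het = calls == GenotypeCall.H
    informative = known & (hom_a | hom_b | (het if t.dominant else False))
    concordant = np.zeros(len(calls), dtype=bool)
    concordant[hom_a & (phen == P1)] = True
    concordant[hom_b & (phen == P2)] = True
    if t.dominant:
        concordant[het & (phen == t.dominant_class)] = True
    return informative, concordant & informative


def trait_scan(t: TraitVector, g: GenotypeMatrix, lmap: LinkageMap) -> pd.DataFrame:
    """Per-marker discordance between trait and marker calls, in map order.

    Returns a frame (marker_id, lg_label, cum_cM, n_informative,
    n_discordant, discordance) whose attrs record the global-minimum
    marker.  Lines must be shared between the trait table and the
    genotypes.
    """
    shared = [l for l in g.lines if l in t.states]
    if not shared:
        raise ValueError("no lines shared between trait and genotype matrix")
    sub = g.subset_lines(shared)
    phen = np.array([t.states[l] for l in shared], dtype=object)

    rows = []
    marker_set = set(sub.markers)
    for _, rec in lmap.frame.iterrows():
        m = rec["marker_id"]
        if m not in marker_set:
            continue
        calls = sub.marker_calls(m)
        informative, concordant = _implied_allele_match(calls, phen, t)
        n = int(informative.sum())
        n_disc = int(n - concordant.sum())
        rows.append(
            (m, rec["lg_label"], float(rec["cum_cM"]), n, n_disc,
             n_disc / n if n else np.nan)
        )
    if not rows:
        raise ValueError("no map markers present in the genotype matrix")
    scan = pd.DataFrame(
        rows,
        columns=["marker_id", "lg_label", "cum_cM", "n_informative", "n_discordant",
                 "discordance"],
    )
    valid = scan["discordance"].notna()
    best = scan.loc[valid, "discordance"].idxmin()
    scan.attrs["min_marker"] = scan.loc[best, "marker_id"]
    scan.attrs["min_lg"] = scan.loc[best, "lg_label"]
    scan.attrs["min_cM"] = float(scan.loc[best, "cum_cM"])
    scan.attrs["min_discordance"] = float(scan.loc[best, "discordance"])
    return scan


@dataclass
class FlankingInterval:
    """Trait placement interval delimited by the nearest recombinant flanks."""

    lg_label: str
    left_marker: str | None
    right_marker: str | None
    left_cM: float
    right_cM: float
    interval_cM: float
    n_cosegregating: int
    cosegregating: tuple[str, ...]
    one_sided: bool = False


def flanking_interval(scan: pd.DataFrame) -> FlankingInterval:
    """Delimit the trait's interval around the scan minimum.

    Expands from the minimum marker along its linkage group to the nearest
    marker on each side with discordance above the minimum; markers inside
    (discordance equal to the minimum) co-segregate with the trait.  At a
    linkage-group end the interval is one-sided and flagged.
    """
    lg = scan.attrs["min_lg"]
    dmin = scan.attrs["min_discordance"]
    sub = scan[scan["lg_label"] == lg].reset_index(drop=True)
    center = int(sub.index[sub["marker_id"] == scan.attrs["min_marker"]][0])
    tol = 1e-12
    lo = center
    while lo > 0 and sub.loc[lo - 1, "discordance"] <= dmin + tol:
        lo -= 1
    hi = center
    while hi < len(sub) - 1 and sub.loc[hi + 1, "discordance"] <= dmin + tol:
        hi += 1
    coseg = tuple(sub.loc[lo:hi, "marker_id"])
    left = sub.loc[lo - 1] if lo > 0 else None
    right = sub.loc[hi + 1] if hi < len(sub) - 1 else None
    left_cM = float(left["cum_cM"]) if left is not None else float(sub.loc[lo, "cum_cM"])
    right_cM = float(right["cum_cM"]) if right is not None else float(sub.loc[hi, "cum_cM"])
    return FlankingInterval(
        lg_label=lg,
        left_marker=None if left is None else str(left["marker_id"]),
        right_marker=None if right is None else str(right["marker_id"]),
        left_cM=left_cM,
        right_cM=right_cM,
        interval_cM=right_cM - left_cM,
        n_cosegregating=len(coseg),
        cosegregating=coseg,
        one_sided=left is None or right is None,
    )


def discordant_lines(t: TraitVector, g: GenotypeMatrix, marker_id: str) -> list[str]:
    """Lines whose phenotype contradicts their call at one marker.

    Typically run at the scan minimum to list candidate mis-scorings or
    stock mix-ups.
    """
    shared = [l for l in g.lines if l in t.states]
    sub = g.subset_lines(shared)
    phen = np.array([t.states[l] for l in shared], dtype=object)
    calls = sub.marker_calls(marker_id)
    informative, concordant = _implied_allele_match(calls, phen, t)
    return [l for l, inf, con in zip(shared, informative, concordant) if inf and not con]
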