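"""Segregation-distortion scans and structural-rearrangement signatures.

In a fully inbred RIL population the two homozygous classes at any marker
are expected 1:1; a signed chi-square statistic per marker (positive for a
parent-1 excess, negative for a parent-2 excess) exposes regions of
viability selection.  A second structural signal is pseudolinkage: blocks
of markers annotated on *different* chromosomes showing essentially zero
recombination, the hallmark of a translocation distinguishing the two
parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_core import GenotypeCall, GenotypeMatrix
from .mapdist import LinkageMap, PairwiseR

__all__ = [
    "DistortionScan",
    "InterchromosomalBlock",
    "signed_chisq",
    "chisq_critical",
    "distance_heatmap",
    "detect_interchromosomal_blocks",
]


@dataclass
class DistortionScan:
    """Per-marker homozygote counts and the signed 1:1 chi-square.

    ``frame`` columns: marker_id, n_parent1_hom, n_parent2_hom, chi2,
    signed_chi2, significant_1pct, flagged (no homozygous calls).
    """

    frame: pd.DataFrame
    parent1_label: str
    parent2_label: str
    alpha: float = 0.01


def signed_chisq(
    g: GenotypeMatrix,
    parent1_label: str = "parent1",
    parent2_label: str = "parent2",
    alpha: float = 0.01,
) -> DistortionScan:
    """Signed chi-square against 1:1 segregation, homozygous calls only.

    With n1 and n2 the two homozygote counts and E = (n1 + n2)/2, the
    statistic is (n1-E)^2/E + (n2-E)^2/E, carrying a positive sign for a
    parent-1 excess and negative for a parent-2 excess (zero when equal).
    Heterozygotes and missing calls do not enter.  Markers with no
    homozygous calls are flagged, not fatal.
    """
    n1 = (g.calls == GenotypeCall.A).sum(axis=1).astype(float)
    n2 = (g.calls == GenotypeCall.B).sum(axis=1).astype(float)
    total = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n1 - n2) ** 2 / total
    chi2 = np.where(total > 0, chi2, np.nan)
    sign = np.sign(n1 - n2)
    crit = chisq_critical(alpha, 1)
    frame = pd.DataFrame(
        {
            "marker_id": g.markers,
            "n_parent1_hom": n1.astype(int),
            "n_parent2_hom": n2.astype(int),
            "chi2": chi2,
            "signed_chi2": sign * chi2,
            "significant_1pct": np.nan_to_num(chi2) > crit,
            "flagged": total == 0,
        }
    )
    return DistortionScan(frame, parent1_label, parent2_label, alpha)


def chisq_critical(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value (e.g. 6.635 at alpha=0.01, 1 df)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.isf(alpha, df))


def distance_heatmap(
    pr: PairwiseR,
    order: LinkageMap,
    path: str | Path,
    scan: DistortionScan | None = None,
    annotate_every: int = 10,
) -> Path:
    """Pairwise-R heat map in map order, with an optional distortion track.

    Markers are arranged identically on both axes in map order; low R
    (tight linkage) renders dark.  When a scan is given, a margin panel
    plots the signed chi-square with guide lines at +-critical and 0.  R
    values are printed along the diagonal every ``annotate_every`` markers.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    map_markers = [m for m in order.frame["marker_id"] if m in set(pr.markers)]
    if len(map_markers) < 2:
        raise ValueError("need at least 2 mapped markers to draw a heat map")
    sub = pr.submatrix(map_markers)
    n = len(map_markers)

    if scan is not None:
        fig, (ax, ax2) = plt.subplots(
            1, 2, figsize=(9.5, 7), gridspec_kw={"width_ratios": [5, 1]}, sharey=True
        )
    else:
        fig, ax = plt.subplots(figsize=(7.5, 7))
    im = ax.imshow(
        np.nan_to_num(sub.R, nan=0.5), cmap="PRGn_r", vmin=0.0, vmax=0.5,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, shrink=0.7, label="R (recombinant-line fraction)")
    step = max(1, annotate_every)
    if n <= 2000:
        for i in range(0, n - 1, step):
            r = sub.R[i, min(i + 1, n - 1)]
            if np.isfinite(r):
                ax.text(i, i, f"{r:.2f}", fontsize=4, ha="left", va="bottom")
    # linkage-group boundaries
    lg_sizes = order.frame[order.frame["marker_id"].isin(map_markers)].groupby(
        "lg_label", sort=False
    ).size()
    edge = 0
    for size in lg_sizes[:-1]:
        edge += size
        ax.axhline(edge - 0.5, color="k", lw=0.4)
        ax.axvline(edge - 0.5, color="k", lw=0.4)
    ax.set_xlabel("markers (map order)")
    ax.set_ylabel("markers (map order)")

    if scan is not None:
        s = scan.frame.set_index("marker_id").reindex(map_markers)
        y = np.arange(n)
        ax2.plot(s["signed_chi2"].to_numpy(), y, lw=0.6, color="#444")
        crit = chisq_critical(scan.alpha, 1)
        for x in (-crit, 0.0, crit):
            ax2.axvline(x, color="#b33", lw=0.6, ls="--" if x else "-")
        ax2.set_xlabel("signed $\\chi^2$")
        ax2.invert_yaxis()
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


@dataclass
class InterchromosomalBlock:
    """A pseudolinkage block: two marker runs on different chromosomes."""

    chrom_a: str
    chrom_b: str
    block_a: tuple[str, ...]  # first..last marker run on chrom_a
    block_b: tuple[str, ...]
    min_R: float
    n_zero_R_pairs: int


def _runs(hits: np.ndarray, gap_tolerance: int) -> list[np.ndarray]:
    """Maximal index runs of True allowing up to ``gap_tolerance`` gaps."""
    idx = np.nonzero(hits)[0]
    if idx.size == 0:
        return []
    runs, start, prev = [], idx[0], idx[0]
    for i in idx[1:]:
        if i - prev > gap_tolerance + 1:
            runs.append(np.arange(start, prev + 1))
            start = i
        prev = i
    runs.append(np.arange(start, prev + 1))
    return runs


def detect_interchromosomal_blocks(
    pr: PairwiseR,
    chrom_labels: Mapping[str, str],
    R_max: float = 0.0,
    gap_tolerance: int = 1,
) -> list[InterchromosomalBlock]:
    """Find runs of markers on different chromosomes with R <= R_max.

    ``pr.markers`` must be in within-chromosome physical/map order.  For
    each chromosome pair, markers participating in at least one
    cross-chromosome pair with R <= R_max (and enough informative lines)
    are collected into maximal runs, tolerating ``gap_tolerance``
    interrupting markers to absorb genotyping error.  Blocks are reported
    largest-first by their count of qualifying pairs.
    """
    labels = np.array([chrom_labels.get(m, "?") for m in pr.markers])
    chroms = list(dict.fromkeys(labels))
    if len(set(labels)) < 2:
        return []
    blocks: list[InterchromosomalBlock] = []
    for ai in range(len(chroms)):
        for bi in range(ai + 1, len(chroms)):
            ca, cb = chroms[ai], chroms[bi]
            ia = np.nonzero(labels == ca)[0]
            ib = np.nonzero(labels == cb)[0]
            sub_R = pr.R[np.ix_(ia, ib)]
            ok = pr.reliable[np.ix_(ia, ib)] & np.isfinite(sub_R)
            hit = ok & (sub_R <= R_max)
            if not hit.any():
                continue
            for run_a in _runs(hit.any(axis=1), gap_tolerance):
                cols = hit[run_a].any(axis=0)
                for run_b in _runs(cols, gap_tolerance):
                    pair_hits = hit[np.ix_(run_a, run_b)]
                    if not pair_hits.any():
                        continue
                    sub = sub_R[np.ix_(run_a, run_b)]
                    blocks.append(
                        InterchromosomalBlock(
                            chrom_a=ca,
                            chrom_b=cb,
                            block_a=tuple(pr.markers[ia[k]] for k in run_a),
                            block_b=tuple(pr.markers[ib[k]] for k in run_b),
                            min_R=float(np.nanmin(sub)),
                            n_zero_R_pairs=int(pair_hits.sum()),
                        )
                    )
    blocks.sort(key=lambda b: -b.n_zero_R_pairs)
    return blocks
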