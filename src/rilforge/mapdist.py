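"""Two-point recombinant fractions and Haldane map distances for RILs.

In a population of extensively selfed inbred lines, the observable quantity
for a marker pair is R, the fraction of lines whose alleles at the two
markers derive from different parents.  Repeated rounds of meiosis inflate
R relative to the per-meiosis recombination rate r ("map expansion"); the
Haldane-Waddington relationship r = R / (2(1 - R)) corrects for it, and
Haldane's mapping function d = -50 ln(1 - 2r) cM turns rates into additive
distances under the no-interference assumption.  For small values
r ~ R/2 ~ d/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_core import GenotypeCall, GenotypeMatrix, MarkerInfo

__all__ = [
    "PairwiseR",
    "LinkageMap",
    "AssemblyComparison",
    "pairwise_R",
    "haldane_waddington_r",
    "haldane_cM",
    "build_map",
    "compare_to_assembly",
]


@dataclass
class PairwiseR:
    """Symmetric recombinant-line fraction matrix.

    ``R[i, j]`` is NaN where no informative line exists; ``reliable`` marks
    pairs scored in at least ``min_informative`` lines (both calls
    homozygous), below which R carries little information.
    """

    markers: list[str]
    R: np.ndarray
    n_informative: np.ndarray
    min_informative: int = 20

    @property
    def reliable(self) -> np.ndarray:
        return self.n_informative >= self.min_informative

    def submatrix(self, marker_ids: Sequence[str]) -> "PairwiseR":
        pos = {m: i for i, m in enumerate(self.markers)}
        idx = np.array([pos[m] for m in marker_ids])
        return PairwiseR(
            list(marker_ids),
            self.R[np.ix_(idx, idx)],
            self.n_informative[np.ix_(idx, idx)],
            self.min_informative,
        )


def pairwise_R(g: GenotypeMatrix, min_informative: int = 20) -> PairwiseR:
    """All-pairs recombinant-line fractions.

    For each marker pair, lines where both calls are homozygous are
    informative; R is the fraction of informative lines in which the two
    calls derive from different parents.  Heterozygous and missing calls
    are excluded pair by pair.
    """
    if g.n_markers < 2:
        raise ValueError("pairwise_R needs at least 2 markers")
    signed = np.zeros(g.calls.shape, dtype=np.float64)
    signed[g.calls == GenotypeCall.A] = 1.0
    signed[g.calls == GenotypeCall.B] = -1.0
    hom = np.abs(signed)
    n = hom @ hom.T  # informative counts
    s = signed @ signed.T  # concordant minus discordant
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (n - s) / (2.0 * n)
    np.fill_diagonal(R, 0.0)
    return PairwiseR(list(g.markers), R, n.astype(np.int64), min_informative)


def haldane_waddington_r(R):
    """Map-expansion correction for selfed inbred lines: r = R / (2(1-R)).

    Accepts scalars or arrays with 0 <= R < 1.  Values of R above 0.5 yield
    r > 0.5 and indicate an unlinked (or mis-phased) pair; they are returned
    untouched for the caller to flag.
    """
    arr = np.asarray(R, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("R must satisfy 0 <= R < 1")
    r = arr / (2.0 * (1.0 - arr))
    return float(r) if np.isscalar(R) else r


def haldane_cM(r):
    """Haldane's mapping function in centimorgans: d = -50 ln(1 - 2r)."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.5):
        raise ValueError("r must satisfy 0 <= r < 0.5 (r = 0.5 is infinite distance)")
    d = -50.0 * np.log1p(-2.0 * arr)
    return float(d) if np.isscalar(r) else d


@dataclass
class LinkageMap:
    """Ordered markers with linkage-group labels and cumulative cM.

    ``frame`` columns: marker_id, lg_label, cum_cM, and optionally
    sequence_name / position_bp physical anchors plus an interval_flag
    ("" | "unlinked" | "low_info") describing the interval *preceding* each
    marker.  Cumulative positions start at 0 within each group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "lg_label", "cum_cM"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"LinkageMap frame needs columns {sorted(required)}")
        for lg, sub in self.frame.groupby("lg_label", sort=False):
            d = np.diff(sub["cum_cM"].to_numpy())
            if len(d) and d.min() < -1e-9:
                raise ValueError(f"cumulative cM not non-decreasing in {lg}")

    @property
    def lg_labels(self) -> list[str]:
        return list(dict.fromkeys(self.frame["lg_label"]))

    def markers_of(self, lg_label: str) -> list[str]:
        sub = self.frame[self.frame["lg_label"] == lg_label]
        if sub.empty:
            raise ValueError(f"unknown linkage group label: {lg_label!r}")
        return list(sub["marker_id"])

    def position_of(self, marker_id: str) -> tuple[str, float]:
        row = self.frame[self.frame["marker_id"] == marker_id]
        if row.empty:
            raise ValueError(f"marker {marker_id!r} not on the map")
        return str(row["lg_label"].iloc[0]), float(row["cum_cM"].iloc[0])

    def length_of(self, lg_label: str) -> float:
        sub = self.frame[self.frame["lg_label"] == lg_label]
        return float(sub["cum_cM"].max() - sub["cum_cM"].min())

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "LinkageMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"marker_id": str, "lg_label": str}))


def _adjacent_R(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """R and informative count for one ordered marker pair (call vectors)."""
    hom_a = (a == GenotypeCall.A) | (a == GenotypeCall.B)
    hom_b = (b == GenotypeCall.A) | (b == GenotypeCall.B)
    both = hom_a & hom_b
    n = int(both.sum())
    if n == 0:
        return np.nan, 0
    disc = int((a[both] != b[both]).sum())
    return disc / n, n


def build_map(
    order: Mapping[str, Sequence[str]],
    g: GenotypeMatrix,
    min_informative: int = 20,
    max_interval_cM: float = 100.0,
) -> LinkageMap:
    """Assemble a linkage map from per-group marker orders.

    Each adjacent interval's distance is haldane_cM(haldane_waddington_r(R))
    from the two-point R of the flanking markers; cumulative positions are
    the running sums.  Intervals with R >= 0.5 (probable ordering error or
    genuinely unlinked neighbors) or with too few informative lines are
    capped at ``max_interval_cM`` / left at 0 and flagged.
    """
    rows = []
    for lg, markers in order.items():
        if len(markers) == 0:
            raise ValueError(f"linkage group {lg!r} has no markers")
        sub = g.subset_markers(list(markers))
        cum = 0.0
        rows.append((markers[0], lg, 0.0, ""))
        for i in range(1, len(markers)):
            R, n = _adjacent_R(sub.calls[i - 1], sub.calls[i])
            flag = ""
            if n < min_informative:
                flag = "low_info"
                d = 0.0 if np.isnan(R) else _safe_distance(R, max_interval_cM)
            else:
                d = _safe_distance(R, max_interval_cM)
                if R >= 0.5:
                    flag = "unlinked"
            cum += d
            rows.append((markers[i], lg, cum, flag))
    frame = pd.DataFrame(rows, columns=["marker_id", "lg_label", "cum_cM", "interval_flag"])
    return LinkageMap(frame)


def _safe_distance(R: float, cap_cM: float) -> float:
    if R >= 0.5:
        return cap_cM
    return min(haldane_cM(haldane_waddington_r(R)), cap_cM)


@dataclass
class AssemblyComparison:
    """Genetic map vs physical assembly: collinearity and marker spacing."""

    per_lg: pd.DataFrame  # lg, n_shared, spearman_abs, spacing stats (Mb)
    series: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_markers: list[str] = field(default_factory=list)


def compare_to_assembly(
    lmap: LinkageMap, info: Sequence[MarkerInfo], assembly: str | None = None
) -> AssemblyComparison:
    """Compare map order against physical positions on one assembly.

    Per linkage group the (cumulative cM, bp) series is returned for
    plotting along with the absolute Spearman rank correlation over all
    annotated markers (markers claimed on a different chromosome, e.g. a
    translocated segment, depress it) and the adjacent-marker physical
    spacing (mean +- SD, Mb) on the group's modal sequence.
    """
    if assembly is not None:
        info = [m for m in info if m.assembly == assembly]
        if not info:
            raise ValueError(f"no markers annotated on assembly {assembly!r}")
    ann = {m.marker_id: m for m in info}
    shared = [m for m in lmap.frame["marker_id"] if m in ann]
    if not shared:
        raise ValueError("no markers shared between map and annotation")
    excluded = [m for m in lmap.frame["marker_id"] if m not in ann]

    per_lg_rows = []
    series: dict[str, pd.DataFrame] = {}
    for lg in lmap.lg_labels:
        sub = lmap.frame[lmap.frame["lg_label"] == lg]
        sub = sub[sub["marker_id"].isin(ann)]
        if sub.empty:
            continue
        df = pd.DataFrame(
            {
                "marker_id": sub["marker_id"].to_numpy(),
                "cum_cM": sub["cum_cM"].to_numpy(),
                "sequence_name": [ann[m].sequence_name for m in sub["marker_id"]],
                "position_bp": [ann[m].position_bp for m in sub["marker_id"]],
            }
        )
        series[lg] = df
        if len(df) >= 3 and df["position_bp"].nunique() > 1:
            rho = abs(stats.spearmanr(df["cum_cM"], df["position_bp"]).statistic)
        else:
            rho = np.nan
        modal_seq = df["sequence_name"].mode().iloc[0]
        on_modal = df[df["sequence_name"] == modal_seq]
        spacing = np.abs(np.diff(on_modal["position_bp"].to_numpy())) / 1e6
        per_lg_rows.append(
            (
                lg,
                len(df),
                rho,
                spacing.mean() if len(spacing) else np.nan,
                spacing.std(ddof=1) if len(spacing) > 1 else np.nan,
            )
        )
    per_lg = pd.DataFrame(
        per_lg_rows,
        columns=["lg_label", "n_shared", "spearman_abs", "spacing_mean_mb", "spacing_sd_mb"],
    )
    return AssemblyComparison(per_lg=per_lg, series=series, excluded_markers=excluded)
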