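"""Core genotype containers, I/O and population summaries for RIL mapping.

A recombinant inbred line (RIL) population descends from a cross between two
inbred parents; after repeated selfing each line is a near-homozygous mosaic
of the two parental genomes.  Every marker call therefore takes one of four
states: homozygous for the parent-1 allele (``A``), homozygous for the
parent-2 allele (``B``), residually heterozygous (``H``), or missing.

This module defines the call alphabet, the marker-by-line call matrix, the
signed +1/-1/0 encoding used by the principal-component ordering machinery,
marker annotation records, and the population-level summaries (heterozygous
fraction, per-line call-category tables) used for data quality control.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCall",
    "GenotypeDialect",
    "GenotypeMatrix",
    "MarkerInfo",
    "PedigreePair",
    "SignedMatrix",
    "DEFAULT_DIALECT",
    "read_genotypes",
    "write_genotypes",
    "read_marker_info",
    "write_marker_info",
    "read_pedigree",
    "encode_signed",
    "het_fraction",
    "expected_het",
    "call_category_table",
]


class GenotypeCall(IntEnum):
    """One marker call: the four-state RIL alphabet."""

    A = 0  # homozygous, parent-1 allele
    B = 1  # homozygous, parent-2 allele
    H = 2  # heterozygous
    MISSING = 3


# lookup tables indexed by GenotypeCall code
_CALL_TOKENS = np.array(["A", "B", "H", "-"])
# signed encoding: A -> +1, B -> -1, H and MISSING -> 0
SIGNED_LUT = np.array([1, -1, 0, 0], dtype=np.int8)


@dataclass(frozen=True)
class GenotypeDialect:
    """Token vocabulary for reading/writing call matrices.

    ``tokens`` maps input tokens (matched case-sensitively after stripping
    whitespace) onto the four call states.  ``out_tokens`` is the canonical
    token written for each state.
    """

    tokens: Mapping[str, GenotypeCall] = field(
        default_factory=lambda: {
            "A": GenotypeCall.A,
            "AA": GenotypeCall.A,
            "0": GenotypeCall.A,
            "B": GenotypeCall.B,
            "BB": GenotypeCall.B,
            "2": GenotypeCall.B,
            "H": GenotypeCall.H,
            "AB": GenotypeCall.H,
            "BA": GenotypeCall.H,
            "1": GenotypeCall.H,
            "NA": GenotypeCall.MISSING,
            "N": GenotypeCall.MISSING,
            "-": GenotypeCall.MISSING,
            "": GenotypeCall.MISSING,
            "NoCall": GenotypeCall.MISSING,
            "NN": GenotypeCall.MISSING,
        }
    )
    out_tokens: Sequence[str] = ("A", "B", "H", "-")
    sep: str = "\t"

    def parse_token(self, token: str) -> GenotypeCall | None:
        return self.tokens.get(token.strip())


DEFAULT_DIALECT = GenotypeDialect()


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Marker-by-line grid of genotype calls.

    ``calls`` holds :class:`GenotypeCall` codes as ``int8`` with shape
    ``(len(markers), len(lines))``.  Markers are rows, RILs are columns.
    """

    markers: list[str]
    lines: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.lines)):
            raise ValueError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.lines)} lines"
            )
        _check_unique(self.markers, "marker")
        _check_unique(self.lines, "line")
        if not np.isin(self.calls, [0, 1, 2, 3]).all():
            raise ValueError("calls contain codes outside the A/B/H/MISSING alphabet")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_idx[marker_id]
        except AttributeError:
            self._marker_idx = {m: i for i, m in enumerate(self.markers)}
            return self._marker_idx[marker_id]

    def line_index(self, line_id: str) -> int:
        try:
            return self._line_idx[line_id]
        except AttributeError:
            self._line_idx = {l: i for i, l in enumerate(self.lines)}
            return self._line_idx[line_id]

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[self.marker_index(marker_id)]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(list(marker_ids), list(self.lines), self.calls[idx])

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.line_index(l) for l in line_ids]
        return GenotypeMatrix(list(self.markers), list(line_ids), self.calls[:, idx])

    def to_frame(self, dialect: GenotypeDialect = DEFAULT_DIALECT) -> pd.DataFrame:
        tok = np.asarray(dialect.out_tokens)
        return pd.DataFrame(tok[self.calls], index=self.markers, columns=self.lines)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.markers), list(self.lines), self.calls.copy())


@dataclass(frozen=True)
class MarkerInfo:
    """Physical annotation of one marker on one assembly (1-based bp)."""

    marker_id: str
    assembly: str
    sequence_name: str
    position_bp: int
    call_category: str | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(
                f"position_bp must be >= 1 (marker {self.marker_id}: {self.position_bp})"
            )


@dataclass(frozen=True)
class PedigreePair:
    """Link between the same RIL lineage sampled at two generations."""

    early_line_id: str
    late_line_id: str


@dataclass
class SignedMatrix:
    """+1/-1/0 encoding of a genotype matrix (markers x lines).

    Parent-1 homozygotes are +1, parent-2 homozygotes -1, heterozygous and
    missing calls 0.  This is the input to the principal-component marker
    projection.
    """

    markers: list[str]
    lines: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.markers), len(self.lines)):
            raise ValueError("signed grid shape does not match marker/line ids")
        if not np.isin(self.values, [-1, 0, 1]).all():
            raise ValueError("signed values must be in {-1, 0, +1}")


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(
    path: str | Path | io.TextIOBase,
    dialect: GenotypeDialect = DEFAULT_DIALECT,
    transpose: bool = False,
) -> GenotypeMatrix:
    """Read a delimited call matrix.

    Canonical orientation: header row of line ids, first column marker ids,
    one row per marker.  With ``transpose=True`` the file is read as
    lines-as-rows and flipped into the canonical orientation.

    Raises ``ValueError`` on empty input, ragged rows, duplicated ids or
    unrecognised call tokens (reported with row/column context).
    """
    df = pd.read_csv(path, sep=dialect.sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no markers: the genotype file has no data rows/columns")
    if transpose:
        df = df.T
    markers = [str(m) for m in df.index]
    lines = [str(l) for l in df.columns]
    _check_unique(markers, "marker")
    _check_unique(lines, "line")

    raw = df.to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=np.int8)
    bad: list[str] = []
    # token -> code cache; matrices repeat a tiny vocabulary
    cache: dict[str, int] = {}
    for (i, j), token in np.ndenumerate(raw):
        t = str(token)
        code = cache.get(t)
        if code is None:
            call = dialect.parse_token(t)
            if call is None:
                bad.append(f"unknown token {t!r} at marker {markers[i]!r}, line {lines[j]!r}")
                if len(bad) >= 20:
                    break
                continue
            code = int(call)
            cache[t] = code
        calls[i, j] = code
    if bad:
        raise ValueError("unrecognised genotype tokens:\n" + "\n".join(bad))
    return GenotypeMatrix(markers, lines, calls)


def write_genotypes(
    g: GenotypeMatrix,
    path: str | Path,
    dialect: GenotypeDialect = DEFAULT_DIALECT,
) -> None:
    """Write the matrix in the canonical orientation with canonical tokens."""
    g.to_frame(dialect).to_csv(path, sep=dialect.sep, index_label="marker_id")


def read_marker_info(path: str | Path) -> list[MarkerInfo]:
    """Read a marker annotation table.

    Expected columns: marker_id, assembly, sequence_name, position_bp and
    optionally call_category.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "sequence_name": str})
    required = {"marker_id", "assembly", "sequence_name", "position_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker annotation lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MarkerInfo(
                marker_id=str(row.marker_id),
                assembly=str(row.assembly),
                sequence_name=str(row.sequence_name),
                position_bp=int(row.position_bp),
                call_category=(
                    str(row.call_category)
                    if "call_category" in df.columns and not pd.isna(row.call_category)
                    else None
                ),
            )
        )
    return out


def write_marker_info(info: Iterable[MarkerInfo], path: str | Path) -> None:
    rows = [
        (m.marker_id, m.assembly, m.sequence_name, m.position_bp, m.call_category or "")
        for m in info
    ]
    pd.DataFrame(
        rows, columns=["marker_id", "assembly", "sequence_name", "position_bp", "call_category"]
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> list[PedigreePair]:
    """Read a two-column (early_line_id, late_line_id) table.

    A late-generation line may descend from at most one early-generation
    line; duplicated late ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("pedigree file needs two columns: early_line_id, late_line_id")
    early, late = df.columns[:2]
    if df[late].duplicated().any():
        dup = df[late][df[late].duplicated()].iloc[0]
        raise ValueError(f"late line {dup!r} is paired with more than one early line")
    return [PedigreePair(str(r[early]), str(r[late])) for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Summaries


def encode_signed(g: GenotypeMatrix) -> SignedMatrix:
    """Encode calls as +1 (A), -1 (B), 0 (H or missing), preserving shape."""
    return SignedMatrix(list(g.markers), list(g.lines), SIGNED_LUT[g.calls])


def het_fraction(g: GenotypeMatrix) -> float:
    """Fraction of non-missing calls that are heterozygous.

    For an F(g) population produced by selfing this is expected to be
    (1/2)^(g-1); see :func:`expected_het`.
    """
    non_missing = int((g.calls != GenotypeCall.MISSING).sum())
    if non_missing == 0:
        raise ValueError("het_fraction undefined: all calls are missing")
    return int((g.calls == GenotypeCall.H).sum()) / non_missing


def expected_het(generation: int) -> float:
    """Expected heterozygous fraction at generation F(g) under selfing.

    The F1 is fully heterozygous and each selfing halves the expectation, so
    the value is (1/2)^(g-1).  By convention ``expected_het(1) == 1.0``.
    """
    if generation < 1:
        raise ValueError(f"generation must be >= 1, got {generation}")
    return 0.5 ** (generation - 1)


def call_category_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-line counts of each call state (columns A, B, H, MISSING)."""
    counts = np.stack([(g.calls == c).sum(axis=0) for c in GenotypeCall], axis=1)
    return pd.DataFrame(counts, index=g.lines, columns=[c.name for c in GenotypeCall])
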