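"""Single-seed-descent RIL population simulator.

The simulator produces marker-by-line genotype matrices with known ground
truth, used to validate every mapping operation in this package.  The
meiosis model is the no-interference (Poisson/Haldane) model: per gamete the
number of crossovers on a linkage group of genetic length L cM is
Poisson(L/100), crossover positions are i.i.d. uniform along the group, and
the starting homolog is a fair coin.  Lines are advanced from a fully
heterozygous F1 by selfing, carrying exactly one offspring per lineage per
generation (single-seed descent).

On top of the clean process the simulator can inject genotyping error,
missing data, per-locus viability weights (segregation distortion), a
mislabeled chromosome segment (the physical signature of a translocation),
and discrete trait scores with a mis-scoring rate.

Haplotypes are stored as founder-origin arrays (0 = parent 1, 1 = parent 2)
of shape ``(n_lines, 2, n_markers)``; genotypes follow from the per-marker
origin sum (0 -> A, 1 -> H, 2 -> B).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genotype_core import GenotypeCall, GenotypeMatrix, MarkerInfo

__all__ = [
    "LinkageGroupSpec",
    "GenomeSpec",
    "SimConfig",
    "SimPopulation",
    "TranslocationDemo",
    "uniform_genome",
    "unlinked_loci_genome",
    "translocation_demo_genome",
    "simulate_gamete",
    "simulate_ssd",
    "self_once",
    "apply_noise",
    "inject_translocation",
    "simulate_trait",
]

# origin sum (0,1,2) -> GenotypeCall code (A,H,B)
_SUM_TO_CALL = np.array(
    [GenotypeCall.A, GenotypeCall.H, GenotypeCall.B], dtype=np.int8
)


@dataclass(frozen=True)
class LinkageGroupSpec:
    """One linkage group: marker ids, genetic positions, physical labels.

    ``chrom_labels`` are the *claimed* chromosome assignments of the markers
    (e.g. from a genome assembly).  They default to the linkage-group name
    but may deliberately disagree with the simulated linkage, which always
    follows the linkage group — that disagreement is how translocation
    signatures are injected.
    """

    name: str
    marker_ids: tuple[str, ...]
    positions_cM: tuple[float, ...]
    chrom_labels: tuple[str, ...] = ()
    positions_bp: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(self.positions_cM):
            raise ValueError(f"LG {self.name}: marker ids and positions differ in length")
        pos = np.asarray(self.positions_cM, dtype=float)
        if len(pos) and np.any(np.diff(pos) < 0):
            raise ValueError(f"LG {self.name}: genetic positions must be non-decreasing")
        if not self.chrom_labels:
            object.__setattr__(self, "chrom_labels", tuple([self.name] * len(self.marker_ids)))
        if not self.positions_bp:
            # default physical coordinates: 1 cM ~ 1 Mb, 1-based
            bp = tuple(int(round(p * 1e6)) + 1 for p in self.positions_cM)
            object.__setattr__(self, "positions_bp", bp)
        if len(self.chrom_labels) != len(self.marker_ids) or len(self.positions_bp) != len(
            self.marker_ids
        ):
            raise ValueError(f"LG {self.name}: annotation fields differ in length")

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1] - self.positions_cM[0]) if self.marker_ids else 0.0


@dataclass(frozen=True)
class GenomeSpec:
    """A set of linkage groups defining the simulated genome."""

    linkage_groups: tuple[LinkageGroupSpec, ...]

    def __post_init__(self) -> None:
        names = [lg.name for lg in self.linkage_groups]
        if len(set(names)) != len(names):
            raise ValueError("linkage group names must be unique")
        ids = self.all_marker_ids
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique across the genome")

    @property
    def all_marker_ids(self) -> list[str]:
        return [m for lg in self.linkage_groups for m in lg.marker_ids]

    @property
    def n_markers(self) -> int:
        return sum(len(lg.marker_ids) for lg in self.linkage_groups)

    @property
    def truth_order(self) -> dict[str, list[str]]:
        return {lg.name: list(lg.marker_ids) for lg in self.linkage_groups}

    def lg_by_name(self, name: str) -> LinkageGroupSpec:
        for lg in self.linkage_groups:
            if lg.name == name:
                return lg
        raise ValueError(f"unknown linkage group: {name!r}")

    def marker_info(self, assembly: str = "sim") -> list[MarkerInfo]:
        """Annotation records as a mapping pipeline would receive them."""
        out = []
        for lg in self.linkage_groups:
            for mid, chrom, bp in zip(lg.marker_ids, lg.chrom_labels, lg.positions_bp):
                out.append(MarkerInfo(mid, assembly, chrom, bp))
        return out

    def positions_of(self, name: str) -> np.ndarray:
        return np.asarray(self.lg_by_name(name).positions_cM, dtype=float)


def uniform_genome(
    n_lgs: int,
    markers_per_lg: int,
    length_cM: float,
    prefix: str = "M",
    lg_names: Sequence[str] | None = None,
    bp_per_cM: float = 1e6,
) -> GenomeSpec:
    """Evenly spaced markers on ``n_lgs`` linkage groups of equal length."""
    if lg_names is None:
        lg_names = [f"LG{i + 1}" for i in range(n_lgs)]
    lgs = []
    for i, name in enumerate(lg_names):
        pos = np.linspace(0.0, length_cM, markers_per_lg)
        ids = tuple(f"{prefix}{i + 1}_{j + 1:04d}" for j in range(markers_per_lg))
        bp = tuple(int(round(p * bp_per_cM)) + 1 for p in pos)
        lgs.append(LinkageGroupSpec(name, ids, tuple(pos), positions_bp=bp))
    return GenomeSpec(tuple(lgs))


def unlinked_loci_genome(n_loci: int, prefix: str = "L") -> GenomeSpec:
    """``n_loci`` independent loci: one single-marker linkage group each."""
    lgs = tuple(
        LinkageGroupSpec(f"{prefix}{i + 1}", (f"{prefix}{i + 1}m",), (0.0,))
        for i in range(n_loci)
    )
    return GenomeSpec(lgs)


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one SSD population.

    ``distortion`` maps marker ids to per-genotype viability weights
    ``(w_A, w_H, w_B)`` in [0, 1]; each generation an offspring survives with
    probability equal to the product of the weights at its genotypes, with
    rejected offspring redrawn from the same parent (single-seed descent on
    surviving seed).
    """

    genome: GenomeSpec
    n_lines: int
    final_generation: int
    error_rate: float = 0.0
    missing_rate: float = 0.0
    distortion: Mapping[str, tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2 (F1 is the starting point)")
        for name, rate in (("error_rate", self.error_rate), ("missing_rate", self.missing_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.distortion:
            ids = set(self.genome.all_marker_ids)
            for mid, w in self.distortion.items():
                if mid not in ids:
                    raise ValueError(f"distortion weight for unknown marker {mid!r}")
                if len(w) != 3 or not all(0.0 <= x <= 1.0 for x in w):
                    raise ValueError(f"weights for {mid!r} must be three values in [0, 1]")


@dataclass
class SimPopulation:
    """Simulated genotypes plus the ground truth tests compare against."""

    genotypes: GenotypeMatrix
    genome: GenomeSpec
    haplotypes: np.ndarray  # (n_lines, 2, n_markers) founder origins, int8
    generation: int

    @property
    def truth_order(self) -> dict[str, list[str]]:
        return self.genome.truth_order

    def _lg_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for lg in self.genome.linkage_groups:
            out[lg.name] = slice(start, start + len(lg.marker_ids))
            start += len(lg.marker_ids)
        return out

    def truth_breakpoints(self) -> list[list[list[tuple[str, float]]]]:
        """Per line, per homolog: (lg name, cM) of each fixed origin switch.

        Switch positions are reported at the midpoint of the marker interval
        containing them (marker resolution is all a genotyping array sees).
        """
        slices = self._lg_slices()
        out = []
        for line in range(self.haplotypes.shape[0]):
            per_homolog = []
            for h in range(2):
                bps: list[tuple[str, float]] = []
                for lg in self.genome.linkage_groups:
                    s = slices[lg.name]
                    origins = self.haplotypes[line, h, s]
                    pos = np.asarray(lg.positions_cM)
                    switch = np.nonzero(np.diff(origins) != 0)[0]
                    for i in switch:
                        bps.append((lg.name, float((pos[i] + pos[i + 1]) / 2)))
                per_homolog.append(bps)
            out.append(per_homolog)
        return out

    def visible_crossover_counts(self) -> np.ndarray:
        """Truth crossover count per line per LG at marker resolution.

        Each origin switch on one homolog contributes 1/2 (a change into or
        out of heterozygosity); opposite switches of the two homologs in the
        same marker interval cancel, exactly as they are invisible to
        genotype-based counting.  Shape ``(n_lines, n_lgs)``.
        """
        slices = self._lg_slices()
        sums = self.haplotypes.sum(axis=1)  # (n_lines, n_markers) origin sums
        counts = np.empty((self.haplotypes.shape[0], len(self.genome.linkage_groups)))
        for j, lg in enumerate(self.genome.linkage_groups):
            s = slices[lg.name]
            counts[:, j] = np.abs(np.diff(sums[:, s], axis=1)).sum(axis=1) / 2.0
        return counts


# ---------------------------------------------------------------------------
# Meiosis


def simulate_gamete(
    parent_homolog_pair: np.ndarray,
    positions_cM: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete from a homolog pair on a single linkage group.

    ``parent_homolog_pair`` has shape ``(2, n_markers)``.  Crossover count is
    Poisson(L/100) with L the genetic length in cM; crossover positions are
    uniform on the group; the starting homolog is a fair coin.
    """
    pos = np.asarray(positions_cM, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted (non-decreasing)")
    pair = np.asarray(parent_homolog_pair)
    if pair.shape != (2, len(pos)):
        raise ValueError("parent_homolog_pair must have shape (2, n_markers)")
    start = int(rng.integers(0, 2))
    length = float(pos[-1] - pos[0]) if len(pos) else 0.0
    n_xo = int(rng.poisson(length / 100.0)) if length > 0 else 0
    if n_xo == 0:
        return pair[start].copy()
    xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_xo))
    which = (start + np.searchsorted(xo, pos, side="left")) % 2
    return pair[which, np.arange(len(pos))]


class _GenomeLayout:
    """Precomputed concatenated-marker layout for fast whole-genome gametes."""

    def __init__(self, genome: GenomeSpec):
        self.genome = genome
        self.pos = np.concatenate(
            [np.asarray(lg.positions_cM, dtype=float) for lg in genome.linkage_groups]
        )
        self.counts = np.array([len(lg.marker_ids) for lg in genome.linkage_groups])
        self.offsets = np.concatenate([[0], np.cumsum(self.counts)])
        self.lengths = np.array([lg.length_cM for lg in genome.linkage_groups])
        self.lams = self.lengths / 100.0
        self.active = np.nonzero(self.lams > 0)[0]
        self.n_lgs = len(genome.linkage_groups)
        self.n_markers = int(self.counts.sum())

    def gamete(self, pair: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One gamete across all linkage groups; ``pair`` is (2, n_markers)."""
        starts = rng.integers(0, 2, size=self.n_lgs)
        parity = np.repeat(starts, self.counts)
        if self.active.size:
            n_xo = rng.poisson(self.lams[self.active])
            for lg_i, k in zip(self.active[n_xo > 0], n_xo[n_xo > 0]):
                lo, hi = self.offsets[lg_i], self.offsets[lg_i + 1]
                p = self.pos[lo:hi]
                xo = np.sort(rng.uniform(p[0], p[-1], size=int(k)))
                parity[lo:hi] = (parity[lo:hi] + np.searchsorted(xo, p)) % 2
        which = parity % 2
        return pair[which, np.arange(self.n_markers)]


def _genotype_matrix(
    genome: GenomeSpec, haplotypes: np.ndarray, line_ids: Sequence[str]
) -> GenotypeMatrix:
    calls = _SUM_TO_CALL[haplotypes.sum(axis=1)]
    return GenotypeMatrix(genome.all_marker_ids, list(line_ids), calls.T)


def _distortion_arrays(config: SimConfig) -> tuple[np.ndarray, np.ndarray] | None:
    if not config.distortion:
        return None
    ids = config.genome.all_marker_ids
    idx = np.array([ids.index(m) for m in config.distortion])
    weights = np.array([config.distortion[ids[i]] for i in idx], dtype=float)
    return idx, weights


def _advance(
    haplotypes: np.ndarray,
    layout: _GenomeLayout,
    rng: np.random.Generator,
    distortion: tuple[np.ndarray, np.ndarray] | None,
    max_tries: int = 200,
) -> np.ndarray:
    """One round of selfing with single-seed descent for every line."""
    n_lines = haplotypes.shape[0]
    out = np.empty_like(haplotypes)
    for i in range(n_lines):
        pair = haplotypes[i]
        for _ in range(max_tries):
            child = np.stack([layout.gamete(pair, rng), layout.gamete(pair, rng)])
            if distortion is None:
                break
            idx, weights = distortion
            sums = child[:, idx].sum(axis=0)  # 0,1,2 at each weighted locus
            p = float(np.prod(weights[np.arange(len(idx)), sums]))
            if rng.uniform() < p:
                break
        out[i] = child
    return out


def simulate_ssd(config: SimConfig) -> SimPopulation:
    """Simulate an F(g) RIL population by single-seed descent.

    Starts from a fully heterozygous F1 (one homolog from each parent) and
    selfs ``final_generation - 1`` times, then reads genotypes off at the
    marker positions.  Error/missing noise from the config is applied to the
    returned genotypes; the haplotype truth is left clean.
    """
    rng = np.random.default_rng(config.seed)
    layout = _GenomeLayout(config.genome)
    n, m = config.n_lines, layout.n_markers
    haplotypes = np.zeros((n, 2, m), dtype=np.int8)
    haplotypes[:, 1, :] = 1  # F1: homolog 0 from parent 1, homolog 1 from parent 2
    distortion = _distortion_arrays(config)
    for _ in range(config.final_generation - 1):
        haplotypes = _advance(haplotypes, layout, rng, distortion)
    width = max(4, len(str(n)))
    line_ids = [f"RIL{i + 1:0{width}d}" for i in range(n)]
    pop = SimPopulation(
        genotypes=_genotype_matrix(config.genome, haplotypes, line_ids),
        genome=config.genome,
        haplotypes=haplotypes,
        generation=config.final_generation,
    )
    if config.error_rate or config.missing_rate:
        pop = apply_noise(pop, config.error_rate, config.missing_rate, rng)
    return pop


def self_once(
    pop: SimPopulation, rng: np.random.Generator, id_suffix: str = "n"
) -> tuple[SimPopulation, list[tuple[str, str]]]:
    """Advance every line one generation; returns the offspring population
    and (parent id, offspring id) pairs for matched-generation comparisons.

    ``rng`` must be a stream independent of the one that produced ``pop``:
    re-seeding with the population's own seed replays the first
    generation's meiosis draws, which artificially preserves every
    residual heterozygous site.
    """
    layout = _GenomeLayout(pop.genome)
    haplotypes = _advance(pop.haplotypes, layout, rng, None)
    ids = [f"{l}_{id_suffix}" for l in pop.genotypes.lines]
    nxt = SimPopulation(
        genotypes=_genotype_matrix(pop.genome, haplotypes, ids),
        genome=pop.genome,
        haplotypes=haplotypes,
        generation=pop.generation + 1,
    )
    return nxt, list(zip(pop.genotypes.lines, ids))


# ---------------------------------------------------------------------------
# Noise, structural injection, traits


def apply_noise(
    pop: SimPopulation,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> SimPopulation:
    """Return a copy with calls dropped to MISSING and/or mis-called.

    Each call is independently set MISSING with ``missing_rate``; each
    surviving call is replaced, with ``error_rate``, by a uniformly chosen
    *different* state among A/B/H.  Haplotype truth is untouched.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    calls = pop.genotypes.calls.copy()
    shape = calls.shape
    drop = rng.uniform(size=shape) < missing_rate
    flip = (rng.uniform(size=shape) < error_rate) & ~drop
    if flip.any():
        current = calls[flip]
        # states 0,1,2 (A,B,H); offset 1 or 2 cyclically picks a different one
        offset = rng.integers(1, 3, size=current.shape)
        wrong = (current + offset) % 3
        # calls that were MISSING stay whatever the flip lands on? No:
        # mis-calls only replace observed states; missing stays missing.
        observed = current != GenotypeCall.MISSING
        current[observed] = wrong[observed]
        calls[flip] = current
    calls[drop] = GenotypeCall.MISSING
    g = GenotypeMatrix(list(pop.genotypes.markers), list(pop.genotypes.lines), calls)
    return replace(pop, genotypes=g)


def inject_translocation(
    genome: GenomeSpec, lg_a: str, lg_b: str, breakpoint_cM: float
) -> GenomeSpec:
    """Relabel the distal segment of ``lg_a`` with ``lg_b``'s chromosome.

    Models the annotation signature of a translocation: the chromosome
    labels claim the segment sits on the other chromosome while simulated
    transmission still follows the original linkage group.  Markers of
    ``lg_a`` at positions >= ``breakpoint_cM`` receive the chromosome label
    of ``lg_b``; genetic positions, marker ids and linkage are unchanged.
    """
    spec_a = genome.lg_by_name(lg_a)
    spec_b = genome.lg_by_name(lg_b)
    if not (spec_a.positions_cM[0] <= breakpoint_cM <= spec_a.positions_cM[-1] + 1e-12):
        # a breakpoint beyond the end swaps a zero-length segment: allowed
        if breakpoint_cM < spec_a.positions_cM[0]:
            raise ValueError(
                f"breakpoint {breakpoint_cM} cM is before the start of {lg_a}"
            )
    target_label = spec_b.chrom_labels[0]
    new_labels = tuple(
        target_label if p >= breakpoint_cM else lab
        for p, lab in zip(spec_a.positions_cM, spec_a.chrom_labels)
    )
    new_a = replace(spec_a, chrom_labels=new_labels)
    lgs = tuple(new_a if lg.name == lg_a else lg for lg in genome.linkage_groups)
    return GenomeSpec(lgs)


@dataclass(frozen=True)
class TranslocationDemo:
    """A two-chromosome genome carrying one translocation signature.

    The junction region is recombination-suppressed (a block of markers at
    essentially identical genetic positions), mimicking the loss of
    recombinant progeny around a translocation breakpoint; the distal half
    of the block carries the other chromosome's label.
    """

    genome: GenomeSpec
    lg_a: str
    lg_b: str
    breakpoint_cM: float
    swapped_markers: tuple[str, ...]  # labeled on lg_b's chromosome, linked to lg_a
    partner_markers: tuple[str, ...]  # the zero-recombination partners on lg_a


def translocation_demo_genome(
    n_flank: int = 20,
    flank_spacing_cM: float = 2.0,
    block_half: int = 6,
    lg_b_markers: int = 31,
    lg_b_length: float = 60.0,
) -> TranslocationDemo:
    """Build the translocation study genome (see :class:`TranslocationDemo`).

    ``LG3`` (chromosome label chr5) carries ``n_flank`` normally spaced
    markers followed by a suppressed junction block of ``2 * block_half``
    markers spanning ~1e-6 cM at its distal end; ``LG6`` (chr1) is an
    ordinary linkage group.  The injected breakpoint falls mid-block, so the
    distal ``block_half`` markers are labeled chr1 while remaining fully
    linked to LG3.
    """
    junction = n_flank * flank_spacing_cM
    pos_a = [i * flank_spacing_cM for i in range(n_flank)]
    pos_a += [junction + i * 1e-7 for i in range(2 * block_half)]
    ids_a = tuple(f"A_{j + 1:04d}" for j in range(len(pos_a)))
    # the translocated tip's physical coordinates live at the start of the
    # partner chromosome, as a real translocated segment's would
    bp_a = [int(round(p * 1e6)) + 1 for p in pos_a[: n_flank + block_half]]
    bp_a += [200_000 + i * 50_000 for i in range(block_half)]
    lg_a = LinkageGroupSpec(
        "LG3", ids_a, tuple(pos_a), tuple(["chr5"] * len(pos_a)), tuple(bp_a)
    )
    pos_b = tuple(np.linspace(0.0, lg_b_length, lg_b_markers))
    ids_b = tuple(f"B_{j + 1:04d}" for j in range(lg_b_markers))
    lg_b = LinkageGroupSpec("LG6", ids_b, pos_b, tuple(["chr1"] * lg_b_markers))
    breakpoint = junction + (block_half - 0.5) * 1e-7
    genome = inject_translocation(GenomeSpec((lg_a, lg_b)), "LG3", "LG6", breakpoint)
    swapped = ids_a[n_flank + block_half:]
    partners = ids_a[n_flank:n_flank + block_half]
    return TranslocationDemo(genome, "LG3", "LG6", breakpoint, swapped, partners)


def simulate_trait(
    pop: SimPopulation,
    locus: str,
    misscore_rate: float,
    rng: np.random.Generator,
    dominant_parent: int | None = None,
):
    """Score a discrete trait controlled by one simulated marker.

    Homozygous lines are scored as the matching parental class.  Residual
    heterozygotes are scored as ``dominant_parent``'s class when given
    (1 or 2), else left unknown.  Each known score is then flipped to the
    other class with ``misscore_rate``.  Returns a
    :class:`~rilforge.trait_mapping.TraitVector`.
    """
    from .trait_mapping import TraitVector, P1, P2, UNKNOWN

    if not 0.0 <= misscore_rate <= 1.0:
        raise ValueError("misscore_rate must be in [0, 1]")
    calls = pop.genotypes.marker_calls(locus)
    states = np.full(len(calls), UNKNOWN, dtype=object)
    states[calls == GenotypeCall.A] = P1
    states[calls == GenotypeCall.B] = P2
    if dominant_parent is not None:
        if dominant_parent not in (1, 2):
            raise ValueError("dominant_parent must be 1 or 2")
        states[calls == GenotypeCall.H] = P1 if dominant_parent == 1 else P2
    known = states != UNKNOWN
    flip = (rng.uniform(size=len(calls)) < misscore_rate) & known
    states[flip] = np.where(states[flip] == P1, P2, P1)
    return TraitVector(
        states=dict(zip(pop.genotypes.lines, states)),
        dominant=dominant_parent is not None,
        dominant_class=(
            None if dominant_parent is None else (P1 if dominant_parent == 1 else P2)
        ),
    )
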