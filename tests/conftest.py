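"""Shared fixtures: small hand-built matrices and mid-size simulated populations."""

from __future__ import annotations

import numpy as np
import pytest

import rilforge as rf
from rilforge.genotype_core import GenotypeCall as GC


def calls_from_tokens(rows: list[str]) -> np.ndarray:
    """Build a call-code grid from rows like 'ABH-' (one char per line)."""
    lut = {"A": GC.A, "B": GC.B, "H": GC.H, "-": GC.MISSING}
    return np.array([[lut[c] for c in row] for row in rows], dtype=np.int8)


@pytest.fixture
def tiny_matrix() -> rf.GenotypeMatrix:
    """3 markers x 4 lines with one het and one missing call."""
    return rf.GenotypeMatrix(
        markers=["m1", "m2", "m3"],
        lines=["L1", "L2", "L3", "L4"],
        calls=calls_from_tokens(["AABB", "AHBB", "AB-B"]),
    )


@pytest.fixture(scope="session")
def f6_population() -> rf.SimPopulation:
    """Noiseless F6: one 100 cM linkage group, 61 markers, 400 lines."""
    genome = rf.uniform_genome(1, 61, 100.0)
    return rf.simulate_ssd(
        rf.SimConfig(genome=genome, n_lines=400, final_generation=6, seed=42)
    )


@pytest.fixture(scope="session")
def seven_lg_population() -> rf.SimPopulation:
    """Noiseless F6: 7 linkage groups x 29 markers x 50 cM, 300 lines."""
    genome = rf.uniform_genome(7, 29, 50.0)
    return rf.simulate_ssd(
        rf.SimConfig(genome=genome, n_lines=300, final_generation=6, seed=7)
    )


@pytest.fixture(scope="session")
def truth_map(f6_population) -> rf.LinkageMap:
    return rf.build_map(f6_population.truth_order, f6_population.genotypes)
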