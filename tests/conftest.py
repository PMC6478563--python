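import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from sgskit.pedigree import Individual, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sib_pedigree():
    """Founder couple with two affected children."""
    return Pedigree(
        "sibs",
        [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("c1", "F", "M", sex="male", is_case=True, is_genotyped=True),
            Individual("c2", "F", "M", sex="female", is_case=True, is_genotyped=True),
        ],
    )


@pytest.fixture
def cousin_pedigree():
    """Two first cousins through a shared grandparental couple."""
    return Pedigree(
        "cousins",
        [
            Individual("GF", sex="male"),
            Individual("GM", sex="female"),
            Individual("A", "GF", "GM", sex="male"),
            Individual("B", "GF", "GM", sex="female"),
            Individual("SA", sex="female"),
            Individual("SB", sex="male"),
            Individual("c1", "A", "SA", is_case=True, is_genotyped=True),
            Individual("c2", "SB", "B", is_case=True, is_genotyped=True),
        ],
    )


@pytest.fixture
def avuncular_pedigree():
    """Uncle and nephew (through the uncle's sibling)."""
    return Pedigree(
        "avunc",
        [
            Individual("GF", sex="male"),
            Individual("GM", sex="female"),
            Individual("U", "GF", "GM", sex="male", is_case=True),
            Individual("B", "GF", "GM", sex="female"),
            Individual("SB", sex="male"),
            Individual("n", "SB", "B", is_case=True),
        ],
    )


def sibship_pedigree(k: int, affected: int | None = None) -> Pedigree:
    """One founder couple with k children; the first ``affected`` are
    genotyped cases (all by default)."""
    if affected is None:
        affected = k
    inds = [Individual("F", sex="male"), Individual("M", sex="female")]
    for i in range(k):
        inds.append(
            Individual(
                f"c{i}", "F", "M",
                is_case=i < affected, is_genotyped=i < affected,
            )
        )
    return Pedigree("sibship", inds)
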