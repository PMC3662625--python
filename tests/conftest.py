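"""Shared fixtures: all test structures are generated, never stored."""

from __future__ import annotations

import pytest

from ligfam.synthconf import (
    ConformerSpec,
    PocketEntry,
    PocketSpec,
    make_conformer,
    make_pocket,
)
from ligfam.topology import LadderPair, SecondaryStructureAnnotation, StrandElement


@pytest.fixture(scope="session")
def sam_conformer():
    """A mid-wheel SAM conformer used across modules."""
    return make_conformer(ConformerSpec(P=18.0, Vmax=40.0, chi=-60.0, gamma=75.0, delta=180.0))


@pytest.fixture(scope="session")
def sah_conformer():
    return make_conformer(ConformerSpec(ligand_code="SAH"))


@pytest.fixture(scope="session")
def standard_pocket(sam_conformer):
    """Pocket with three constructed contacts and twenty decoy carbons."""
    spec = PocketSpec(
        entries=(
            PocketEntry("N6", "ASP", "OD1", 2.9),
            PocketEntry("O2'", "GLU", "OE1", 3.1),
            PocketEntry("N1", "SER", "OG", 3.0),
        ),
        decoy_atoms=20,
        seed=7,
    )
    return make_pocket(sam_conformer, spec)


def ladder_chain(order: list[int], antiparallel: set[int] | None = None) -> SecondaryStructureAnnotation:
    """Independent permutation-to-graph oracle: consecutive spatial
    neighbours in ``order`` become ladder pairs."""
    n = len(order)
    antiparallel = antiparallel or set()
    elements = [StrandElement("A", 10 * k, 10 * k + 5) for k in range(1, n + 1)]
    ladders = [
        LadderPair(
            order[i],
            order[i + 1],
            "antiparallel" if order[i + 1] in antiparallel else "parallel",
        )
        for i in range(n - 1)
    ]
    return SecondaryStructureAnnotation(elements=elements, ladders=ladders)


@pytest.fixture
def chain_oracle():
    return ladder_chain
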