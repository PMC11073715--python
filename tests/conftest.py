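"""Shared fixtures: one default synthetic world and its derived tables.

Session-scoped so the expensive generation + calling happens once.
"""

from __future__ import annotations

import pytest

from lnct3d import rnachrom as rc
from lnct3d import synthetic as syn

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world() -> syn.SyntheticWorld:
    return syn.generate_world(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def genes(world) -> dict[str, syn.GeneModel]:
    return {g.gene_id: g for g in world.genes}


@pytest.fixture(scope="session")
def contacts(world):
    return syn.simulate_contacts(world)


@pytest.fixture(scope="session")
def called(world, genes, contacts):
    """Full calling chain on the default world: (binned, background, sig)."""
    surviving, _ = rc.filter_nascent(contacts, genes)
    binned = rc.bin_contacts(surviving, genes)
    background = rc.estimate_background(binned)
    sig = rc.iterative_binomial_caller(binned, background, scope="intra")
    return binned, background, sig


@pytest.fixture(scope="session")
def hic_table(world):
    return syn.simulate_hic(world)
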