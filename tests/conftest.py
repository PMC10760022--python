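import numpy as np
import pytest

import nestor_lite as nl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_chain_specs():
    return [nl.ChainSpec("A", 30), nl.ChainSpec("B", 20, rigid_body="body1")]


@pytest.fixture
def small_topology(two_chain_specs):
    return nl.build_representation(two_chain_specs, 10)


@pytest.fixture
def small_model(small_topology, rng):
    return nl.initialize_model(small_topology, rng)


@pytest.fixture
def two_bead_topology():
    """One 10-residue chain as two 5-residue beads: the minimal flexible system."""
    return nl.build_representation([nl.ChainSpec("A", 10)], 5)


@pytest.fixture
def place_beads():
    """Factory: StructureModel at explicit coordinates."""

    def _place(topology, coords):
        return nl.StructureModel(np.asarray(coords, dtype=float), topology)

    return _place


@pytest.fixture
def crosslinks_ten():
    return [nl.Crosslink("A", i + 1, "B", i + 1) for i in range(10)]
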