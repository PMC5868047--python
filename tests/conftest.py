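import numpy as np
import pytest

from anisoverify.datasets import (load_assignments, load_caulamidine_a,
                                  load_correlations)
from anisoverify.graph import Atom, MoleculeGraph


@pytest.fixture(scope="session")
def caulamidine():
    return load_caulamidine_a()


@pytest.fixture(scope="session")
def assignments():
    return load_assignments()


@pytest.fixture(scope="session")
def correlations():
    return {cs.experiment.value: cs for cs in load_correlations()}


@pytest.fixture(scope="session")
def benzene():
    """C6H6 with labels '1'..'6' on the ring carbons (no coordinates)."""
    atoms = [Atom(i, "C", str(i + 1)) for i in range(6)]
    atoms += [Atom(6 + i, "H") for i in range(6)]
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    bonds += [(i, 6 + i, 1.0) for i in range(6)]
    return MoleculeGraph(atoms, bonds, {str(i + 1): i for i in range(6)},
                         name="benzene")


@pytest.fixture(scope="session")
def decoy_set(caulamidine):
    """True structure + constitutional/configurational decoys + enantiomer,
    each with its own independently modelled conformer where appropriate."""
    from anisoverify.synth import gen_decoys, reembed

    g = caulamidine
    swap = reembed(gen_decoys(g, "swap_halogen_positions",
                              carbons=("7", "6"))[0], seed=17)
    epi11 = gen_decoys(g, "invert_stereocenters", seed=11, centers=["11"])[0]
    epi_ring = gen_decoys(g, "invert_stereocenters", seed=13,
                          centers=["10", "23"])[0]
    ent = gen_decoys(g, "mirror_all")[0]
    return {"true": g, "constitutional": swap, "epi11": epi11,
            "epi_ring": epi_ring, "enantiomer": ent}
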