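import numpy as np
import pytest

from mitoarbor.morphology import NeuronMorphology, Node, Structure

S = Structure.SOMA
D = Structure.DENDRITE_BASAL
A = Structure.AXON


def build_morphology(rows, soma_center=None):
    """rows: (id, structure, x, y, z, radius, parent_id) tuples."""
    return NeuronMorphology([Node(*r) for r in rows], soma_center=soma_center)


@pytest.fixture
def straight_cable():
    """10 collinear dendrite nodes spaced 5 μm; 45 μm of cable from the root."""
    rows = [(1, D, 0.0, 0.0, 0.0, 0.5, None)]
    for i in range(1, 10):
        rows.append((i + 1, D, 5.0 * i, 0.0, 0.0, 0.5, i))
    return build_morphology(rows, soma_center=(0.0, 0.0, 0.0))


@pytest.fixture
def binary_tree_depth3():
    """Soma plus a complete binary dendritic tree with 3 branchpoints."""
    rows = [
        (1, S, 0.0, 0.0, 0.0, 2.0, None),
        (2, D, 10.0, 0.0, 0.0, 1.0, 1),   # branchpoint (root of tree)
        (3, D, 20.0, 10.0, 0.0, 1.0, 2),  # branchpoint
        (4, D, 20.0, -10.0, 0.0, 1.0, 2), # branchpoint
        (5, D, 30.0, 15.0, 0.0, 1.0, 3),
        (6, D, 30.0, 5.0, 0.0, 1.0, 3),
        (7, D, 30.0, -5.0, 0.0, 1.0, 4),
        (8, D, 30.0, -15.0, 0.0, 1.0, 4),
    ]
    return build_morphology(rows, soma_center=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20160904)
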