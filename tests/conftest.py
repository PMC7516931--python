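"""Shared fixtures: small reference graphs and fields used across modules."""

import numpy as np
import pytest

from tmfields import (
    BINARY,
    GibbsField,
    JointTable,
    MultilayerGraph,
    NodeId,
    PotentialSet,
)

# Vertices of the 4-variable, 2-layer reference graph (labels I / II).
X2I = NodeId(1, 0)
X3I = NodeId(2, 0)
X4I = NodeId(3, 0)
X3II = NodeId(2, 1)
X4II = NodeId(3, 1)


@pytest.fixture
def two_layer_graph() -> MultilayerGraph:
    """4 variables x 2 layers: an intra-layer triangle {X2I,X3I,X4I} plus the
    inter-layer coupling {X3I,X3II}."""
    return MultilayerGraph.from_edges(
        4, 2, [(X2I, X3I), (X3I, X4I), (X2I, X4I), (X3I, X3II)]
    )


@pytest.fixture
def chain_field() -> GibbsField:
    """Binary chain u - v - w on a 3-variable single layer, attractive pairs."""
    u, v, w = NodeId(0, 0), NodeId(1, 0), NodeId(2, 0)
    g = MultilayerGraph.from_edges(3, 1, [(u, v), (v, w)])
    attract = np.exp(np.array([[1.0, -1.0], [-1.0, 1.0]]))
    return GibbsField(g, BINARY, PotentialSet({(u, v): attract, (v, w): attract}))


def random_joint(n_vertices: int, seed: int, n_labels: int = 2) -> JointTable:
    """Strictly positive random joint table on a single-layer vertex row."""
    rng = np.random.default_rng(seed)
    shape = (n_labels,) * n_vertices
    w = rng.gamma(2.0, size=shape) + 0.05
    verts = tuple(NodeId(i, 0) for i in range(n_vertices))
    from tmfields import LabelSet

    labels = BINARY if n_labels == 2 else LabelSet(tuple(range(n_labels)))
    return JointTable.from_unnormalized(verts, labels, w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
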