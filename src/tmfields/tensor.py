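"""Adjacency-tensor views and multilayer degree centralities.

The 4-index hypermatrix A[i,j,h,k] (variable i in layer h linked to variable
j in layer k) is treated directly as the multilayer adjacency tensor: the
embedding that would pair it with a unit 4-tensor carries no independent
data, so contractions are implemented as plain index sums.

    K[i]      = sum_{j,h,k} A[i,j,h,k]      multidegree centrality
    k[i](h,k) = sum_j A[i,j,h,k]            layer-pair degree

and K = sum_{h,k} k(h,k) holds identically.  Round-trip conversions between
hypermatrices and MultilayerGraph edge sets live here too.
"""

from __future__ import annotations

import numpy as np

from .graph import MultilayerGraph, NodeId, canon_edge
from .mi import Hypermatrix


def multidegree_centrality(a: Hypermatrix) -> np.ndarray:
    """K[i]: full contraction over the partner variable and both layer indices.

    For a binary tensor each undirected edge contributes 1 to each endpoint's
    variable total; weighted tensors yield strength totals.
    """
    return a.values.sum(axis=(1, 2, 3))


def layer_pair_degree(a: Hypermatrix, h: int, k: int) -> np.ndarray:
    """k[i](h,k): connections of variable i in layer h to any variable in layer k."""
    nl = a.n_layers
    if not (0 <= h < nl and 0 <= k < nl):
        raise IndexError(f"layer pair ({h},{k}) outside [0,{nl})")
    return a.values[:, :, h, k].sum(axis=1)


def neighborhood_size(a: Hypermatrix, v: NodeId) -> int:
    """|N_{X_ih}| = |mb(X_ih)|: the degree of one vertex, from a binary tensor."""
    if a.weighted:
        raise ValueError("neighborhood sizes are counts; use a binary tensor")
    v = NodeId(*v)
    if not (0 <= v.var < a.n_vars and 0 <= v.layer < a.n_layers):
        raise IndexError(f"vertex {v} outside the tensor's grid")
    return int(a.values[v.var, :, v.layer, :].sum())


def hypermatrix_from_graph(g: MultilayerGraph) -> Hypermatrix:
    """Encode an edge set as a binary 4-index adjacency hypermatrix."""
    m = np.zeros((g.n_vars, g.n_vars, g.n_layers, g.n_layers))
    for u, v in g.edges:
        m[u.var, v.var, u.layer, v.layer] = 1.0
        m[v.var, u.var, v.layer, u.layer] = 1.0
    return Hypermatrix(m, weighted=False)


def graph_from_hypermatrix(a: Hypermatrix) -> MultilayerGraph:
    """Decode the nonzero pattern of a binary hypermatrix into an edge set.

    Inverse of :func:`hypermatrix_from_graph`; validation of symmetry and the
    zero bi-diagonal happens in the Hypermatrix constructor.
    """
    if a.weighted:
        raise ValueError("graph extraction requires a binary adjacency tensor")
    edges = set()
    for i, j, h, k in zip(*np.nonzero(a.values)):
        edges.add(canon_edge(NodeId(int(i), int(h)), NodeId(int(j), int(k))))
    return MultilayerGraph(a.n_vars, a.n_layers, frozenset(edges))
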