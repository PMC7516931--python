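"""Clique potentials from positive joints: the constructive Hammersley-Clifford step.

Given any strictly positive joint P over the vertices of a multilayer graph,
the Moebius inclusion-exclusion construction defines, for every vertex subset
sigma, a candidate potential

    f_sigma(x_sigma) = prod_{zeta subseteq sigma}
                       P(X_zeta = x_zeta, X_rest = default) ^ ((-1)^(|sigma|-|zeta|))

where "default" pins every vertex outside zeta to the designated default
label.  Two facts make these proper clique potentials:

(i)  the product of f_sigma over *all* subsets telescopes back to P exactly
     (an inclusion-exclusion identity, true for any positive P);
(ii) if P is Markov with respect to a graph G, then f_sigma == 1 for every
     sigma that is not a clique of G.

Both facts are implemented here as machine checks, alongside minimal-I-map
construction (the graph whose edges are exactly the conditionally dependent
pairs given everything else).  All products are accumulated in log space with
integer sign bookkeeping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .errors import CapacityError, PositivityError
from .gibbs import JointTable
from .graph import MultilayerGraph, NodeId, canon_key

#: Largest subset for a single candidate potential.
MAX_SUBSET = 20
#: Largest vertex count for whole-lattice verification (2^|V| subsets).
MAX_VERIFY_VERTICES = 10
#: Strict positivity floor; below this the theorem's hypothesis fails.
POSITIVITY_FLOOR = 1e-300

#: Default tolerances: exact-arithmetic identities vs CI classification.
TOL_IDENTITY = 1e-8
TOL_CI = 1e-6


def _check_positive(p: JointTable) -> None:
    if float(p.probs.min()) <= POSITIVITY_FLOOR:
        raise PositivityError(
            "joint table is not strictly positive (min entry "
            f"{float(p.probs.min()):.3e}); the Moebius construction requires "
            "a strictly positive measure"
        )


def _log_candidate(
    log_p: np.ndarray, axes: Tuple[int, ...], n: int, d: int
) -> np.ndarray:
    """log f_sigma as an array over the restricted configurations of sigma.

    ``axes`` are the global joint-table axes of sigma's vertices (ascending);
    ``d`` is the default label index.  Implements the inclusion-exclusion sum
    over all zeta subseteq sigma directly: each term is a slice of log P with
    every axis outside zeta pinned to the default.
    """
    m = len(axes)
    out = np.zeros((log_p.shape[0],) * m)
    for r in range(m + 1):
        sign = 1 if (m - r) % 2 == 0 else -1
        for zeta_local in itertools.combinations(range(m), r):
            zeta_global = {axes[i] for i in zeta_local}
            # Full index over all n axes: free on zeta, default elsewhere.
            index = tuple(
                slice(None) if a in zeta_global else d for a in range(n)
            )
            term = log_p[index]
            missing = tuple(i for i in range(m) if i not in zeta_local)
            if missing:
                term = np.expand_dims(term, axis=missing)
            out = out + sign * term
    return out


@dataclass
class CandidatePotential:
    """Moebius candidate potential f_sigma on a vertex subset."""

    vertices: Tuple[NodeId, ...]
    values: np.ndarray  # shape (k,)*|sigma|, strictly positive

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values)


def moebius_potential(
    p: JointTable,
    sigma: Iterable[NodeId],
    default=None,
    max_subset: int = MAX_SUBSET,
) -> CandidatePotential:
    """Candidate potential f_sigma by inclusion-exclusion over subsets of sigma."""
    _check_positive(p)
    verts = tuple(sorted((NodeId(*v) for v in sigma), key=canon_key))
    if len(verts) > max_subset:
        raise CapacityError(
            f"candidate potential on {len(verts)} vertices exceeds guard {max_subset}"
        )
    for v in verts:
        if v not in p.vertices:
            raise IndexError(f"{v} is not a vertex of the joint table")
    d = p.labels.default_index if default is None else p.labels.index(default)
    axes = tuple(p.axis(v) for v in verts)
    log_f = _log_candidate(np.log(p.probs), axes, len(p.vertices), d)
    return CandidatePotential(verts, np.exp(log_f))


@dataclass
class FactorizationReport:
    """Outcome of checking prod_sigma f_sigma == P over every configuration."""

    ok: bool
    max_rel_error: float
    worst_index: Tuple[int, ...]

    def __bool__(self) -> bool:
        return self.ok


def verify_factorization(
    p: JointTable,
    default=None,
    tol: float = TOL_IDENTITY,
    max_vertices: int = MAX_VERIFY_VERTICES,
) -> FactorizationReport:
    """Check condition (i): the product of all candidate potentials rebuilds P.

    Enumerates all 2^|V| subsets, so it is guarded on vertex count.  Reports
    the maximum relative deviation |prod f / P - 1| over configurations.
    """
    _check_positive(p)
    n = len(p.vertices)
    if n > max_vertices:
        raise CapacityError(
            f"factorization check enumerates 2^{n} subsets; guard is {max_vertices} vertices"
        )
    d = p.labels.default_index if default is None else p.labels.index(default)
    log_p = np.log(p.probs)
    total = np.zeros_like(log_p)
    for r in range(n + 1):
        for axes in itertools.combinations(range(n), r):
            log_f = _log_candidate(log_p, axes, n, d)
            missing = tuple(a for a in range(n) if a not in axes)
            if missing:
                log_f = np.expand_dims(log_f, axis=missing)
            total = total + log_f
    rel = np.abs(np.expm1(total - log_p))
    worst = np.unravel_index(int(rel.argmax()), rel.shape)
    return FactorizationReport(bool(rel.max() < tol), float(rel.max()), worst)


@dataclass
class CliqueSupportReport:
    """Outcome of checking f_sigma == 1 on every non-clique sigma."""

    ok: bool
    max_deviation: float
    worst_subset: Optional[Tuple[NodeId, ...]]
    worst_index: Optional[Tuple[int, ...]]

    def __bool__(self) -> bool:
        return self.ok


def verify_clique_support(
    p: JointTable,
    g: MultilayerGraph,
    default=None,
    tol: float = TOL_IDENTITY,
    max_vertices: int = MAX_VERIFY_VERTICES,
) -> CliqueSupportReport:
    """Check condition (ii): non-clique candidate potentials are unity.

    Meaningful when ``p`` is Markov with respect to ``g`` (e.g. built from a
    Gibbs field on ``g``); a non-Markov joint simply yields ``ok=False`` with
    the worst offending subset.
    """
    _check_positive(p)
    n = len(p.vertices)
    if n > max_vertices:
        raise CapacityError(
            f"clique-support check enumerates 2^{n} subsets; guard is {max_vertices} vertices"
        )
    if tuple(g.vertices) != tuple(p.vertices):
        raise ValueError("graph and joint table have different vertex sets")
    d = p.labels.default_index if default is None else p.labels.index(default)
    log_p = np.log(p.probs)
    worst_dev = 0.0
    worst_subset = None
    worst_index = None
    verts = p.vertices
    for r in range(2, n + 1):
        for axes in itertools.combinations(range(n), r):
            subset = tuple(verts[a] for a in axes)
            if g.is_clique(subset):
                continue
            f = np.exp(_log_candidate(log_p, axes, n, d))
            dev = np.abs(f - 1.0)
            if float(dev.max()) > worst_dev:
                worst_dev = float(dev.max())
                worst_subset = subset
                worst_index = np.unravel_index(int(dev.argmax()), dev.shape)
    return CliqueSupportReport(worst_dev < tol, worst_dev, worst_subset, worst_index)


def ci_graph_from_joint(
    p: JointTable,
    tol: float = TOL_CI,
    n_vars: int | None = None,
    n_layers: int | None = None,
) -> MultilayerGraph:
    """The minimal I-map of a strictly positive joint.

    Draws an edge {u, v} exactly when u and v are NOT conditionally
    independent given all remaining vertices (pairwise Markov construction;
    under positivity the resulting graph satisfies the global Markov property
    with respect to ``p``).
    """
    from .ci import ci_given_rest

    _check_positive(p)
    if n_vars is None:
        n_vars = 1 + max(v.var for v in p.vertices)
    if n_layers is None:
        n_layers = 1 + max(v.layer for v in p.vertices)
    edges = []
    for u, v in itertools.combinations(p.vertices, 2):
        stmt = ci_given_rest(p, u, v, tol=tol)
        if not stmt.holds:
            edges.append((u, v))
    return MultilayerGraph.from_edges(n_vars, n_layers, edges)
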