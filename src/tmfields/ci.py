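"""Conditional kernels and conditional-independence testing.

Exact CI on joint tables uses the cross-multiplied product form

    u independent of v given S  <=>
    P(u, v, S) * P(S)  ==  P(u, S) * P(v, S)   for every configuration,

which avoids dividing by small marginals; the reported deviation is the
normalized |P(uvS)P(S) - P(uS)P(vS)| / P(S)^2.  Empirical CI on sample data
uses plug-in conditional mutual information with a stratified permutation
null.  I-map and perfect-map checks connect graph separation with the CI
relations of a distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .errors import CapacityError
from .gibbs import JointTable
from .graph import MultilayerGraph, NodeId, canon_key

TOL_CI = 1e-6
#: Largest vertex count for exhaustive global-Markov (I-map) checking.
MAX_IMAP_VERTICES = 10


def _canon(subset: Iterable[NodeId]) -> Tuple[NodeId, ...]:
    return tuple(sorted((NodeId(*v) for v in subset), key=canon_key))


def expand_marginal(
    arr: np.ndarray, sub: Tuple[NodeId, ...], full: Tuple[NodeId, ...]
) -> np.ndarray:
    """Broadcast a marginal over ``sub`` against the axes of ``full``.

    Both tuples must be canonically ordered with ``sub`` a subsequence of
    ``full``; inserts singleton axes for the missing vertices.
    """
    subset = set(sub)
    missing = tuple(i for i, v in enumerate(full) if v not in subset)
    return np.expand_dims(arr, axis=missing) if missing else arr


@dataclass
class ConditionalKernel:
    """Conditional table C_A(B) = P(B | A) from exact marginals.

    ``probs`` carries one axis per vertex of ``given`` + ``target`` in
    canonical order; summing over the target axes gives 1 for every
    conditioning configuration.
    """

    given: Tuple[NodeId, ...]
    target: Tuple[NodeId, ...]
    probs: np.ndarray

    @property
    def vertices(self) -> Tuple[NodeId, ...]:
        return _canon(self.given + self.target)


def conditional_kernel(
    p: JointTable, given: Iterable[NodeId], target: Iterable[NodeId]
) -> ConditionalKernel:
    """C_given(target) = P(given, target) / P(given), by exact summation."""
    a = _canon(given)
    b = _canon(target)
    if set(a) & set(b):
        raise ValueError("conditioning and target sets must be disjoint")
    union = _canon(a + b)
    joint = p.marginal(union)
    marg = p.marginal(a)
    return ConditionalKernel(a, b, joint / expand_marginal(marg, a, union))


@dataclass
class CIStatement:
    """Outcome of one conditional-independence query.

    ``max_deviation`` is the exact normalized product-form deviation for joint
    tables, or the conditional-MI estimate (bits) for empirical tests.
    """

    left: NodeId
    right: NodeId
    given: Tuple[NodeId, ...]
    holds: bool
    max_deviation: float


def set_ci_deviation(
    p: JointTable,
    a: Iterable[NodeId],
    b: Iterable[NodeId],
    c: Iterable[NodeId],
) -> float:
    """max |P(ABC)P(C) - P(AC)P(BC)| / P(C)^2 over all configurations."""
    sa, sb, sc = _canon(a), _canon(b), _canon(c)
    if set(sa) & set(sb) or set(sa) & set(sc) or set(sb) & set(sc):
        raise ValueError("A, B, C must be pairwise disjoint")
    full = _canon(sa + sb + sc)
    p_abc = p.marginal(full)
    p_c = expand_marginal(p.marginal(sc), sc, full)
    p_ac = expand_marginal(p.marginal(_canon(sa + sc)), _canon(sa + sc), full)
    p_bc = expand_marginal(p.marginal(_canon(sb + sc)), _canon(sb + sc), full)
    dev = np.abs(p_abc * p_c - p_ac * p_bc) / p_c**2
    return float(dev.max())


def ci_given_set(
    p: JointTable,
    u: NodeId,
    v: NodeId,
    s: Iterable[NodeId] = (),
    tol: float = TOL_CI,
) -> CIStatement:
    """Is u independent of v given the set ``s``, in the exact joint ``p``?"""
    u, v = NodeId(*u), NodeId(*v)
    s = _canon(s)
    if u == v or u in s or v in s:
        raise ValueError("u, v must be distinct and outside the conditioning set")
    dev = set_ci_deviation(p, (u,), (v,), s)
    return CIStatement(u, v, s, dev < tol, dev)


def ci_given_rest(
    p: JointTable, u: NodeId, v: NodeId, tol: float = TOL_CI
) -> CIStatement:
    """Pairwise CI of u, v given every other vertex of the joint."""
    u, v = NodeId(*u), NodeId(*v)
    rest = tuple(w for w in p.vertices if w not in (u, v))
    return ci_given_set(p, u, v, rest, tol)


def count_pairwise_tests(n_vars: int, n_layers: int) -> int:
    """Number of unordered vertex pairs, binom(N*L, 2): one CI test per pair."""
    if n_vars < 1 or n_layers < 1:
        raise ValueError("n_vars and n_layers must be >= 1")
    m = n_vars * n_layers
    return m * (m - 1) // 2


@dataclass
class IMapReport:
    """Outcome of a global-Markov (I-map) check."""

    ok: bool
    mode: str  # "full" or "reduced"
    counterexample: Optional[Tuple[Tuple[NodeId, ...], Tuple[NodeId, ...], Tuple[NodeId, ...]]]
    max_deviation: float
    n_checked: int

    def __bool__(self) -> bool:
        return self.ok


def is_independence_map(
    g: MultilayerGraph,
    p: JointTable,
    tol: float = TOL_CI,
    max_vertices: int = MAX_IMAP_VERTICES,
) -> IMapReport:
    """Does every separation of ``g`` correspond to a CI relation of ``p``?

    Full mode (up to ``max_vertices`` vertices) enumerates every separator set
    C and, for each, every bipartition of the connected components of G - C
    into two nonempty sides A and B.  Because conditional independence is
    closed under taking subsets of A and B (decomposition), this certifies the
    global Markov property for *every* separated triple.  Beyond the guard a
    reduced check is used — all pairwise CI for non-edges plus all
    single-vertex separators — and labeled as such.
    """
    if tuple(g.vertices) != tuple(p.vertices):
        raise ValueError("graph and joint table have different vertex sets")
    verts = g.vertices
    n = len(verts)
    worst = 0.0
    checked = 0
    if n <= max_vertices:
        mode = "full"
        for r in range(n - 1):
            for c in itertools.combinations(verts, r):
                comps = g.connected_components_without(c)
                m = len(comps)
                if m < 2:
                    continue
                # Bipartitions of components; component 0 stays on side A.
                for mask in range(1, 2 ** (m - 1)):
                    a: list = []
                    b: list = []
                    for i, comp in enumerate(comps):
                        if i > 0 and (mask >> (i - 1)) & 1:
                            b.extend(comp)
                        else:
                            a.extend(comp)
                    if not b:
                        continue
                    dev = set_ci_deviation(p, a, b, c)
                    checked += 1
                    worst = max(worst, dev)
                    if dev >= tol:
                        return IMapReport(
                            False, mode, (_canon(a), _canon(b), _canon(c)), dev, checked
                        )
    else:
        mode = "reduced"
        for u, v in itertools.combinations(verts, 2):
            if g.has_edge(u, v):
                continue
            stmt = ci_given_rest(p, u, v, tol)
            checked += 1
            worst = max(worst, stmt.max_deviation)
            if not stmt.holds:
                rest = tuple(w for w in verts if w not in (u, v))
                return IMapReport(False, mode, ((u,), (v,), rest), stmt.max_deviation, checked)
        for c in verts:
            comps = g.connected_components_without((c,))
            m = len(comps)
            for mask in range(1, 2 ** (m - 1)):
                a, b = [], []
                for i, comp in enumerate(comps):
                    if i > 0 and (mask >> (i - 1)) & 1:
                        b.extend(comp)
                    else:
                        a.extend(comp)
                if not b:
                    continue
                dev = set_ci_deviation(p, a, b, (c,))
                checked += 1
                worst = max(worst, dev)
                if dev >= tol:
                    return IMapReport(False, mode, (_canon(a), _canon(b), (c,)), dev, checked)
    return IMapReport(True, mode, None, worst, checked)


def is_perfect_map(
    g: MultilayerGraph, p: JointTable, tol: float = TOL_CI
) -> bool:
    """True iff ``g`` is an I-map of ``p`` and equals the minimal I-map of ``p``."""
    from .hammersley import ci_graph_from_joint

    if not is_independence_map(g, p, tol).ok:
        return False
    minimal = ci_graph_from_joint(p, tol, n_vars=g.n_vars, n_layers=g.n_layers)
    return minimal.edges == g.edges


# ---------------------------------------------------------------------------
# Empirical CI on sample data


def _codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    from .mi import discretize

    x = np.asarray(x)
    if np.issubdtype(x.dtype, np.floating):
        return discretize(x, n_bins)
    _, inv = np.unique(x, return_inverse=True)
    return inv


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> float:
    """Plug-in conditional MI I(x; y | z) in bits over discrete codes.

    ``z`` is a single stratum code vector (combine several conditioning
    columns beforehand).  Strata observed only once carry no information and
    contribute zero; a warning records their presence.
    """
    from .mi import mutual_information

    n = len(x)
    total = 0.0
    thin = 0
    for zv in np.unique(z):
        m = z == zv
        cnt = int(m.sum())
        if cnt < 2:
            thin += 1
            continue
        total += (cnt / n) * mutual_information(x[m], y[m])
    if thin:
        warnings.warn(
            f"{thin} conditioning stratum(s) with fewer than 2 samples skipped",
            stacklevel=2,
        )
    return total


def empirical_ci_test(
    data,
    u: NodeId,
    v: NodeId,
    s: Iterable[NodeId] = (),
    n_bins: int = 10,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed=0,
    max_given: int = 3,
) -> CIStatement:
    """Permutation CI test on sample data: I(u; v | s) against a stratified null.

    ``data`` is a SampleTensor (or a raw (samples, vars, layers) array).  The
    target column is permuted within strata of the conditioning columns to
    build the null; ``holds`` is True iff the observed conditional MI falls
    below the (1 - alpha) null quantile.  The conditioning set is capped at
    ``max_given`` vertices so strata stay populated.
    """
    values = np.asarray(getattr(data, "values", data))
    u, v = NodeId(*u), NodeId(*v)
    s = _canon(s)
    if len(s) > max_given:
        raise CapacityError(
            f"conditioning on {len(s)} vertices exceeds the guard {max_given}"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x = _codes(values[:, u.var, u.layer], n_bins)
    y = _codes(values[:, v.var, v.layer], n_bins)
    if s:
        zcols = [_codes(values[:, w.var, w.layer], n_bins) for w in s]
        z = zcols[0].copy()
        for col in zcols[1:]:
            z = z * (col.max() + 1) + col
    else:
        z = np.zeros(len(x), dtype=np.int64)
    observed = conditional_mutual_information(x, y, z)
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(z == zv) for zv in np.unique(z)]
    null = np.empty(n_perm)
    y_perm = y.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in range(n_perm):
            for idx in strata:
                y_perm[idx] = y[idx][rng.permutation(len(idx))]
            null[t] = conditional_mutual_information(x, y_perm, z)
    threshold = float(np.quantile(null, 1.0 - alpha))
    return CIStatement(u, v, s, bool(observed < threshold), float(observed))
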