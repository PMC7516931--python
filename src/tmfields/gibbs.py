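"""Exact Gibbs fields on small multilayer graphs.

A Gibbs field attaches a strictly positive potential phi_C to cliques of a
multilayer graph and defines the joint measure

    P(omega) = (1/Z) * prod_C phi_C(omega_C),        Z = sum_omega prod_C phi_C

with the product over all cliques (a *nearest-neighbor Gibbs potential*: any
subset that is not a clique carries the constant potential 1).  Equivalently,
with the dimensionless energy U(omega) = -sum_C log phi_C(omega_C),
P = exp(-U)/Z.  Everything here is exact: joints, marginals and conditionals
are computed by full enumeration of the configuration space S^(N*L), guarded
by a capacity limit.  Products of potentials are accumulated in log space.

An approximate single-site heat-bath sampler is provided for fields above the
enumeration guard; it is meant for fixture generation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, Iterable, Mapping, Tuple

import numpy as np

from .errors import CapacityError, PositivityError
from .graph import MultilayerGraph, NodeId, canon_key

#: Largest configuration space the exact operations will enumerate.
MAX_CONFIGURATIONS = 2**20

#: A configuration is a total assignment vertex -> label.
Configuration = Dict[NodeId, Any]


@dataclass(frozen=True)
class LabelSet:
    """Ordered finite label set S with a designated default ("zero") label.

    The default label plays the role of the reference state pinned by the
    Moebius clique-potential construction.
    """

    labels: Tuple[Any, ...]
    default: Any = None

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a label set needs at least two labels")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be distinct")
        if self.default is None:
            object.__setattr__(self, "default", labels[0])
        if self.default not in labels:
            raise ValueError("default label must be a member of the label set")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: Any) -> int:
        return self.labels.index(label)

    @property
    def default_index(self) -> int:
        return self.labels.index(self.default)


BINARY = LabelSet((0, 1))


def _canon_subset(subset: Iterable[NodeId]) -> Tuple[NodeId, ...]:
    return tuple(sorted((NodeId(*v) for v in subset), key=canon_key))


@dataclass
class PotentialSet:
    """Strictly positive clique potentials, stored as dense small tables.

    ``tables`` maps a canonically sorted vertex tuple to an array with one
    axis per vertex (in that order) and one entry per label, holding phi
    values.  Subsets with no entry implicitly carry the constant potential 1.
    """

    tables: Dict[Tuple[NodeId, ...], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: Dict[Tuple[NodeId, ...], np.ndarray] = {}
        for subset, table in self.tables.items():
            key = _canon_subset(subset)
            arr = np.asarray(table, dtype=float)
            if arr.ndim != len(key):
                raise ValueError(
                    f"potential on {key} must have {len(key)} axes, got {arr.ndim}"
                )
            if np.any(arr <= 0):
                raise PositivityError(f"potential on {key} has non-positive entries")
            canon[key] = arr
        self.tables = canon

    def items(self):
        return self.tables.items()

    def subsets(self):
        return self.tables.keys()

    def __getitem__(self, subset) -> np.ndarray:
        return self.tables[_canon_subset(subset)]


@dataclass
class GibbsField:
    """A multilayer graph, a label set, and nearest-neighbor Gibbs potentials."""

    graph: MultilayerGraph
    labels: LabelSet
    potentials: PotentialSet

    def __post_init__(self) -> None:
        k = len(self.labels)
        for subset, table in self.potentials.items():
            if not self.graph.is_clique(subset):
                raise ValueError(
                    f"potential support {subset} is not a clique of the graph"
                )
            if table.shape != (k,) * len(subset):
                raise ValueError(
                    f"potential on {subset} must have shape {(k,) * len(subset)}"
                )

    @property
    def vertices(self) -> Tuple[NodeId, ...]:
        return self.graph.vertices

    @property
    def n_configurations(self) -> int:
        return len(self.labels) ** self.graph.n_vertices


@dataclass
class JointTable:
    """Explicit strictly positive probability table over all configurations.

    ``probs`` has one axis per vertex of ``vertices`` (canonical order) and one
    index per label.  This is the brute-force oracle's currency: marginals are
    axis sums, conditionals are ratios of marginals.
    """

    vertices: Tuple[NodeId, ...]
    labels: LabelSet
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = _canon_subset(self.vertices)
        self.probs = np.asarray(self.probs, dtype=float)
        k = len(self.labels)
        if self.probs.shape != (k,) * len(self.vertices):
            raise ValueError(
                f"probability table must have shape {(k,) * len(self.vertices)}"
            )
        if np.any(self.probs <= 0):
            raise PositivityError("joint table must be strictly positive")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"joint table sums to {total!r}, not 1")

    @classmethod
    def from_unnormalized(cls, vertices, labels, weights) -> "JointTable":
        w = np.asarray(weights, dtype=float)
        return cls(tuple(vertices), labels, w / w.sum())

    def axis(self, v: NodeId) -> int:
        return self.vertices.index(NodeId(*v))

    def marginal(self, subset: Iterable[NodeId]) -> np.ndarray:
        """Marginal table over ``subset``; axes keep canonical vertex order.

        The empty subset yields a 0-d array equal to 1.
        """
        keep = set(NodeId(*v) for v in subset)
        drop = tuple(i for i, v in enumerate(self.vertices) if v not in keep)
        return self.probs.sum(axis=drop) if drop else self.probs

    def prob(self, w: Configuration) -> float:
        return float(self.probs[self._index(w)])

    def _index(self, w: Configuration) -> Tuple[int, ...]:
        try:
            return tuple(self.labels.index(w[v]) for v in self.vertices)
        except KeyError as exc:
            raise ValueError(f"configuration missing vertex {exc.args[0]}") from exc

    def configurations(self):
        """Iterate all configurations as dicts, in row-major index order."""
        k = len(self.labels)
        n = len(self.vertices)
        for flat in range(k**n):
            idx = np.unravel_index(flat, (k,) * n)
            yield {
                v: self.labels.labels[i] for v, i in zip(self.vertices, idx)
            }


def _guard(field: GibbsField, max_configurations: int) -> None:
    if field.n_configurations > max_configurations:
        raise CapacityError(
            f"configuration space of size {field.n_configurations} exceeds the "
            f"enumeration guard {max_configurations}"
        )


def log_weight_array(
    field: GibbsField, max_configurations: int = MAX_CONFIGURATIONS
) -> np.ndarray:
    """log prod_C phi_C over the whole configuration space, as a dense array.

    Shape (k,)*n with one axis per vertex in canonical order; potential tables
    broadcast into place, so the cost is one vectorized add per stored clique.
    """
    _guard(field, max_configurations)
    verts = field.vertices
    ax = {v: i for i, v in enumerate(verts)}
    k = len(field.labels)
    out = np.zeros((k,) * len(verts))
    for subset, table in field.potentials.items():
        shape = [1] * len(verts)
        for v in subset:
            shape[ax[v]] = k
        out += np.log(table).reshape(shape)
    return out


def energy(field: GibbsField, w: Configuration) -> float:
    """Dimensionless energy U(w) = -sum over stored potentials of log phi."""
    idx = {NodeId(*v): field.labels.index(lab) for v, lab in w.items()}
    missing = set(field.vertices) - set(idx)
    if missing:
        raise ValueError(f"configuration missing vertices {sorted(missing)}")
    u = 0.0
    for subset, table in field.potentials.items():
        u -= math.log(float(table[tuple(idx[v] for v in subset)]))
    return u


def partition_function(
    field: GibbsField, max_configurations: int = MAX_CONFIGURATIONS
) -> float:
    """Z = sum over all configurations of prod_C phi_C, by exact enumeration."""
    lw = log_weight_array(field, max_configurations)
    m = float(lw.max())
    return float(np.exp(m) * np.exp(lw - m).sum())


def gibbs_probability(
    field: GibbsField, w: Configuration, max_configurations: int = MAX_CONFIGURATIONS
) -> float:
    """P(w) = prod_C phi_C(w_C) / Z, strictly positive."""
    lw = log_weight_array(field, max_configurations)
    m = float(lw.max())
    log_z = m + math.log(float(np.exp(lw - m).sum()))
    idx = {NodeId(*v): field.labels.index(lab) for v, lab in w.items()}
    missing = set(field.vertices) - set(idx)
    if missing:
        raise ValueError(f"configuration missing vertices {sorted(missing)}")
    lp = 0.0
    for subset, table in field.potentials.items():
        lp += math.log(float(table[tuple(idx[v] for v in subset)]))
    return math.exp(lp - log_z)


def to_joint_table(
    field: GibbsField, max_configurations: int = MAX_CONFIGURATIONS
) -> JointTable:
    """Materialize P over all of the configuration space as a JointTable."""
    lw = log_weight_array(field, max_configurations)
    w = np.exp(lw - lw.max())
    return JointTable.from_unnormalized(field.vertices, field.labels, w)


def local_characteristic(
    field: GibbsField, v: NodeId, w: Configuration
) -> Dict[Any, float]:
    """Conditional distribution of vertex ``v`` given the rest of ``w``.

    Computed from the cliques containing ``v`` only:

        P(v = s | rest) = prod_{C contains v} phi_C(w with v<-s) / normalizer

    which is the local characteristic of the field; by the Markov property it
    coincides with the full-joint conditional and depends only on the
    neighbors of ``v``.
    """
    v = NodeId(*v)
    field.graph._check_vertex(v)
    labels = field.labels
    idx = {NodeId(*u): labels.index(lab) for u, lab in w.items() if NodeId(*u) != v}
    needed = set()
    relevant = []
    for subset, table in field.potentials.items():
        if v in subset:
            relevant.append((subset, np.log(table)))
            needed.update(u for u in subset if u != v)
    missing = needed - set(idx)
    if missing:
        raise ValueError(f"configuration missing neighbors {sorted(missing)}")
    k = len(labels)
    score = np.zeros(k)
    for subset, logt in relevant:
        pos = subset.index(v)
        base = [idx[u] if u != v else 0 for u in subset]
        for s in range(k):
            base[pos] = s
            score[s] += logt[tuple(base)]
    score -= score.max()
    p = np.exp(score)
    p /= p.sum()
    return {labels.labels[s]: float(p[s]) for s in range(k)}


def exact_sample(
    field: GibbsField,
    n: int,
    seed,
    max_configurations: int = MAX_CONFIGURATIONS,
) -> list:
    """``n`` independent draws from the exact joint; reproducible given ``seed``."""
    idx = sample_indices(field, n, seed, max_configurations)
    labels = field.labels.labels
    verts = field.vertices
    return [
        {v: labels[i] for v, i in zip(verts, row)} for row in idx
    ]


def sample_indices(
    field: GibbsField,
    n: int,
    seed,
    max_configurations: int = MAX_CONFIGURATIONS,
) -> np.ndarray:
    """Exact sampling returning an (n, n_vertices) array of label indices."""
    if n < 0:
        raise ValueError("n must be non-negative")
    joint = to_joint_table(field, max_configurations)
    rng = np.random.default_rng(seed)
    flat = joint.probs.ravel()
    flat = flat / flat.sum()
    draws = rng.choice(flat.size, size=n, p=flat)
    if n == 0:
        return np.empty((0, len(field.vertices)), dtype=np.int64)
    return np.stack(np.unravel_index(draws, joint.probs.shape), axis=1)


def gibbs_sample(
    field: GibbsField,
    n: int,
    seed,
    burn_in: int | None = None,
    spacing: int = 1,
) -> list:
    """Approximate sampling by single-site heat-bath sweeps.

    For fields above the enumeration guard.  Draws are correlated; this is a
    fixture generator, not an exact sampler, and is never used as an oracle.
    Burn-in defaults to 100 sweeps per vertex.
    """
    rng = np.random.default_rng(seed)
    verts = field.vertices
    labels = field.labels.labels
    if burn_in is None:
        burn_in = 100 * len(verts)
    state: Configuration = {
        v: labels[rng.integers(len(labels))] for v in verts
    }
    out = []
    sweeps = burn_in + n * spacing
    for t in range(sweeps):
        for v in verts:
            dist = local_characteristic(field, v, state)
            labs = list(dist)
            probs = np.array([dist[l] for l in labs])
            state[v] = labs[rng.choice(len(labs), p=probs / probs.sum())]
        if t >= burn_in and (t - burn_in) % spacing == 0 and len(out) < n:
            out.append(dict(state))
    return out
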