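"""Multilayer graphs for tensor Markov fields.

A tensor Markov field lives on a multilayer graph: each vertex is a pair
(variable index, layer index), written ``X_ih`` for variable *i* observed in
layer/context *h*.  Edges are undirected and may connect vertices on the same
layer (intra-layer) or across layers (inter-layer); the edge set is the
*neighborhood law* of the field.  This module provides the graph container and
the purely graph-theoretic queries the probabilistic machinery relies on:
neighborhoods, cliques (all complete subsets, including the empty set and
singletons), vertex-set separation, and Markov blankets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, NamedTuple, Tuple

import networkx as nx

from .errors import CapacityError

#: Default cap on vertex count for exhaustive clique enumeration.
MAX_CLIQUE_VERTICES = 24


class NodeId(NamedTuple):
    """A tensor index naming one vertex X_ih: variable ``var`` in layer ``layer``."""

    var: int
    layer: int


def canon_key(v: NodeId) -> Tuple[int, int]:
    """Canonical sort key for vertices: (layer, var)."""
    return (v.layer, v.var)


def canon_edge(u: NodeId, v: NodeId) -> Tuple[NodeId, NodeId]:
    """Canonical ordered form of an undirected edge."""
    return (u, v) if canon_key(u) <= canon_key(v) else (v, u)


@dataclass(frozen=True)
class MultilayerGraph:
    """Undirected multilayer graph on the vertex grid [0,N) x [0,L).

    Edges are stored as canonically ordered pairs; self-loops are rejected.
    An inter-layer coupling of the same variable, ``{(i,h),(i,k)}`` with
    ``h != k``, is a legal edge — only ``i == j and h == k`` is forbidden.
    """

    n_vars: int
    n_layers: int
    edges: FrozenSet[Tuple[NodeId, NodeId]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_vars < 1 or self.n_layers < 1:
            raise ValueError("n_vars and n_layers must be >= 1")
        canonical = set()
        for e in self.edges:
            u, v = e
            u, v = NodeId(*u), NodeId(*v)
            if u == v:
                raise ValueError(f"self-loop on {u}")
            for w in (u, v):
                self._check_vertex(w)
            canonical.add(canon_edge(u, v))
        object.__setattr__(self, "edges", frozenset(canonical))

    def _check_vertex(self, v: NodeId) -> None:
        if not (0 <= v.var < self.n_vars and 0 <= v.layer < self.n_layers):
            raise IndexError(
                f"vertex {v} outside grid [0,{self.n_vars}) x [0,{self.n_layers})"
            )

    @classmethod
    def from_edges(
        cls,
        n_vars: int,
        n_layers: int,
        edges: Iterable[Tuple[Tuple[int, int], Tuple[int, int]]],
    ) -> "MultilayerGraph":
        """Build from an iterable of ((var,layer),(var,layer)) pairs."""
        es = frozenset(
            canon_edge(NodeId(*a), NodeId(*b)) for a, b in edges
        )
        return cls(n_vars, n_layers, es)

    @property
    def vertices(self) -> Tuple[NodeId, ...]:
        """All N*L vertices in canonical (layer, var) order."""
        return tuple(
            NodeId(i, h)
            for h in range(self.n_layers)
            for i in range(self.n_vars)
        )

    @property
    def n_vertices(self) -> int:
        return self.n_vars * self.n_layers

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return canon_edge(NodeId(*u), NodeId(*v)) in self.edges

    def neighbors(self, v: NodeId) -> FrozenSet[NodeId]:
        """The neighborhood N_{X_ih}: every vertex sharing an edge with ``v``."""
        v = NodeId(*v)
        self._check_vertex(v)
        out = set()
        for a, b in self.edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return frozenset(out)

    # In a tensor Markov field the Markov blanket of a vertex is exactly its
    # set of first neighbors (undirected local Markov property).
    markov_blanket = neighbors

    def is_clique(self, s: Iterable[NodeId]) -> bool:
        """True iff every pair in ``s`` is an edge; true for the empty set and singletons."""
        members = [NodeId(*v) for v in s]
        for v in members:
            self._check_vertex(v)
        return all(
            self.has_edge(u, v) for u, v in itertools.combinations(members, 2)
        )

    def enumerate_cliques(
        self, max_vertices: int = MAX_CLIQUE_VERTICES
    ) -> list:
        """Every complete subset of V, including the empty set and singletons.

        Returned as frozensets in deterministic canonical order (by size, then
        lexicographic on the sorted vertex keys).  Guarded: refuses graphs with
        more than ``max_vertices`` vertices.
        """
        if self.n_vertices > max_vertices:
            raise CapacityError(
                f"clique enumeration limited to {max_vertices} vertices; "
                f"graph has {self.n_vertices}"
            )
        g = self.to_networkx()
        cliques = [frozenset()]
        cliques.extend(frozenset(c) for c in nx.enumerate_all_cliques(g))
        cliques.sort(key=lambda c: (len(c), sorted(canon_key(v) for v in c)))
        return cliques

    def separates(
        self,
        a: Iterable[NodeId],
        b: Iterable[NodeId],
        c: Iterable[NodeId],
    ) -> bool:
        """True iff deleting ``c`` leaves no path from any vertex of ``a`` to any of ``b``.

        ``a``, ``b``, ``c`` must be pairwise disjoint subsets of V.
        """
        sa = frozenset(NodeId(*v) for v in a)
        sb = frozenset(NodeId(*v) for v in b)
        sc = frozenset(NodeId(*v) for v in c)
        for v in sa | sb | sc:
            self._check_vertex(v)
        if sa & sb or sa & sc or sb & sc:
            raise ValueError("a, b, c must be pairwise disjoint")
        if not sa or not sb:
            return True
        # BFS from a through the graph with c removed.
        adj = {v: set() for v in self.vertices if v not in sc}
        for u, v in self.edges:
            if u not in sc and v not in sc:
                adj[u].add(v)
                adj[v].add(u)
        seen = set(sa)
        frontier = list(sa)
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w in sb:
                        return False
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            frontier = nxt
        return True

    def connected_components_without(self, c: Iterable[NodeId]) -> list:
        """Connected components (as frozensets) of the graph with ``c`` deleted."""
        sc = frozenset(NodeId(*v) for v in c)
        adj = {v: set() for v in self.vertices if v not in sc}
        for u, v in self.edges:
            if u not in sc and v not in sc:
                adj[u].add(v)
                adj[v].add(u)
        comps = []
        seen: set = set()
        for start in adj:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        comp.add(w)
                        stack.append(w)
            comps.append(frozenset(comp))
        comps.sort(key=lambda s: sorted(canon_key(v) for v in s))
        return comps

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g
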