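"""Synthetic multilayer scenarios with planted dependency structure.

Every inference component of the package is exercised against data whose
generating mechanism is fully known: a random multilayer graph is planted, a
strictly positive Gibbs field with pairwise edge potentials is drawn on it,
the exact joint is materialized, and i.i.d. samples are taken from that joint
(optionally mapped to noisy real-valued levels to emulate continuous omics
measurements such as per-sample gene and miRNA expression layers).

All randomness flows from a single scenario seed through named substreams
(graph / potentials / sampling / noise), so each component can be regenerated
independently and scenarios are bit-reproducible.

Defaults define the reference study conditions: 4 variables x 2 layers with
binary labels (a 256-configuration space, fully enumerable), edge densities
p_intra=0.25 / p_inter=0.10 (average degree near 1, matching the sparsity of
small illustrative multilayer dependency graphs), interaction strength 1.0,
and 2000 exact samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gibbs import (
    BINARY,
    GibbsField,
    JointTable,
    LabelSet,
    PotentialSet,
    sample_indices,
    to_joint_table,
)
from .graph import MultilayerGraph, NodeId, canon_edge
from .mi import SampleTensor

DEFAULT_N_VARS = 4
DEFAULT_N_LAYERS = 2
DEFAULT_P_INTRA = 0.25
DEFAULT_P_INTER = 0.10
DEFAULT_N_SAMPLES = 2000
DEFAULT_STRENGTH = 1.0
DEFAULT_NOISE_SD = 0.5


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _substreams(seed, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class PlantedScenario:
    """A planted graph, its Gibbs field, exact joint, and exact samples."""

    graph: MultilayerGraph
    field: GibbsField
    joint: JointTable
    samples: SampleTensor
    seed: int
    params: dict = field(default_factory=dict)


def random_multilayer_graph(
    n_vars: int,
    n_layers: int,
    p_intra: float = DEFAULT_P_INTRA,
    p_inter: float = DEFAULT_P_INTER,
    seed=0,
) -> MultilayerGraph:
    """Erdos-Renyi-style multilayer graph with separate intra/inter edge rates."""
    for p in (p_intra, p_inter):
        if not 0.0 <= p <= 1.0:
            raise ValueError("edge probabilities must lie in [0, 1]")
    rng = _rng(seed)
    verts = [
        NodeId(i, h) for h in range(n_layers) for i in range(n_vars)
    ]
    edges = set()
    for u, v in itertools.combinations(verts, 2):
        p = p_intra if u.layer == v.layer else p_inter
        if rng.random() < p:
            edges.add(canon_edge(u, v))
    return MultilayerGraph(n_vars, n_layers, frozenset(edges))


def random_gibbs_field(
    g: MultilayerGraph,
    labels: LabelSet = BINARY,
    strength: float = DEFAULT_STRENGTH,
    seed=0,
) -> GibbsField:
    """Random pairwise potentials on every edge, bounded away from degeneracy.

    Each edge gets a (k x k) table whose log entries are drawn uniformly from
    [-strength, -0.2*strength] union [0.2*strength, strength]: the minimum
    magnitude keeps planted interactions statistically visible, so exact
    structure recovery is not foiled by near-product potentials.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    rng = _rng(seed)
    k = len(labels)
    tables = {}
    for u, v in sorted(g.edges):
        mag = rng.uniform(0.2 * strength, strength, size=(k, k))
        sign = rng.choice((-1.0, 1.0), size=(k, k))
        tables[(u, v)] = np.exp(sign * mag)
    return GibbsField(g, labels, PotentialSet(tables))


def make_scenario(
    n_vars: int = DEFAULT_N_VARS,
    n_layers: int = DEFAULT_N_LAYERS,
    p_intra: float = DEFAULT_P_INTRA,
    p_inter: float = DEFAULT_P_INTER,
    n_samples: int = DEFAULT_N_SAMPLES,
    strength: float = DEFAULT_STRENGTH,
    seed: int = 0,
    labels: LabelSet = BINARY,
) -> PlantedScenario:
    """Graph -> field -> exact joint -> exact samples, all cross-linked."""
    g_rng, f_rng, s_rng, _ = _substreams(seed, 4)
    graph = random_multilayer_graph(n_vars, n_layers, p_intra, p_inter, g_rng)
    fld = random_gibbs_field(graph, labels, strength, f_rng)
    joint = to_joint_table(fld)
    idx = sample_indices(fld, n_samples, s_rng)
    values = np.empty((n_samples, n_vars, n_layers), dtype=np.int64)
    for a, v in enumerate(fld.vertices):
        values[:, v.var, v.layer] = idx[:, a]
    samples = SampleTensor(values)
    params = dict(
        n_vars=n_vars,
        n_layers=n_layers,
        p_intra=p_intra,
        p_inter=p_inter,
        n_samples=n_samples,
        strength=strength,
    )
    return PlantedScenario(graph, fld, joint, samples, seed, params)


def gaussianize(
    s: PlantedScenario,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: Optional[int] = None,
) -> SampleTensor:
    """Continuous emulation: map each label index to a real level plus noise.

    Levels are the label indices spaced one unit apart with independent
    Gaussian noise, so the planted dependency structure survives up to noise;
    used to exercise discretization and MI inference on real-valued data.
    If ``seed`` is omitted, the scenario's own noise substream is used.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if seed is None:
        rng = _substreams(s.seed, 4)[3]
    else:
        rng = _rng(seed)
    base = s.samples.values.astype(float)
    return SampleTensor(base + rng.normal(0.0, noise_sd, size=base.shape))
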