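"""Exact Gibbs measures: energy, partition function, locality, sampling."""

import itertools
import math

import numpy as np
import pytest

from tmfields import (
    BINARY,
    CapacityError,
    GibbsField,
    LabelSet,
    MultilayerGraph,
    NodeId,
    PotentialSet,
    energy,
    exact_sample,
    gibbs_probability,
    local_characteristic,
    partition_function,
    random_gibbs_field,
    random_multilayer_graph,
    to_joint_table,
)

A = NodeId(0, 0)
B = NodeId(1, 0)


def make_pair_field(log_pot: np.ndarray) -> GibbsField:
    g = MultilayerGraph.from_edges(2, 1, [(A, B)])
    return GibbsField(g, BINARY, PotentialSet({(A, B): np.exp(log_pot)}))


def brute_force_joint(field: GibbsField) -> dict:
    """Oracle: enumerate configurations, multiply potentials, normalize."""
    verts = field.vertices
    labels = field.labels.labels
    weights = {}
    for combo in itertools.product(labels, repeat=len(verts)):
        w = dict(zip(verts, combo))
        total = 1.0
        for subset, table in field.potentials.items():
            idx = tuple(field.labels.index(w[v]) for v in subset)
            total *= float(table[idx])
        weights[combo] = total
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


class TestPartitionFunction:
    def test_unit_potentials_count_configurations(self):
        g = MultilayerGraph(3, 1)
        f = GibbsField(g, BINARY, PotentialSet({}))
        assert partition_function(f) == pytest.approx(8.0, abs=1e-12)

    def test_single_vertex_field(self):
        g = MultilayerGraph(1, 1)
        f = GibbsField(g, BINARY, PotentialSet({(A,): np.array([2.0, 3.0])}))
        assert partition_function(f) == pytest.approx(5.0)
        assert gibbs_probability(f, {A: 0}) == pytest.approx(0.4)
        jt = to_joint_table(f)
        assert jt.prob({A: 0}) == pytest.approx(0.4)
        assert jt.prob({A: 1}) == pytest.approx(0.6)

    def test_probabilities_normalize(self, rng):
        g = random_multilayer_graph(3, 2, 0.4, 0.3, rng)
        f = random_gibbs_field(g, seed=rng)
        jt = to_joint_table(f)
        assert jt.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_capacity_guard(self):
        g = MultilayerGraph(7, 3)
        f = GibbsField(g, BINARY, PotentialSet({}))
        with pytest.raises(CapacityError):
            partition_function(f)


class TestEnergyMeasureDuality:
    def test_unit_potentials_zero_energy(self):
        g = MultilayerGraph(2, 1)
        f = GibbsField(g, BINARY, PotentialSet({}))
        assert energy(f, {A: 0, B: 1}) == 0.0

    def test_matching_pair_energy(self):
        log_pot = np.array([[1.0, 0.0], [0.0, 1.0]])
        f = make_pair_field(log_pot)
        assert energy(f, {A: 0, B: 0}) == pytest.approx(-1.0)
        assert energy(f, {A: 0, B: 1}) == pytest.approx(0.0)

    def test_probability_equals_boltzmann_weight(self, rng):
        g = random_multilayer_graph(2, 2, 0.5, 0.5, rng)
        f = random_gibbs_field(g, seed=rng)
        z = partition_function(f)
        jt = to_joint_table(f)
        for w in jt.configurations():
            assert gibbs_probability(f, w) == pytest.approx(
                math.exp(-energy(f, w)) / z, rel=1e-10
            )
            assert gibbs_probability(f, w) == pytest.approx(jt.prob(w), rel=1e-10)

    def test_incomplete_configuration_rejected(self):
        f = make_pair_field(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            energy(f, {A: 0})


class TestJointTableOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        g = random_multilayer_graph(2, 2, 0.5, 0.4, seed)
        f = random_gibbs_field(g, seed=seed)
        oracle = brute_force_joint(f)
        jt = to_joint_table(f)
        for combo, p in oracle.items():
            assert jt.prob(dict(zip(f.vertices, combo))) == pytest.approx(p, rel=1e-10)


class TestLocalCharacteristic:
    def test_isolated_vertex_is_uniform(self):
        g = MultilayerGraph(2, 1)
        f = GibbsField(g, BINARY, PotentialSet({}))
        dist = local_characteristic(f, A, {B: 1})
        assert dist == {0: pytest.approx(0.5), 1: pytest.approx(0.5)}

    def test_attractive_pair_closed_form(self):
        # phi(x, y) = e^{[x == y]}; neighbor fixed at 0.
        f = make_pair_field(np.array([[1.0, 0.0], [0.0, 1.0]]))
        dist = local_characteristic(f, A, {B: 0})
        e = math.e
        assert dist[0] == pytest.approx(e / (e + 1))

    def test_matches_full_joint_conditional(self, rng):
        for _ in range(5):
            g = random_multilayer_graph(3, 2, 0.4, 0.3, rng)
            f = random_gibbs_field(g, seed=rng)
            jt = to_joint_table(f)
            for v in f.vertices:
                ax = jt.axis(v)
                cond = jt.probs / jt.probs.sum(axis=ax, keepdims=True)
                for w in itertools.islice(jt.configurations(), 8):
                    dist = local_characteristic(f, v, w)
                    idx = list(jt._index(w))
                    for li, lab in enumerate(jt.labels.labels):
                        idx[ax] = li
                        assert dist[lab] == pytest.approx(
                            cond[tuple(idx)], abs=1e-12
                        )

    def test_depends_only_on_neighbors(self, chain_field):
        # Changing the far end of the chain must not move P(u | rest).
        u, w = NodeId(0, 0), NodeId(2, 0)
        base = {NodeId(1, 0): 0, w: 0}
        flipped = {NodeId(1, 0): 0, w: 1}
        assert local_characteristic(chain_field, u, base) == local_characteristic(
            chain_field, u, flipped
        )


class TestExactSampling:
    def test_zero_draws(self, chain_field):
        assert exact_sample(chain_field, 0, seed=1) == []

    def test_seed_determinism(self, chain_field):
        assert exact_sample(chain_field, 25, seed=7) == exact_sample(
            chain_field, 25, seed=7
        )

    def test_uniform_field_frequencies(self):
        g = MultilayerGraph(2, 1)
        f = GibbsField(g, BINARY, PotentialSet({}))
        n = 10000
        draws = exact_sample(f, n, seed=11)
        counts = {}
        for w in draws:
            key = (w[A], w[B])
            counts[key] = counts.get(key, 0) + 1
        p = 0.25
        se = math.sqrt(p * (1 - p) / n)
        for key in itertools.product((0, 1), repeat=2):
            assert abs(counts.get(key, 0) / n - p) < 4 * se


def test_label_set_validation():
    with pytest.raises(ValueError):
        LabelSet((0,))
    with pytest.raises(ValueError):
        LabelSet((0, 1), default=2)
    ls = LabelSet(("low", "high"))
    assert ls.default == "low" and len(ls) == 2


def test_non_clique_potential_rejected():
    g = MultilayerGraph(2, 1)  # edgeless: {A, B} is not a clique
    with pytest.raises(ValueError):
        GibbsField(g, BINARY, PotentialSet({(A, B): np.ones((2, 2))}))


def test_nonpositive_potential_rejected():
    from tmfields import PositivityError

    with pytest.raises(PositivityError):
        PotentialSet({(A,): np.array([1.0, 0.0])})
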