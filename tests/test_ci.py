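"""Conditional kernels, CI product forms, I-maps, and empirical CI tests."""

import itertools

import numpy as np
import pytest

from tmfields import (
    BINARY,
    JointTable,
    MultilayerGraph,
    NodeId,
    SampleTensor,
    ci_given_rest,
    ci_given_set,
    conditional_kernel,
    count_pairwise_tests,
    empirical_ci_test,
    is_independence_map,
    is_perfect_map,
    random_gibbs_field,
    random_multilayer_graph,
    to_joint_table,
)
from tmfields.ci import expand_marginal

from conftest import random_joint

U, V, W = NodeId(0, 0), NodeId(1, 0), NodeId(2, 0)


class TestConditionalKernel:
    def test_empty_conditioning_is_marginal(self):
        p = random_joint(3, 0)
        k = conditional_kernel(p, (), (U, V))
        assert np.allclose(k.probs, p.marginal((U, V)))

    def test_rows_normalize(self):
        p = random_joint(4, 1)
        verts = p.vertices
        k = conditional_kernel(p, verts[:2], verts[2:])
        assert np.allclose(k.probs.sum(axis=(2, 3)), 1.0, atol=1e-10)

    def test_independent_joint_ignores_conditioning(self):
        px = np.array([0.3, 0.7])
        py = np.array([0.6, 0.4])
        p = JointTable((U, V), BINARY, np.outer(px, py))
        k = conditional_kernel(p, (U,), (V,))
        assert np.allclose(k.probs[0], k.probs[1])

    def test_recursion_identity(self):
        # C_{AB}(D | C) == C_{AB}(CD) / C_{AB}(C), both sides built separately.
        p = random_joint(4, 7)
        a, b, c, d = p.vertices
        lhs = conditional_kernel(p, (a, b, c), (d,)).probs
        joint_cd = conditional_kernel(p, (a, b), (c, d)).probs
        just_c = conditional_kernel(p, (a, b), (c,)).probs
        rhs = joint_cd / just_c[..., None]
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_overlap_rejected(self):
        p = random_joint(3, 0)
        with pytest.raises(ValueError):
            conditional_kernel(p, (U,), (U, V))


def fork_joint(seed: int = 0) -> JointTable:
    """u <- s -> v: built from P(s) P(u|s) P(v|s), so u and v are CI given s."""
    rng = np.random.default_rng(seed)
    ps = rng.dirichlet((2.0, 2.0))
    pu = rng.dirichlet((2.0, 2.0), size=2)
    pv = rng.dirichlet((2.0, 2.0), size=2)
    probs = np.einsum("s,su,sv->usv", ps, pu, pv)
    # vertex order (u, s, v) = ((0,0), (1,0), (2,0)) canonical
    return JointTable((U, V, W), BINARY, probs)


class TestExactCI:
    def test_fork_is_ci_given_parent(self):
        p = fork_joint()
        stmt = ci_given_set(p, U, W, (V,), tol=1e-10)
        assert stmt.holds and stmt.max_deviation < 1e-12

    def test_fork_children_marginally_dependent(self):
        p = fork_joint(seed=1)
        assert not ci_given_set(p, U, W, (), tol=1e-6).holds

    def test_directly_coupled_pair_is_dependent(self):
        probs = np.array([[0.4, 0.1], [0.1, 0.4]])
        p = JointTable((U, V), BINARY, probs)
        assert not ci_given_set(p, U, V, (), tol=1e-6).holds

    def test_full_conditioning_set_equals_given_rest(self):
        p = random_joint(4, 3)
        u, v = p.vertices[0], p.vertices[2]
        rest = tuple(w for w in p.vertices if w not in (u, v))
        a = ci_given_set(p, u, v, rest)
        b = ci_given_rest(p, u, v)
        assert a.max_deviation == b.max_deviation

    def test_chain_endpoints_ci_given_rest(self, chain_field):
        p = to_joint_table(chain_field)
        assert ci_given_rest(p, U, W).holds
        assert not ci_given_rest(p, U, V).holds

    def test_independent_joint_all_pairs_ci(self):
        px = np.array([0.3, 0.7])
        probs = np.einsum("i,j,k->ijk", px, px, px)
        p = JointTable((U, V, W), BINARY, probs)
        for a, b in itertools.combinations(p.vertices, 2):
            assert ci_given_rest(p, a, b).holds


class TestCountPairwiseTests:
    @pytest.mark.parametrize(
        "n_vars,n_layers,expected", [(4, 2, 28), (1, 1, 0), (3, 3, 36)]
    )
    def test_closed_form(self, n_vars, n_layers, expected):
        assert count_pairwise_tests(n_vars, n_layers) == expected

    def test_equals_all_pairs_sweep(self):
        g = random_multilayer_graph(3, 2, 0.3, 0.3, seed=0)
        f = random_gibbs_field(g, seed=0)
        p = to_joint_table(f)
        sweep = list(itertools.combinations(p.vertices, 2))
        assert len(sweep) == count_pairwise_tests(3, 2)


class TestIndependenceMaps:
    def test_complete_graph_is_always_an_imap(self):
        p = random_joint(3, 11)
        g = MultilayerGraph.from_edges(3, 1, [(U, V), (V, W), (U, W)])
        assert is_independence_map(g, p).ok

    def test_edgeless_graph_requires_full_independence(self):
        px = np.array([0.3, 0.7])
        indep = JointTable((U, V, W), BINARY, np.einsum("i,j,k->ijk", px, px, px))
        g = MultilayerGraph(3, 1)
        assert is_independence_map(g, indep).ok
        dependent = fork_joint()
        rep = is_independence_map(g, dependent)
        assert not rep.ok and rep.counterexample is not None

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_field_graph_is_an_imap_of_its_joint(self, seed):
        g = random_multilayer_graph(3, 2, 0.4, 0.3, seed=seed)
        f = random_gibbs_field(g, seed=seed)
        rep = is_independence_map(g, to_joint_table(f))
        assert rep.ok and rep.mode == "full"

    def test_chain_graph_is_perfect_map_of_chain_field(self, chain_field):
        p = to_joint_table(chain_field)
        assert is_perfect_map(chain_field.graph, p)

    def test_extra_edge_breaks_perfectness(self):
        px = np.array([0.4, 0.6])
        indep = JointTable((U, V), BINARY, np.outer(px, px))
        edgeless = MultilayerGraph(2, 1)
        with_edge = MultilayerGraph.from_edges(2, 1, [(U, V)])
        assert is_perfect_map(edgeless, indep)
        assert not is_perfect_map(with_edge, indep)


class TestEmpiricalCI:
    def _tensor(self, cols: dict, n: int) -> SampleTensor:
        nv = 1 + max(v.var for v in cols)
        nl = 1 + max(v.layer for v in cols)
        values = np.zeros((n, nv, nl), dtype=np.int64)
        for v, col in cols.items():
            values[:, v.var, v.layer] = col
        return SampleTensor(values)

    def test_column_copy_is_dependent(self, rng):
        x = rng.integers(0, 2, size=500)
        data = self._tensor({U: x, V: x}, 500)
        stmt = empirical_ci_test(data, U, V, (), n_perm=100, seed=1)
        assert not stmt.holds

    def test_conditionally_independent_fork(self, rng):
        held = 0
        n = 2000
        for rep in range(10):
            s = rng.integers(0, 2, size=n)
            noise = rng.random(size=(2, n))
            x = np.where(noise[0] < 0.2 + 0.6 * s, 1, 0)
            y = np.where(noise[1] < 0.2 + 0.6 * s, 1, 0)
            data = self._tensor({U: x, V: y, W: s}, n)
            stmt = empirical_ci_test(
                data, U, V, (W,), alpha=0.05, n_perm=100, seed=rep
            )
            held += stmt.holds
        assert held >= 8  # alpha=0.05 false-rejection rate allows rare misses

    def test_tiny_alpha_accepts(self, rng):
        x = rng.integers(0, 2, size=300)
        y = rng.integers(0, 2, size=300)
        data = self._tensor({U: x, V: y}, 300)
        stmt = empirical_ci_test(data, U, V, (), alpha=1e-9, n_perm=50, seed=0)
        assert stmt.holds

    def test_conditioning_guard(self, rng):
        data = SampleTensor(rng.integers(0, 2, size=(50, 5, 1)))
        from tmfields import CapacityError

        with pytest.raises(CapacityError):
            empirical_ci_test(
                data, NodeId(0, 0), NodeId(1, 0),
                [NodeId(i, 0) for i in (2, 3, 4)], max_given=2,
            )


def test_expand_marginal_broadcasting():
    p = random_joint(3, 5)
    full = p.vertices
    sub = (full[0], full[2])
    arr = expand_marginal(p.marginal(sub), sub, full)
    assert arr.shape == (2, 1, 2)
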