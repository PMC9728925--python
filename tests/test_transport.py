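import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from tcrot import (
    Repertoire,
    TcrBeta,
    ValidationError,
    effort_matrix,
    exact_emd,
    repertoire_transport,
    sinkhorn_plan,
    transport_cost,
)
from tcrot.errors import SizeError


def random_instance(rng, n, m, scale=100.0):
    D = rng.random((n, m)) * scale
    r = rng.random(n)
    r /= r.sum()
    c = rng.random(m)
    c /= c.sum()
    return r, c, D


def min_cost_flow_emd(r, c, D, denom=10_000):
    """Independent oracle: integerized min-cost flow via networkx.

    Masses are rationalized to multiples of 1/denom and costs to integers,
    so the result matches the LP on instances built from such data.
    """
    n, m = D.shape
    G = nx.DiGraph()
    ri = np.round(r * denom).astype(int)
    ci = np.round(c * denom).astype(int)
    assert ri.sum() == ci.sum()
    for i in range(n):
        G.add_node(("s", i), demand=-int(ri[i]))
    for j in range(m):
        G.add_node(("t", j), demand=int(ci[j]))
    for i in range(n):
        for j in range(m):
            G.add_edge(("s", i), ("t", j), weight=int(round(D[i, j])))
    flow = nx.min_cost_flow(G)
    cost = sum(
        flow[("s", i)][("t", j)] * int(round(D[i, j]))
        for i in range(n)
        for j in range(m)
    )
    return cost / denom


class TestExactEmd:
    def test_identity_coupling_optimal(self):
        r = np.array([0.2, 0.3, 0.5])
        D = np.array([[0.0, 5, 9], [5, 0, 4], [9, 4, 0]])
        plan = exact_emd(r, r, D)
        assert transport_cost(plan.P, D) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(plan.P, np.diag(r), atol=1e-9)

    def test_2x2_symmetric_zero(self):
        r = np.array([0.5, 0.5])
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        plan = exact_emd(r, r, D)
        assert transport_cost(plan.P, D) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_square_matches_assignment(self, rng):
        # with uniform marginals the transport polytope's vertices are the
        # permutation matrices, so the Hungarian algorithm is an exact,
        # independent oracle
        for n in (3, 4, 6):
            D = rng.random((n, n)) * 50
            u = np.full(n, 1.0 / n)
            plan = exact_emd(u, u, D)
            ri, ci = linear_sum_assignment(D)
            assert transport_cost(plan.P, D) == pytest.approx(
                D[ri, ci].sum() / n, abs=1e-9
            )

    def test_small_enumeration_oracle(self, rng):
        # 3x3 uniform: enumerate all permutations explicitly
        D = rng.random((3, 3))
        u = np.full(3, 1.0 / 3)
        plan = exact_emd(u, u, D)
        best = min(
            sum(D[i, p[i]] for i in range(3)) / 3
            for p in itertools.permutations(range(3))
        )
        assert transport_cost(plan.P, D) == pytest.approx(best, abs=1e-12)

    def test_min_cost_flow_oracle_nonuniform(self, rng):
        for _ in range(5):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            # rational masses and integer costs so the flow oracle is exact
            ra = rng.integers(1, 10, n)
            ca = rng.integers(1, 10, m)
            denom = int(np.lcm(ra.sum(), ca.sum()))
            r = ra / ra.sum()
            c = ca / ca.sum()
            D = rng.integers(0, 60, (n, m)).astype(float)
            plan = exact_emd(r, c, D)
            assert transport_cost(plan.P, D) == pytest.approx(
                min_cost_flow_emd(r, c, D, denom=denom), abs=1e-9
            )

    def test_size_guard(self):
        with pytest.raises(SizeError):
            exact_emd(
                np.full(200, 1 / 200), np.full(200, 1 / 200), np.zeros((200, 200))
            )


class TestSinkhorn:
    def test_single_atom(self):
        plan = sinkhorn_plan(np.array([1.0]), np.array([1.0]), np.array([[0.0]]), 0.1)
        assert plan.P[0, 0] == pytest.approx(1.0)

    def test_forced_mass_move(self):
        r = np.array([1.0, 0.0])
        c = np.array([0.0, 1.0])
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        plan = sinkhorn_plan(r, c, D, 1e-3)
        assert transport_cost(plan.P, D) == pytest.approx(1.0, rel=1e-6)

    def test_cost_close_to_and_above_emd(self, rng):
        for _ in range(5):
            r, c, D = random_instance(rng, 6, 8)
            eps = 1e-3 * D.max()
            sk = sinkhorn_plan(r, c, D / D.max(), eps / D.max())
            lp = exact_emd(r, c, D)
            cost_sk = transport_cost(sk.P, D)
            cost_lp = transport_cost(lp.P, D)
            assert cost_sk >= cost_lp - 1e-9
            assert cost_sk <= cost_lp * 1.05

    def test_feasibility_property(self, rng):
        for _ in range(10):
            n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            r, c, D = random_instance(rng, n, m, scale=1.0)
            plan = sinkhorn_plan(r, c, D, 0.05)
            assert plan.marginal_violation() < 1e-6
            assert (plan.P >= 0).all()

    def test_monotone_refinement(self, rng):
        r, c, D = random_instance(rng, 7, 7, scale=1.0)
        lp_cost = transport_cost(exact_emd(r, c, D).P, D)
        costs = [
            transport_cost(sinkhorn_plan(r, c, D, eps).P, D)
            for eps in (0.1, 0.01, 0.001)
        ]
        for hi, lo in zip(costs, costs[1:]):
            assert lo <= hi + 1e-6
        assert costs[-1] <= lp_cost * 1.02 + 1e-9
        assert costs[-1] >= lp_cost - 1e-9

    def test_entropy_above_lp_vertex(self, rng):
        for _ in range(5):
            r, c, D = random_instance(rng, 5, 6, scale=1.0)
            sk = sinkhorn_plan(r, c, D, 0.05)
            lp = exact_emd(r, c, D)
            assert sk.entropy >= lp.entropy - 1e-9

    def test_zero_mass_atoms_reinserted(self):
        r = np.array([0.5, 0.0, 0.5])
        c = np.array([0.5, 0.5])
        D = np.ones((3, 2))
        plan = sinkhorn_plan(r, c, D, 0.1)
        assert np.allclose(plan.P[1], 0)
        assert plan.marginal_violation() < 1e-9

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValidationError):
            sinkhorn_plan(np.array([0.5, 0.4]), np.array([1.0]), np.zeros((2, 1)), 0.1)
        with pytest.raises(ValidationError):
            sinkhorn_plan(np.array([1.0]), np.array([1.0]), np.zeros((1, 1)), -1.0)


class TestEffort:
    def test_zero_distance_zero_effort(self, rng):
        P = rng.random((3, 4))
        assert np.allclose(effort_matrix(P, np.zeros((3, 4))), 0)

    def test_singleton(self):
        assert effort_matrix(np.array([[1.0]]), np.array([[7.0]]))[0, 0] == pytest.approx(7.0)

    def test_total_cost_is_double_sum(self, rng):
        P = rng.random((5, 6))
        D = rng.random((5, 6))
        manual = sum(P[i, j] * D[i, j] for i in range(5) for j in range(6))
        assert transport_cost(P, D) == pytest.approx(manual, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            effort_matrix(np.zeros((2, 2)), np.zeros((2, 3)))


class TestRepertoireTransport:
    def test_self_transport_near_zero(self, germline, background_pair):
        r1, _ = background_pair
        res = repertoire_transport(r1, r1, germline)
        assert res.total_cost < 0.02 * res.D.mean()

    def test_disjoint_singletons(self, germline):
        from tcrot import tcrdist_pair

        t1 = TcrBeta(germline.alleles[0], "CASSF")
        t2 = TcrBeta(germline.alleles[1], "CAWWGF")
        res = repertoire_transport(
            Repertoire.from_tcrs([t1]), Repertoire.from_tcrs([t2]), germline
        )
        assert res.total_cost == pytest.approx(tcrdist_pair(t1, t2, germline), rel=1e-9)

    def test_cost_close_to_emd_on_repertoires(self, germline, small_pair):
        r1, r2 = small_pair
        res = repertoire_transport(r1, r2, germline, epsilon=0.001)
        lp = exact_emd(r1.mass, r2.mass, res.D)
        lp_cost = transport_cost(lp.P, res.D)
        assert lp_cost <= res.total_cost <= lp_cost * 1.05

    def test_effort_identity(self, germline, small_pair):
        r1, r2 = small_pair
        res = repertoire_transport(r1, r2, germline)
        assert np.allclose(res.effort, res.plan.P * res.D)
        assert res.total_cost == pytest.approx(res.effort.sum(), rel=1e-12)
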