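"""Pebble engine: worked examples, ledger conservation, oracle agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pebblegame.engine import PebbleEngineError, init_state, run
from pebblegame.ensemble import polymatroid_rank_oracle, shared_dof_oracle
from pebblegame.fixtures import fully_rigid_network
from pebblegame.network import WeightedNetwork

from conftest import random_weighted_network


class TestWorkedTriangle:
    """The fractional game on the 0.6/5/5 triangle, checked end to end."""

    def test_dof_totals(self, triangle):
        state = run(triangle)
        assert state.free_dof() == pytest.approx(7.4)
        assert state.excess_dof() == pytest.approx(1.4)
        assert state.absorbed_redundant == pytest.approx(0.0)

    def test_three_singleton_clusters(self, triangle):
        labels = run(triangle).rigid_cluster_decomposition()
        assert labels.cluster_sizes == [1, 1, 1]

    def test_insertion_order_irrelevant(self, triangle):
        for perm in itertools.permutations(triangle.edges):
            state = run(WeightedNetwork(3, list(perm)))
            assert state.free_dof() == pytest.approx(7.4)

    def test_shared_dof_matches_lp_oracle_and_is_symmetric(self, triangle):
        state = run(triangle)
        for a, b in itertools.combinations(range(3), 2):
            expected = shared_dof_oracle(triangle, a, b)
            assert state.shared_excess_dof(a, b) == pytest.approx(expected)
            assert state.shared_excess_dof(b, a) == pytest.approx(expected)

    def test_pinned_probe_collects_the_excess_then_fails(self, triangle):
        # after convergence 1.4 excess DOF remain; with 6 pebbles pinned on
        # vertex 0 a search on vertex 1 can gather exactly that excess
        state = run(triangle)
        gathered, _ = state.collect_pebbles(0, 6)
        assert gathered == pytest.approx(6)
        gathered, _ = state.collect_pebbles(1, 6, pinned=0)
        assert gathered == pytest.approx(1.4)


class TestInsertionMechanics:
    def test_initial_state(self, triangle):
        state = init_state(triangle)
        assert state.free_dof() == 18
        assert state.ledger_residual() == 0

    def test_single_vertex(self):
        state = run(WeightedNetwork(1, []))
        assert state.free_dof() == 6
        assert state.excess_dof() == 0

    def test_integer_mode_rejects_fractional_capacity(self, triangle):
        with pytest.raises(ValueError, match="integer"):
            init_state(triangle, mode="integer")

    def test_overloaded_pair_condenses(self):
        # a pair can absorb at most 6 DOF; capacity 7 leaves 1 redundant
        state = run(WeightedNetwork(2, [(0, 1, 7.0)]))
        assert state.free_dof() == pytest.approx(6.0)
        assert state.absorbed_redundant == pytest.approx(1.0)
        assert state.find(0) == state.find(1)
        assert state.ledger_residual() == pytest.approx(0.0)

    def test_edge_internal_to_supervertex_is_redundant(self):
        state = init_state(WeightedNetwork(2, []))
        state.insert_edge(0, 1, 6.0)
        state.insert_edge(0, 1, 3.0)
        assert state.absorbed_redundant == pytest.approx(3.0)
        assert state.free_dof() == pytest.approx(6.0)

    def test_zero_capacity_edge_is_a_no_op(self):
        state = init_state(WeightedNetwork(2, []))
        state.insert_edge(0, 1, 0.0)
        assert state.free_dof() == 12
        assert state.absorbed_redundant == 0

    def test_pull_through_chain_conserves_ledger(self):
        state = run(WeightedNetwork(3, [(0, 1, 6.0), (1, 2, 6.0)]))
        assert state.free_dof() == pytest.approx(6.0)
        assert state.ledger_residual() == pytest.approx(0.0)
        assert state.rigid_cluster_decomposition().cluster_sizes == [3]

    def test_collect_on_isolated_vertex(self):
        state = init_state(WeightedNetwork(2, []))
        gathered, visited = state.collect_pebbles(0, 6)
        assert gathered == 6
        assert visited == {0}

    def test_condense_single_vertex_is_no_op(self):
        state = init_state(WeightedNetwork(2, []))
        state.condense([0])
        assert state.free_dof() == 12


class TestComponents:
    def test_disjoint_rigid_pieces_have_no_excess(self):
        # two disconnected rigid triangles: 12 free DOF, 6 trivial each
        edges = [(0, 1, 6.0), (1, 2, 6.0), (3, 4, 6.0), (4, 5, 6.0)]
        state = run(WeightedNetwork(6, edges))
        assert state.free_dof() == pytest.approx(12.0)
        assert state.excess_dof() == pytest.approx(0.0)

    def test_zero_edge_network_all_singletons(self):
        state = run(WeightedNetwork(4, []))
        assert state.excess_dof() == 0
        assert state.rigid_cluster_decomposition().cluster_sizes == [1] * 4

    def test_disconnected_bodies_share_six_dof(self):
        state = run(WeightedNetwork(2, []))
        assert state.shared_excess_dof(0, 1) == pytest.approx(6.0)
        assert state.shared_excess_dof(0, 0) == 0.0


class TestFullyRigidChain:
    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_exactly_six_dof_one_cluster(self, n):
        state = run(fully_rigid_network(n))
        assert state.free_dof() == pytest.approx(6.0)
        assert state.excess_dof() == pytest.approx(0.0)
        assert state.rigid_cluster_decomposition().cluster_sizes == [n]
        assert state.ledger_residual() == pytest.approx(0.0)


class TestProbeRestoration:
    def test_queries_do_not_mutate_converged_state(self, triangle):
        state = run(triangle)
        before_free = dict(state.free)
        before_covers = {
            (min(a, b), max(a, b)): dict(state.adj[a][b].cover)
            for a in state.adj for b in state.adj[a]
        }
        state.rigid_cluster_decomposition()
        state.shared_excess_dof(0, 2)
        assert state.free == before_free
        after_covers = {
            (min(a, b), max(a, b)): dict(state.adj[a][b].cover)
            for a in state.adj for b in state.adj[a]
        }
        assert after_covers == before_covers

    def test_queries_require_completed_run(self, triangle):
        state = init_state(triangle)
        with pytest.raises(PebbleEngineError):
            state.rigid_cluster_decomposition()
        with pytest.raises(PebbleEngineError):
            state.shared_excess_dof(0, 1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_free_dof_matches_lp_rank_oracle(seed):
    """Engine free DOF equals 6|V| minus the polymatroid LP rank."""
    rng = np.random.default_rng(seed)
    net = random_weighted_network(rng)
    state = run(net)
    rank = polymatroid_rank_oracle(net)
    assert state.free_dof() == pytest.approx(6 * net.n_vertices - rank,
                                             abs=1e-6)
    assert state.ledger_residual() == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_insertion_order_invariance(seed):
    """Total free DOF is the same for every edge insertion order."""
    rng = np.random.default_rng(seed)
    net = random_weighted_network(rng, max_edges=4)
    reference = run(net).free_dof()
    for perm in itertools.permutations(net.edges):
        state = run(WeightedNetwork(net.n_vertices, list(perm)))
        assert state.free_dof() == pytest.approx(reference, abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_integer_and_fractional_modes_coincide(seed):
    """On integer capacities the two modes are the same game."""
    rng = np.random.default_rng(seed)
    net = random_weighted_network(rng, integer=True)
    s_int = run(net, mode="integer")
    s_frac = run(net, mode="fractional")
    assert s_int.free_dof() == s_frac.free_dof()
    assert s_int.rigid_cluster_decomposition().label == \
        s_frac.rigid_cluster_decomposition().label


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_adding_an_edge_never_increases_free_dof(seed):
    rng = np.random.default_rng(seed)
    net = random_weighted_network(rng)
    if not net.edges:
        return
    smaller = WeightedNetwork(net.n_vertices, net.edges[:-1])
    assert run(net).free_dof() <= run(smaller).free_dof() + 1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_rcd_partition_consistent_with_shared_dof(seed):
    """Co-labeled pairs share no excess DOF; cross-cluster pairs share some."""
    rng = np.random.default_rng(seed)
    net = random_weighted_network(rng)
    state = run(net)
    labels = state.rigid_cluster_decomposition().label
    assert len(labels) == net.n_vertices
    for a, b in itertools.combinations(range(net.n_vertices), 2):
        shared = state.shared_excess_dof(a, b)
        if labels[a] == labels[b]:
            assert shared <= 1e-9
        else:
            assert shared > 1e-9
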