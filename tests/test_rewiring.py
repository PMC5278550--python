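import networkx as nx
import numpy as np
import pytest

from robustcoop import graph_core as gc
from robustcoop import rewiring as rw
from robustcoop import robustness as rb

from conftest import random_connected_graph


def apply_and_validate(g, move):
    rw.apply_move(g, move)
    assert not any(u == v for u, v in g.edges)
    return g


class TestRelink:
    def test_preserves_counts_and_shifts_two_degrees(self, rng):
        g = random_connected_graph(20, 40, 0)
        for _ in range(100):
            work = g.copy()
            before = dict(work.degree())
            move = rw.propose_relink(work, rng)
            apply_and_validate(work, move)
            assert work.number_of_nodes() == 20
            assert work.number_of_edges() == 40
            after = dict(work.degree())
            changed = {v: after[v] - before[v] for v in work if after[v] != before[v]}
            assert sorted(changed.values()) == [-1, 1]

    def test_only_legal_relinks_attach_isolated_node(self, rng):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        g.add_node(3)
        for _ in range(20):
            move = rw.propose_relink(g, rng)
            assert any(3 in e for e in move.added)

    def test_complete_graph_has_no_move(self, rng):
        with pytest.raises(rw.MoveError):
            rw.propose_relink(nx.complete_graph(5), rng)

    def test_changes_heterogeneity(self, rng):
        """Relinks reshape the degree distribution (H moves)."""
        g = nx.watts_strogatz_graph(30, 4, 0.0, seed=0)  # regular: H = 0
        work = g.copy()
        rw.apply_move(work, rw.propose_relink(work, rng))
        assert gc.heterogeneity(work) > 0.0


class TestSwap:
    def test_degree_sequence_and_H_exactly_preserved(self, rng):
        g = random_connected_graph(25, 50, 1)
        h0 = gc.heterogeneity(g)
        degrees0 = sorted(d for _, d in g.degree())
        work = g.copy()
        for _ in range(100):
            try:
                move = rw.propose_swap(work, rng)
            except rw.MoveError:
                break
            apply_and_validate(work, move)
            assert dict(work.degree()) == dict(g.degree())
        assert sorted(d for _, d in work.degree()) == degrees0
        assert gc.heterogeneity(work) == h0  # bitwise: same degree multiset
        assert work.number_of_edges() == 50

    def test_directed_swaps_steer_assortativity(self, rng):
        """Accepted r-increasing swaps raise r (Xulvi-Brunet–Sokolov style)."""
        g = gc.generate_ba(100, 2, seed=4)
        r0 = gc.assortativity(g)
        work = g.copy()
        accepted = 0
        while accepted < 100:
            try:
                move = rw.propose_swap(work, rng, direction="increase_r")
            except rw.MoveError:
                break
            rw.apply_move(work, move)
            accepted += 1
        assert gc.assortativity(work) > r0 + 0.1

    def test_too_few_edges_rejected(self, rng):
        with pytest.raises(rw.MoveError):
            rw.propose_swap(nx.path_graph(2), rng)


class TestDirectedMoves:
    def test_robustness_moves_never_lower_R(self, rng):
        g = gc.generate_ba(60, 2, seed=1)
        r0 = rb.robustness_R(g)
        out = rw.robustness_directed_moves(g, steps=10, patience=100, rng=rng)
        assert rb.robustness_R(out) >= r0
        assert out.number_of_edges() == g.number_of_edges()
        assert nx.is_connected(out)

    def test_cooperation_moves_conserve_counts_and_connectivity(self, rng):
        g = gc.generate_ws(60, 4, 0.1, seed=1)
        out = rw.cooperation_directed_moves(g, steps=15, patience=100, rng=rng)
        assert out.number_of_nodes() == 60
        assert out.number_of_edges() == g.number_of_edges()
        assert nx.is_connected(out)

    def test_cooperation_moves_preserve_degrees_by_default(self, rng):
        """Default cooperation variation is degree-preserving (swaps only)."""
        g = gc.generate_ba(80, 2, seed=2)
        out = rw.cooperation_directed_moves(g, steps=20, patience=100, rng=rng)
        assert dict(out.degree()) == dict(g.degree())
        assert gc.assortativity(out) < gc.assortativity(g)

    def test_hub_biased_relinks_grow_hubs_from_homogeneous_start(self, rng):
        """The optional relink mix creates hub-and-spoke structure."""
        g = gc.generate_ws(80, 4, 0.05, seed=2)
        max0 = max(d for _, d in g.degree())
        work = g
        for _ in range(10):
            work = rw.cooperation_directed_moves(
                work, steps=20, patience=100, rng=rng, relink_mix=1.0
            )
        assert max(d for _, d in work.degree()) > max0 + 3
        assert gc.heterogeneity(work) > gc.heterogeneity(g)


class TestHillClimb:
    def test_trajectory_strictly_monotone(self):
        g = gc.generate_ba(60, 2, seed=3)
        for objective, direction in (("R", "max"), ("H", "min"), ("H", "max")):
            _, value, traj = rw.hill_climb(
                g, objective, direction, patience=100, rng=0, max_accepts=30
            )
            diffs = np.diff(traj)
            assert np.all(diffs > 0) if direction == "max" else np.all(diffs < 0)

    def test_final_value_no_worse_than_start(self):
        g = gc.generate_ba(60, 2, seed=3)
        start = rb.robustness_R(g)
        _, value, _ = rw.hill_climb(g, "R", "max", patience=50, rng=1, max_accepts=10)
        assert value >= start

    def test_minimum_structure_returned_unchanged(self, rng):
        # H of a regular ring is already 0: no relink can reduce it further
        ring = nx.watts_strogatz_graph(20, 4, 0.0, seed=0)
        out, value, traj = rw.hill_climb(ring, "H", "min", patience=25, rng=rng)
        assert value == 0.0
        assert traj == []
        assert set(out.edges) == set(ring.edges)

    def test_connectivity_preserved_when_required(self):
        g = gc.generate_ba(40, 2, seed=6)
        out, _, _ = rw.hill_climb(
            g, "H", "max", patience=50, rng=2, max_accepts=50, connectivity_required=True
        )
        assert nx.is_connected(out)

    def test_input_graph_not_mutated(self):
        g = gc.generate_ba(30, 2, seed=8)
        edges_before = set(g.edges)
        rw.hill_climb(g, "H", "max", patience=30, rng=3, max_accepts=10)
        assert set(g.edges) == edges_before

    def test_undefined_objective_signalled(self, rng):
        ring = nx.watts_strogatz_graph(20, 4, 0.0, seed=0)
        with pytest.raises(gc.UndefinedMeasureError):
            rw.hill_climb(ring, "r", "max", patience=10, rng=rng)

    def test_unknown_objective_rejected(self, rng):
        with pytest.raises(ValueError):
            rw.hill_climb(nx.path_graph(5), "Q", "max", rng=rng)

    def test_swap_climb_keeps_H_fixed_while_moving_r(self):
        """The key operator separation: swaps move r at exactly fixed H."""
        g = gc.generate_ba(80, 2, seed=9)
        h0 = gc.heterogeneity(g)
        out, r_val, traj = rw.hill_climb(
            g, "r", "max", patience=100, rng=4, max_accepts=50
        )
        assert len(traj) > 0
        assert r_val > gc.assortativity(g)
        assert gc.heterogeneity(out) == h0
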