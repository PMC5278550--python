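import dataclasses

import numpy as np
import pytest

from robustcoop import graph_core as gc
from robustcoop import moea


def brute_force_fronts(points):
    """Peel non-dominated layers by exhaustive pairwise comparison."""
    remaining = list(range(len(points)))
    ranks = {}
    rank = 1
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                moea._dominates(points[j], points[i]) for j in remaining if j != i
            )
        ]
        for i in front:
            ranks[i] = rank
        remaining = [i for i in remaining if i not in front]
        rank += 1
    return np.array([ranks[i] for i in range(len(points))])


def make_individual(r, fc, seed=0):
    return moea.Individual(
        network=gc.generate_er(10, 12, seed), robustness=r, cooperation=fc,
        eval_seed=seed, realizations=1,
    )


class TestNondominatedSort:
    def test_mutually_nondominated_front(self):
        ranks = moea.fast_nondominated_sort([(1, 3), (2, 2), (3, 1)])
        assert list(ranks) == [1, 1, 1]

    def test_dominated_point_demoted(self):
        ranks = moea.fast_nondominated_sort([(1, 3), (2, 2), (3, 1), (1, 1)])
        assert list(ranks) == [1, 1, 1, 2]

    def test_matches_brute_force_on_random_point_sets(self, rng):
        for _ in range(20):
            pts = [tuple(p) for p in rng.random((40, 2)).round(1)]
            np.testing.assert_array_equal(
                moea.fast_nondominated_sort(pts), brute_force_fronts(pts)
            )


class TestCrowding:
    def test_boundary_points_infinite(self):
        pts = [(1, 3), (2, 2), (3, 1)]
        ranks = moea.fast_nondominated_sort(pts)
        dist = moea.crowding_distance(pts, ranks)
        assert dist[0] == np.inf and dist[2] == np.inf

    def test_middle_point_normalized_distance(self):
        pts = [(1, 3), (2, 2), (3, 1)]
        dist = moea.crowding_distance(pts, moea.fast_nondominated_sort(pts))
        assert dist[1] == pytest.approx(2.0)

    def test_compare_prefers_lower_rank_then_distance(self):
        ranks = np.array([1, 2, 1, 1])
        dist = np.array([0.5, np.inf, 2.0, 2.0])
        assert moea.crowded_compare(0, 1, ranks, dist) == 0
        assert moea.crowded_compare(0, 2, ranks, dist) == 2
        assert moea.crowded_compare(2, 3, ranks, dist) == 2  # full tie: first


class TestArchive:
    def test_dominated_candidate_ignored(self):
        archive = moea.ParetoArchive([make_individual(2, 2)])
        assert not archive.add(make_individual(1, 1))
        assert len(archive) == 1

    def test_dominating_candidate_replaces_all(self):
        archive = moea.ParetoArchive([make_individual(1, 2), make_individual(2, 1)])
        assert archive.add(make_individual(3, 3))
        assert [m.objectives for m in archive] == [(3, 3)]

    def test_matches_replay_oracle(self, rng):
        """Archive equals the non-dominated filter of every candidate seen."""
        stream = [make_individual(r, fc) for r, fc in rng.random((200, 2)).round(2)]
        archive = moea.ParetoArchive()
        moea.update_EP(archive, stream)
        pts = [ind.objectives for ind in stream]
        expected = set()
        seen = set()
        for i, p in enumerate(pts):
            if p in seen:
                continue
            seen.add(p)
            if not any(moea._dominates(q, p) for q in pts if q != p):
                expected.add(p)
        assert {m.objectives for m in archive} == expected

    def test_archive_always_mutually_nondominated(self, rng):
        archive = moea.ParetoArchive()
        for r, fc in rng.random((100, 2)):
            archive.add(make_individual(r, fc))
            objs = [m.objectives for m in archive.members]
            assert all(
                not moea._dominates(a, b)
                for i, a in enumerate(objs)
                for j, b in enumerate(objs)
                if i != j
            )


@pytest.fixture(scope="module")
def tiny_cfg():
    return moea.MoeaConfig(
        initial="ba",
        n=40,
        mean_degree=4.0,
        omega=6,
        generations=3,
        search_realizations=2,
        search_transient=60,
        select_realizations=2,
        select_transient=60,
        report_realizations=3,
        report_transient=80,
        sample_sweeps=20,
        mutation_steps=3,
        mutation_patience=10,
        init_patience=40,
        init_budget=300,
        archive_topup_realizations=0,  # deterministic cached evaluations
        seed=5,
    )


@pytest.fixture(scope="module")
def tiny_result(tiny_cfg):
    return moea.run_moea(tiny_cfg)


class TestMutation:
    def test_offspring_conserves_counts(self, tiny_cfg, rng):
        parent = moea.evaluate_network(tiny_cfg.base_network(rng), tiny_cfg, 3)
        m0 = parent.network.number_of_edges()
        for _ in range(5):
            child = moea.mutate(parent, tiny_cfg, rng)
            assert child.network.number_of_nodes() == 40
            assert child.network.number_of_edges() == m0

    def test_robustness_branch_never_lowers_R(self, tiny_cfg, rng):
        cfg = dataclasses.replace(tiny_cfg, operator_mix=1.0)
        parent = moea.evaluate_network(cfg.base_network(rng), cfg, 3)
        for _ in range(5):
            assert moea.mutate(parent, cfg, rng).robustness >= parent.robustness

    def test_cooperation_branch_preserves_counts_and_varies(self, tiny_cfg, rng):
        cfg = dataclasses.replace(tiny_cfg, operator_mix=0.0)
        parent = moea.evaluate_network(cfg.base_network(rng), cfg, 3)
        child = moea.mutate(parent, cfg, rng)
        assert child.network.number_of_nodes() == parent.network.number_of_nodes()
        assert child.network.number_of_edges() == parent.network.number_of_edges()
        assert set(child.network.edges) != set(parent.network.edges)


class TestRunMoea:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            moea.run_moea(moea.MoeaConfig(omega=1))
        with pytest.raises(ValueError):
            moea.MoeaConfig(initial="edgelist").base_network(np.random.default_rng(0))

    def test_every_network_keeps_N_and_M(self, tiny_result):
        m0 = tiny_result.base_network.number_of_edges()
        for member in tiny_result.archive:
            assert member.network.number_of_nodes() == 40
            assert member.network.number_of_edges() == m0
            gc.validate_network(member.network)

    def test_archive_sorted_by_R_has_nonincreasing_fc(self, tiny_result):
        members = tiny_result.archive.sorted_by_robustness()
        fcs = [m.cooperation for m in members]
        assert all(a >= b for a, b in zip(fcs, fcs[1:]))

    def test_hypervolume_nondecreasing_across_generations(self, tiny_result):
        # holds exactly when archive evaluations are deterministic (no top-up)
        hv = [entry["hypervolume"] for entry in tiny_result.log]
        assert all(a <= b + 1e-12 for a, b in zip(hv, hv[1:]))

    def test_archive_topup_refines_estimates(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, archive_topup_realizations=2, generations=2)
        result = moea.run_moea(cfg)
        # long-lived members accumulated extra realizations beyond the search batch
        assert max(m.realizations for m in result.archive) > cfg.search_realizations

    def test_bitwise_reproducible_from_master_seed(self, tiny_cfg, tiny_result):
        again = moea.run_moea(tiny_cfg)
        assert [m.objectives for m in again.archive] == [
            m.objectives for m in tiny_result.archive
        ]
        assert {frozenset(m.network.edges) for m in again.archive} == {
            frozenset(m.network.edges) for m in tiny_result.archive
        }

    def test_initialize_population_spreads_heterogeneity(self, tiny_cfg, rng):
        base = tiny_cfg.base_network(rng)
        population = moea.initialize_population(base, 6, tiny_cfg, rng)
        assert len(population) == 6
        h_values = [gc.heterogeneity(ind.network) for ind in population]
        assert max(h_values) - min(h_values) > 0.05
        m0 = base.number_of_edges()
        assert all(ind.network.number_of_edges() == m0 for ind in population)
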