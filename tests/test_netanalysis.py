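"""Cluster extraction and behavioural metrics."""

import networkx as nx
import numpy as np
import pytest

from evacsim.attitudes import CommunicationGraph, CommunicationParams
from evacsim.engine import SimulationConfig, run_simulation
from evacsim.netanalysis import (
    behaviour_change_ratio,
    cluster_trajectories,
    evacuated_attitude_histogram,
    extract_clusters,
    group_size_timeseries,
    large_group_share,
    max_negative_cluster_size,
    normalise_time,
)


def random_graph(n, p, seed):
    r = np.random.default_rng(seed)
    mask = (r.random((n, n)) < p) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    return CommunicationGraph(n=n, src=src, dst=dst)


def partition_sets(clusters):
    return {frozenset(c.members.tolist()) for c in clusters}


class TestClusters:
    def test_empty_edges_all_singletons(self):
        g = CommunicationGraph(n=5, src=np.empty(0, int), dst=np.empty(0, int))
        cl = extract_clusters(g)
        assert len(cl) == 5 and all(c.size == 1 for c in cl)

    def test_three_cycle_plus_isolate(self):
        g = CommunicationGraph(n=4, src=np.array([0, 1, 2]), dst=np.array([1, 2, 0]))
        sizes = sorted(c.size for c in extract_clusters(g))
        assert sizes == [1, 3]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_networkx_scc(self, seed):
        g = random_graph(30, 0.05, seed)
        ours = partition_sets(extract_clusters(g))
        nxg = g.to_networkx()
        theirs = {frozenset(s) for s in nx.strongly_connected_components(nxg)}
        assert ours == theirs

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_reachability_oracle(self, seed):
        """Brute force: i ~ j iff i reaches j and j reaches i."""
        n = 12
        g = random_graph(n, 0.12, 100 + seed)
        adj = np.zeros((n, n), dtype=bool)
        adj[g.src, g.dst] = True
        reach = adj | np.eye(n, dtype=bool)
        for _ in range(n):
            reach = reach | (reach @ reach)
        mutual = reach & reach.T
        expected = {frozenset(np.nonzero(mutual[i])[0].tolist()) for i in range(n)}
        assert partition_sets(extract_clusters(g)) == expected

    def test_partition_covers_all_agents(self):
        g = random_graph(40, 0.08, 7)
        cl = extract_clusters(g)
        assert sum(c.size for c in cl) == 40

    def test_centre_and_attitude_fill_in(self):
        g = CommunicationGraph(n=2, src=np.array([0, 1]), dst=np.array([1, 0]))
        pos = np.array([[0.0, 0.0], [2.0, 2.0]])
        att = np.array([0.2, 0.6])
        (c,) = extract_clusters(g, positions=pos, attitudes=att, timestamp=3.0)
        assert np.allclose(c.centre, [1.0, 1.0])
        assert c.mean_attitude == pytest.approx(0.4)
        assert c.timestamp == 3.0


def make_result(graph, states_row, attitudes_row=None, positions_row=None,
                initial_attitudes=None, final_states=None, arrivals=None):
    """Minimal single-snapshot SimulationResult stand-in for metric tests."""
    from evacsim.engine import SimulationResult

    n = graph.n
    att = np.array([attitudes_row if attitudes_row is not None else np.zeros(n)],
                   dtype=np.float32)
    pos = np.array([positions_row if positions_row is not None else np.zeros((n, 2))],
                   dtype=np.float32)
    return SimulationResult(
        times=np.array([0.0]),
        attitudes=att,
        positions=pos,
        states=np.array([states_row], dtype=np.int8),
        graphs=[graph],
        initial_attitudes=(initial_attitudes if initial_attitudes is not None
                           else np.zeros(n)),
        initial_positions=pos[0],
        leader_indices=np.empty(0, dtype=np.intp),
        arrival_times=(arrivals if arrivals is not None else np.full(n, np.nan)),
        final_states=(final_states if final_states is not None
                      else np.array(states_row, dtype=np.int8)),
        horizon=100.0,
        seed=0,
    )


class TestGroupSizes:
    def test_large_small_counts(self):
        # 12-agent mutually connected evacuating cluster + 3 lone evacuees
        n = 15
        block = np.arange(12)
        src = np.repeat(block, 12)
        dst = np.tile(block, 12)
        m = src != dst
        g = CommunicationGraph(n=n, src=src[m], dst=dst[m])
        states = np.ones(n, dtype=np.int8)
        ts = group_size_timeseries(make_result(g, states), size_threshold=10)
        assert ts.loc[0, "large"] == 12 and ts.loc[0, "small"] == 3

    def test_exactly_threshold_counts_large(self):
        n = 10
        src = np.repeat(np.arange(n), n)
        dst = np.tile(np.arange(n), n)
        m = src != dst
        g = CommunicationGraph(n=n, src=src[m], dst=dst[m])
        ts = group_size_timeseries(make_result(g, np.ones(n)), size_threshold=10)
        assert ts.loc[0, "large"] == 10  # "10 or more" is inclusive

    def test_nobody_evacuating(self):
        g = CommunicationGraph(n=4, src=np.empty(0, int), dst=np.empty(0, int))
        ts = group_size_timeseries(make_result(g, np.zeros(4)))
        assert ts.loc[0, "large"] == 0 and ts.loc[0, "small"] == 0

    def test_idle_members_do_not_inflate_cluster_size(self):
        """Cluster size counts evacuating members only (induced subgraph)."""
        n = 12  # full 12-clique but only 4 evacuating
        src = np.repeat(np.arange(n), n)
        dst = np.tile(np.arange(n), n)
        m = src != dst
        g = CommunicationGraph(n=n, src=src[m], dst=dst[m])
        states = np.zeros(n)
        states[:4] = 1
        ts = group_size_timeseries(make_result(g, states), size_threshold=10)
        assert ts.loc[0, "large"] == 0 and ts.loc[0, "small"] == 4


class TestClusterTrajectories:
    def test_sign_classification_and_min_size(self):
        # two 2-clusters: one positive (0.6), one negative (-0.4); one singleton
        g = CommunicationGraph(
            n=5, src=np.array([0, 1, 2, 3]), dst=np.array([1, 0, 3, 2])
        )
        att = np.array([0.6, 0.6, -0.4, -0.4, 0.9])
        pos = np.array([[0, 0], [1, 0], [5, 5], [6, 5], [9, 9]], dtype=float)
        res = make_result(g, np.ones(5), attitudes_row=att, positions_row=pos)
        pos_traj = cluster_trajectories(res, "positive", min_size=2)
        neg_traj = cluster_trajectories(res, "negative", min_size=2)
        assert len(pos_traj) == 1 and pos_traj.loc[0, "size"] == 2
        assert pos_traj.loc[0, "mean_attitude"] == pytest.approx(0.6)
        assert len(neg_traj) == 1 and neg_traj.loc[0, "x"] == pytest.approx(5.5)
        # the positive singleton is excluded by min_size
        assert max_negative_cluster_size(res) == 2

    def test_invalid_sign(self):
        g = CommunicationGraph(n=1, src=np.empty(0, int), dst=np.empty(0, int))
        with pytest.raises(ValueError):
            cluster_trajectories(make_result(g, np.zeros(1)), "sideways")


class TestHistogramAndRatios:
    def test_nobody_evacuated_all_zero(self):
        g = CommunicationGraph(n=3, src=np.empty(0, int), dst=np.empty(0, int))
        res = make_result(g, np.zeros(3), final_states=np.zeros(3, dtype=np.int8))
        counts, edges, frac = evacuated_attitude_histogram(res)
        assert counts.sum() == 0 and frac == 0.0
        assert len(edges) == 21

    def test_band_fraction_excludes_high(self):
        g = CommunicationGraph(n=4, src=np.empty(0, int), dst=np.empty(0, int))
        res = make_result(
            g,
            np.full(4, 2),
            initial_attitudes=np.array([0.9, 0.9, 0.9, 0.9]),
            final_states=np.full(4, 2, dtype=np.int8),
        )
        _, _, frac = evacuated_attitude_histogram(res)
        assert frac == 0.0

    def test_bin_width_must_divide_range(self):
        g = CommunicationGraph(n=1, src=np.empty(0, int), dst=np.empty(0, int))
        res = make_result(g, np.zeros(1))
        with pytest.raises(ValueError):
            evacuated_attitude_histogram(res, bin_width=0.3)

    def test_frozen_limit_band_fraction(self, small_city, small_nav):
        """mu = 0: evacuated set = {A0 >= 0.5}; P(A <= 0.8 | A >= 0.5) = 0.6."""
        cfg = SimulationConfig(
            urban=small_city,
            n_agents=400,
            comm=CommunicationParams(mu=0.0),
            horizon=600.0,
            seed=17,
        )
        res = run_simulation(cfg, nav=small_nav)
        _, _, frac = evacuated_attitude_histogram(res)
        n_evac = int((res.final_states == 2).sum())
        se = np.sqrt(0.6 * 0.4 / n_evac)
        assert abs(frac - 0.6) < 4 * se

    def test_behaviour_change_ratio(self):
        g = CommunicationGraph(n=4, src=np.empty(0, int), dst=np.empty(0, int))
        res = make_result(
            g,
            np.zeros(4),
            initial_attitudes=np.array([0.6, 0.7, 0.2, -0.5]),
            final_states=np.array([2, 0, 0, 0], dtype=np.int8),
        )
        assert behaviour_change_ratio(res) == pytest.approx(0.5)
        res_none = make_result(
            g, np.zeros(4), initial_attitudes=np.full(4, -0.9)
        )
        with pytest.raises(ValueError):
            behaviour_change_ratio(res_none)

    def test_frozen_limit_no_behaviour_change(self, small_city, small_nav):
        cfg = SimulationConfig(
            urban=small_city,
            n_agents=200,
            comm=CommunicationParams(mu=0.0),
            horizon=600.0,
            seed=19,
        )
        res = run_simulation(cfg, nav=small_nav)
        assert behaviour_change_ratio(res) == 0.0

    def test_normalise_time(self):
        g = CommunicationGraph(n=2, src=np.empty(0, int), dst=np.empty(0, int))
        res = make_result(
            g,
            np.full(2, 2),
            final_states=np.full(2, 2, dtype=np.int8),
            arrivals=np.array([40.0, 80.0]),
        )
        res.times = np.array([0.0, 40.0, 80.0])
        tn = normalise_time(res)
        assert np.allclose(tn, [0.0, 0.5, 1.0])
        res_none = make_result(g, np.zeros(2))
        with pytest.raises(ValueError):
            normalise_time(res_none)

    def test_large_group_share_bounds(self, small_city, small_nav):
        cfg = SimulationConfig(urban=small_city, n_agents=120, horizon=200.0, seed=23)
        res = run_simulation(cfg, nav=small_nav)
        s = large_group_share(res)
        assert 0.0 <= s <= 1.0
        s_int = large_group_share(res, phase=None)
        assert 0.0 <= s_int <= 1.0
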