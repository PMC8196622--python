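"""Lagged correlation, graph construction, network metrics, recovery."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from calcinet import (ConnectivityGraph, GroundTruth, SyntheticScenario,
                      build_graph, compute_dff, compute_metrics,
                      correlation_vs_distance, evaluate_recovery,
                      lagged_correlation, pairwise_lagged_correlations,
                      render_traces, simulate_events, simulate_recording)
from calcinet.network import PAIR_COLUMNS, PairwiseCorrelations
from calcinet.simulate import EDGE_COLUMNS

from _reference import (naive_graph_edges, naive_lagged_correlation,
                        set_recovery)
from conftest import make_traceset


def smooth_noise(rng, n, scale=5):
    raw = rng.normal(size=n + scale)
    return np.convolve(raw, np.ones(scale) / scale, mode="valid")[:n]


class TestLaggedCorrelation:
    def test_self_correlation_is_one_at_zero_lag(self):
        rng = np.random.default_rng(0)
        a = smooth_noise(rng, 300)
        res = lagged_correlation(a, a, 10.0, 2.0)
        assert res.rho == pytest.approx(1.0, abs=1e-12)
        assert res.lag == 0.0

    def test_pure_shift_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = smooth_noise(rng, 400)
        b = np.roll(a, 3)  # b[3:] == a[:-3]
        res = lagged_correlation(a, b, 10.0, 2.0)
        assert res.rho == pytest.approx(1.0, abs=1e-6)
        assert res.lag == pytest.approx(1.5)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(2)
        a = smooth_noise(rng, 500)
        b = np.roll(smooth_noise(rng, 500) + 0.5 * a, 4)
        fwd = lagged_correlation(a, b, 10.0, 2.0)
        rev = lagged_correlation(b, a, 10.0, 2.0)
        assert rev.rho == pytest.approx(fwd.rho, abs=1e-12)
        assert rev.lag == pytest.approx(-fwd.lag)

    def test_matches_bruteforce_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=200)
            b = rng.normal(size=200)
            got = lagged_correlation(a, b, 10.0, 2.0)
            rho, lag = naive_lagged_correlation(a, b, 20, 2.0)
            assert got.rho == pytest.approx(rho, abs=1e-10)
            assert got.lag == lag

    def test_zero_variance_pair_raises(self):
        with pytest.raises(ValueError, match="not correlatable"):
            lagged_correlation(np.ones(100), np.arange(100.0), 5.0, 2.0)

    def test_pairwise_matches_single_pair_path(self):
        rng = np.random.default_rng(4)
        ts = make_traceset(np.array([smooth_noise(rng, 300)
                                     for _ in range(6)]))
        pw = pairwise_lagged_correlations(ts, max_lag=8.0)
        for row in pw.table.itertuples(index=False):
            i = ts.cell_ids.index(row.cell_a)
            j = ts.cell_ids.index(row.cell_b)
            single = lagged_correlation(ts.fluorescence[i],
                                        ts.fluorescence[j], 8.0, 2.0)
            assert row.rho == pytest.approx(single.rho, abs=1e-10)
            assert row.lag_s == pytest.approx(single.lag)

    def test_constant_trace_pairs_skipped_not_fatal(self):
        rng = np.random.default_rng(5)
        mat = np.array([smooth_noise(rng, 200), smooth_noise(rng, 200),
                        np.full(200, 7.0)])
        pw = pairwise_lagged_correlations(make_traceset(mat), max_lag=5.0)
        assert pw.n_skipped == 2
        assert len(pw.table) == 1
        graph = build_graph(make_traceset(mat), pairwise=pw)
        assert graph.n_cells == 3  # nodes kept even when uncorrelatable


class TestBuildGraph:
    def test_identical_traces_give_reciprocal_zero_lag_clique(self):
        rng = np.random.default_rng(6)
        base = smooth_noise(rng, 300)
        ts = make_traceset(np.tile(base, (3, 1)))
        graph = build_graph(ts, max_lag=5.0)
        assert graph.n_edges == 6
        for _, _, d in graph.graph.edges(data=True):
            assert d["lag_s"] == 0.0
            assert d["rho"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_reference_on_noise(self):
        rng = np.random.default_rng(7)
        ts = make_traceset(rng.normal(size=(8, 400)),
                           positions=rng.uniform(0, 400, (8, 2)))
        graph = build_graph(ts, edge_threshold=0.05, max_lag=5.0)
        oracle = naive_graph_edges(ts.fluorescence, ts.cell_ids, 2.0, 10,
                                   threshold=0.05)
        assert graph.edge_set() == oracle

    def test_planted_chain_recovered_with_correct_lag(self):
        sc = SyntheticScenario(n_cells=2, transmit_probability=1.0,
                               delay_jitter_sd=0.0, noise_sd=0.02,
                               duration=600.0, seed=0)
        edges = pd.DataFrame([[0, 1, 2.0, 40.0]], columns=EDGE_COLUMNS)
        truth = GroundTruth(positions=np.array([[0.0, 0.0], [40.0, 0.0]]),
                            edges=edges)
        drive = [np.sort(np.random.default_rng(0).uniform(0, 590, 12)),
                 np.array([])]
        events, _ = simulate_events(truth, sc, spontaneous=drive)
        ts = render_traces(events, sc, truth.positions)
        graph = build_graph(compute_dff(ts))
        assert ("cell_000", "cell_001") in graph.edge_set()
        lag = graph.graph.edges["cell_000", "cell_001"]["lag_s"]
        assert lag == pytest.approx(2.0, abs=0.5)

    def test_raising_threshold_only_removes_edges(self, small_recording):
        ts, _ = small_recording
        dff = compute_dff(ts)
        pw = pairwise_lagged_correlations(dff)
        previous = None
        for threshold in (0.1, 0.2, 0.3, 0.5, 0.8):
            graph = build_graph(dff, edge_threshold=threshold, pairwise=pw)
            metrics = compute_metrics(graph, pw)
            if previous is not None:
                assert graph.edge_set() <= previous.edge_set()
                assert metrics.mean_connections_per_cell <= \
                    prev_metrics.mean_connections_per_cell
                assert metrics.percent_possible_connections <= \
                    prev_metrics.percent_possible_connections
            previous, prev_metrics = graph, metrics

    def test_permutation_equivariance(self, small_recording):
        ts, _ = small_recording
        dff = compute_dff(ts)
        perm = [3, 1, 7, 0, 5, 2, 6, 4]
        shuffled = dff.subset(perm)
        g1 = build_graph(dff)
        g2 = build_graph(shuffled)
        assert g1.edge_set() == g2.edge_set()  # labels travel with the cells
        m1 = compute_metrics(g1, pairwise_lagged_correlations(dff))
        m2 = compute_metrics(g2, pairwise_lagged_correlations(shuffled))
        assert m1.percent_possible_connections == pytest.approx(
            m2.percent_possible_connections)
        assert (m1.mean_corr_all or 0.0) == pytest.approx(
            m2.mean_corr_all or 0.0, abs=1e-12)

    def test_time_reversal_flips_edge_orientation(self):
        sc = SyntheticScenario(n_cells=2, transmit_probability=1.0,
                               delay_jitter_sd=0.0, noise_sd=0.02,
                               duration=600.0, seed=1)
        edges = pd.DataFrame([[0, 1, 3.0, 60.0]], columns=EDGE_COLUMNS)
        truth = GroundTruth(positions=np.array([[0.0, 0.0], [60.0, 0.0]]),
                            edges=edges)
        drive = [np.sort(np.random.default_rng(1).uniform(0, 590, 12)),
                 np.array([])]
        events, _ = simulate_events(truth, sc, spontaneous=drive)
        ts = render_traces(events, sc, truth.positions)
        dff = compute_dff(ts)
        forward = build_graph(dff)
        backward = build_graph(dff.with_fluorescence(dff.fluorescence[:, ::-1]))
        assert forward.edge_set() == {("cell_000", "cell_001")}
        assert backward.edge_set() == {("cell_001", "cell_000")}
        rho_f = forward.graph.edges["cell_000", "cell_001"]["rho"]
        rho_b = backward.graph.edges["cell_001", "cell_000"]["rho"]
        assert rho_b == pytest.approx(rho_f, abs=1e-9)


def manual_graph(nodes, edges, threshold=0.3, max_lag=10.0):
    g = nx.DiGraph()
    for name, (x, y) in nodes.items():
        g.add_node(name, x=x, y=y)
    for src, dst, rho, lag, dist in edges:
        attrs = {"rho": rho, "lag_s": lag, "distance_um": dist}
        if lag > 0:
            attrs["speed_um_s"] = dist / lag
        g.add_edge(src, dst, **attrs)
    return ConnectivityGraph(graph=g, edge_threshold=threshold,
                             max_lag=max_lag)


def manual_pairwise(rows):
    return PairwiseCorrelations(
        table=pd.DataFrame(rows, columns=PAIR_COLUMNS),
        max_lag=10.0, method="pearson",
        n_cells=len({c for r in rows for c in r[:2]}))


class TestComputeMetrics:
    def test_complete_synchronous_graph_closed_form(self):
        nodes = {f"c{i}": (50.0 * i, 0.0) for i in range(4)}
        edges = [(a, b, 0.5, 0.0, abs(int(a[1]) - int(b[1])) * 50.0)
                 for a, b in itertools.permutations(nodes, 2)]
        pw = manual_pairwise(
            [[a, b, 0.5, 0.0, 0.5, abs(int(a[1]) - int(b[1])) * 50.0]
             for a, b in itertools.combinations(nodes, 2)])
        m = compute_metrics(manual_graph(nodes, edges), pw)
        assert m.mean_corr_all == pytest.approx(0.5)
        assert m.mean_connections_per_cell == pytest.approx(6.0)
        assert m.percent_possible_connections == pytest.approx(100.0)
        assert m.mean_delay_rate is None  # no positive-lag edge

    def test_empty_graph_zeroes_and_absences(self):
        nodes = {"a": (0.0, 0.0), "b": (10.0, 0.0), "c": (500.0, 0.0)}
        m = compute_metrics(manual_graph(nodes, []), manual_pairwise([]))
        assert m.mean_connections_per_cell == 0.0
        assert m.percent_possible_connections == 0.0
        assert m.mean_corr_all is None
        assert m.mean_delay_rate is None

    def test_hand_worked_five_node_fixture(self):
        # 5 cells on a line at 0,80,160,240,320 um; two directed edges:
        # a->b (rho .6, lag 4 s, 80 um -> 20 um/s) and
        # c->e (rho .4, lag 8 s, 160 um -> 20 um/s).
        nodes = {n: (80.0 * i, 0.0)
                 for i, n in enumerate("abcde")}
        edges = [("a", "b", 0.6, 4.0, 80.0), ("c", "e", 0.4, 8.0, 160.0)]
        rows = []
        rho_by_pair = {("a", "b"): 0.6, ("c", "e"): 0.4}
        for x, y in itertools.combinations("abcde", 2):
            dist = abs(ord(x) - ord(y)) * 80.0
            rows.append([x, y, rho_by_pair.get((x, y), 0.1), 0.0, 0.1, dist])
        m = compute_metrics(manual_graph(nodes, edges), manual_pairwise(rows),
                            adjacency_radius=100.0)
        # mean over 10 pairs: (0.6 + 0.4 + 8*0.1)/10
        assert m.mean_corr_all == pytest.approx(0.18)
        # adjacent pairs (<=100 um): the four 80-um neighbours,
        # rho = .6,.1,.1,.1
        assert m.mean_corr_adjacent == pytest.approx(0.225)
        assert m.mean_connections_per_cell == pytest.approx(2 * 2 / 5)
        assert m.percent_possible_connections == pytest.approx(
            100.0 * 2 / 20)
        assert m.mean_delay_rate == pytest.approx(20.0)


class TestDistanceCorrelation:
    def test_two_cells_give_one_point(self):
        pw = manual_pairwise([["a", "b", 0.4, 0.0, 0.4, 120.0]])
        points, binned = correlation_vs_distance(pw)
        assert len(points) == 1
        assert binned["bin_left_um"].tolist() == [100.0]

    def test_colocated_pair_retained_at_distance_zero(self):
        pw = manual_pairwise([["a", "b", 0.9, 0.0, 0.9, 0.0]])
        points, _ = correlation_vs_distance(pw)
        assert points["distance_um"].tolist() == [0.0]


class TestEvaluateRecovery:
    def _truth(self, edges, n=4):
        table = pd.DataFrame(
            [[s, d, 1.0, 50.0] for s, d in edges], columns=EDGE_COLUMNS
        ).astype({"src": int, "dst": int})
        return GroundTruth(positions=np.zeros((n, 2)), edges=table)

    def _graph(self, edges, n=4):
        ids = [f"cell_00{i}" for i in range(n)]
        nodes = {cid: (0.0, 0.0) for cid in ids}
        return manual_graph(nodes, [(ids[s], ids[d], 0.5, 1.0, 50.0)
                                    for s, d in edges])

    def test_perfect_recovery(self):
        truth = self._truth([(0, 1), (2, 3)])
        graph = self._graph([(0, 1), (2, 3)])
        score = evaluate_recovery(graph, truth)
        assert score.precision == score.recall == score.f1 == 1.0
        assert score.delay_error == pytest.approx(0.0)

    def test_empty_inference_leaves_precision_undefined(self):
        score = evaluate_recovery(self._graph([]), self._truth([(0, 1)]))
        assert score.recall == 0.0
        assert score.precision is None
        assert score.f1 is None

    def test_mismatched_cell_sets_rejected(self):
        with pytest.raises(ValueError, match="different cell sets"):
            evaluate_recovery(self._graph([], n=3), self._truth([(0, 1)], n=4))

    def test_random_graphs_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        ids = [f"cell_00{i}" for i in range(5)]
        pairs = list(itertools.permutations(range(5), 2))
        for _ in range(20):
            true = [pairs[i] for i in rng.choice(len(pairs), 6, replace=False)]
            guess = [pairs[i] for i in rng.choice(len(pairs), 6,
                                                  replace=False)]
            score = evaluate_recovery(self._graph(guess, n=5),
                                      self._truth(true, n=5))
            p, r, f1 = set_recovery(
                {(ids[s], ids[d]) for s, d in guess},
                {(ids[s], ids[d]) for s, d in true})
            assert score.precision == pytest.approx(p)
            assert score.recall == pytest.approx(r)
            assert (score.f1 is None) == (f1 is None)
            if f1 is not None:
                assert score.f1 == pytest.approx(f1)
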