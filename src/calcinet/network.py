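"""Directed functional connectivity from maximum lagged correlation.

For every unordered pair of cells the Pearson correlation of their normalized
traces is evaluated at every integer-frame shift within ``|lag| <= max_lag``
on the overlapping segments.  A pair whose maximum correlation exceeds the
edge threshold (0.3 by default) becomes a directed edge from the leading cell
to the lagging cell; the lag, interpreted as the calcium-wave travel time,
combines with the inter-cell distance into a propagation speed.  Five
culture-level parameters summarize the graph: mean correlation of all pairs,
mean correlation of adjacent (spatially close) pairs, mean connections per
cell, percentage of existing connections out of all ordered pairs, and mean
propagation speed of delays.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .simulate import GroundTruth
from .traces import TraceSet

__all__ = [
    "LaggedCorrelation",
    "PairwiseCorrelations",
    "ConnectivityGraph",
    "NetworkMetrics",
    "RecoveryScore",
    "lagged_correlation",
    "pairwise_lagged_correlations",
    "build_graph",
    "compute_metrics",
    "correlation_vs_distance",
    "evaluate_recovery",
]

logger = logging.getLogger(__name__)

#: Columns of the pairwise correlation table (canonical orientation a < b;
#: positive lag means cell_b follows cell_a).
PAIR_COLUMNS = ["cell_a", "cell_b", "rho", "lag_s", "rho_zero", "distance_um"]


@dataclasses.dataclass(frozen=True)
class LaggedCorrelation:
    """Maximum correlation of a pair and the shift achieving it.

    ``lag`` is in seconds and signed: positive means the second trace follows
    the first.  Ties over shifts are broken toward the smallest ``|lag|``,
    then toward the negative lag.
    """

    rho: float
    lag: float


def _lag_order(max_lag_frames: int) -> list[int]:
    """Signed frame shifts in tie-break priority order: 0, -1, +1, -2, ..."""
    order = [0]
    for k in range(1, max_lag_frames + 1):
        order.extend((-k, k))
    return order


def _shifted_corr(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Pearson correlation of a[t] with b[t + k] on the overlap; NaN if a
    window is constant."""
    if k >= 0:
        x, y = a[:len(a) - k] if k else a, b[k:]
    else:
        x, y = a[-k:], b[:len(b) + k]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return np.nan
    return float((x @ y) / denom)


def lagged_correlation(trace_a: np.ndarray,
                       trace_b: np.ndarray,
                       max_lag: float,
                       sampling_rate: float) -> LaggedCorrelation:
    """Maximum lagged Pearson correlation of two equal-length traces.

    ``max_lag`` is in seconds; shifts are evaluated at every integer frame in
    ``[-max_lag, +max_lag]``.  Raises ``ValueError`` on zero-variance input
    (callers building graphs skip such pairs instead).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and equal length")
    max_lag_frames = int(np.floor(max_lag * sampling_rate))
    if len(a) <= 2 * max_lag_frames:
        raise ValueError("traces must be longer than 2 x max_lag in frames")
    best_rho, best_k = -np.inf, 0
    saw_nan = False
    for k in _lag_order(max_lag_frames):
        rho = _shifted_corr(a, b, k)
        if np.isnan(rho):
            saw_nan = True
            continue
        if rho > best_rho:
            best_rho, best_k = rho, k
    if not np.isfinite(best_rho):
        raise ValueError("zero-variance trace: pair is not correlatable")
    if saw_nan:
        logger.warning("constant overlap window at some lags; those lags "
                       "were skipped")
    return LaggedCorrelation(rho=best_rho, lag=best_k / sampling_rate)


@dataclasses.dataclass
class PairwiseCorrelations:
    """Full pairwise lagged-correlation table of a recording.

    One row per unordered pair in canonical orientation (``cell_a`` before
    ``cell_b`` in the trace-set order); sub-threshold pairs are included.
    Pairs involving a zero-variance trace are dropped and counted in
    ``n_skipped``.
    """

    table: pd.DataFrame
    max_lag: float
    method: str
    n_cells: int
    n_skipped: int = 0


def _rank_transform(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(_sstats.rankdata, 1, x)


def pairwise_lagged_correlations(trace_set: TraceSet,
                                 max_lag: float = 10.0,
                                 method: str = "pearson"
                                 ) -> PairwiseCorrelations:
    """Lagged correlation for every unordered pair of cells, vectorized.

    For each non-negative frame shift ``k`` the full cross-correlation matrix
    between ``x[:, :T-k]`` and ``x[:, k:]`` is computed in one matrix product;
    negative shifts are its transpose.  The per-pair maximum and tie-breaking
    match :func:`lagged_correlation` exactly.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = trace_set.fluorescence
    if method == "spearman":
        x = _rank_transform(x)
    n, t = x.shape
    fs = trace_set.sampling_rate
    max_lag_frames = int(np.floor(max_lag * fs))
    if t <= 2 * max_lag_frames:
        raise ValueError("traces must be longer than 2 x max_lag in frames")

    corr_by_k: dict[int, np.ndarray] = {}
    for k in range(max_lag_frames + 1):
        a = x[:, :t - k] if k else x
        b = x[:, k:] if k else x
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt(np.einsum("ij,ij->i", a, a))
        sb = np.sqrt(np.einsum("ij,ij->i", b, b))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_by_k[k] = (a @ b.T) / np.outer(sa, sb)

    best = np.full((n, n), -np.inf)
    lag_frames = np.zeros((n, n), dtype=int)
    invalid = np.zeros((n, n), dtype=bool)
    for k in _lag_order(max_lag_frames):
        c = corr_by_k[k] if k >= 0 else corr_by_k[-k].T
        invalid |= np.isnan(c)
        update = c > best  # strict: earlier (preferred) lags win ties
        np.copyto(best, c, where=update)
        lag_frames[update] = k
    # A pair is unusable if any evaluated window was constant.
    usable = ~invalid

    rho_zero = corr_by_k[0]
    dist = np.linalg.norm(trace_set.positions[:, None, :]
                          - trace_set.positions[None, :, :], axis=-1)
    rows, skipped = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if not usable[i, j]:
                skipped += 1
                continue
            rows.append({
                "cell_a": trace_set.cell_ids[i],
                "cell_b": trace_set.cell_ids[j],
                "rho": best[i, j],
                "lag_s": lag_frames[i, j] / fs,
                "rho_zero": rho_zero[i, j],
                "distance_um": dist[i, j],
            })
    if skipped:
        logger.warning("%d pairs skipped as non-correlatable "
                       "(zero-variance window)", skipped)
    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return PairwiseCorrelations(table=table, max_lag=max_lag, method=method,
                                n_cells=n, n_skipped=skipped)


@dataclasses.dataclass
class ConnectivityGraph:
    """Directed functional-connectivity graph.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry positions and
    whose edges carry ``rho``, ``lag_s``, ``distance_um`` and — for positive
    lags — ``speed_um_s``.  Supra-threshold pairs whose lag is not significant
    are stored as a reciprocal pair of zero-lag edges without a speed.
    """

    graph: nx.DiGraph
    edge_threshold: float
    max_lag: float

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [{
            "src": u, "dst": v,
            "rho": d["rho"], "lag_s": d["lag_s"],
            "distance_um": d["distance_um"],
            "speed_um_s": d.get("speed_um_s", np.nan),
        } for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(
            rows, columns=["src", "dst", "rho", "lag_s", "distance_um",
                           "speed_um_s"])

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())


def build_graph(trace_set: TraceSet,
                edge_threshold: float = 0.3,
                max_lag: float = 10.0,
                significance_margin: float = 0.05,
                method: str = "pearson",
                pairwise: PairwiseCorrelations | None = None
                ) -> ConnectivityGraph:
    """Infer the directed graph: an edge wherever max lagged rho > threshold.

    Direction points from the leading to the lagging cell.  A lag counts as
    significant only when the maximum rho exceeds the zero-lag rho by at least
    ``significance_margin``; otherwise the pair is treated as synchronous and
    becomes a reciprocal zero-lag edge pair.
    """
    if pairwise is None:
        pairwise = pairwise_lagged_correlations(trace_set, max_lag, method)
    g = nx.DiGraph()
    for i, cell_id in enumerate(trace_set.cell_ids):
        g.add_node(cell_id, x=float(trace_set.positions[i, 0]),
                   y=float(trace_set.positions[i, 1]))
    usable_cells = {c for pair in zip(pairwise.table["cell_a"],
                                      pairwise.table["cell_b"]) for c in pair}
    if len(usable_cells) < 2 and trace_set.n_cells >= 2:
        logger.warning("fewer than 2 correlatable cells; graph is empty")

    for row in pairwise.table.itertuples(index=False):
        if not row.rho > edge_threshold:
            continue
        lag = row.lag_s
        significant = lag != 0.0 and (row.rho - row.rho_zero
                                      >= significance_margin)
        attrs = {"rho": float(row.rho), "distance_um": float(row.distance_um)}
        if significant:
            src, dst = (row.cell_a, row.cell_b) if lag > 0 else \
                       (row.cell_b, row.cell_a)
            abs_lag = abs(lag)
            edge = dict(attrs, lag_s=abs_lag)
            if abs_lag > 0:
                edge["speed_um_s"] = float(row.distance_um) / abs_lag
            g.add_edge(src, dst, **edge)
        else:
            g.add_edge(row.cell_a, row.cell_b, lag_s=0.0, **attrs)
            g.add_edge(row.cell_b, row.cell_a, lag_s=0.0, **attrs)
    return ConnectivityGraph(graph=g, edge_threshold=edge_threshold,
                             max_lag=max_lag)


@dataclasses.dataclass
class NetworkMetrics:
    """The five culture-level network parameters.

    Correlation means over empty sets and the delay rate of a graph without
    positive-lag edges are ``None`` rather than zero.
    """

    mean_corr_all: float | None
    mean_corr_adjacent: float | None
    mean_connections_per_cell: float
    percent_possible_connections: float
    mean_delay_rate: float | None     # um/s
    n_cells: int
    n_edges: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def ordered_fields() -> list[str]:
        return ["mean_corr_all", "mean_corr_adjacent",
                "mean_connections_per_cell", "percent_possible_connections",
                "mean_delay_rate"]


def compute_metrics(graph: ConnectivityGraph,
                    pairwise: PairwiseCorrelations,
                    adjacency_radius: float = 100.0) -> NetworkMetrics:
    """Fold graph + full pairwise table into the five network parameters.

    ``mean_corr_all`` / ``mean_corr_adjacent`` average the maximum lagged rho
    over all (resp. spatially adjacent, distance <= ``adjacency_radius``)
    pairs including sub-threshold ones; connections per cell counts in+out
    degree; the connection percentage is taken against all ordered pairs
    N(N-1); the delay rate averages distance/lag over positive-lag edges.
    """
    table = pairwise.table
    n = graph.n_cells
    e = graph.n_edges
    mean_all = float(table["rho"].mean()) if len(table) else None
    adj = table[table["distance_um"] <= adjacency_radius]
    mean_adj = float(adj["rho"].mean()) if len(adj) else None
    speeds = [d["speed_um_s"] for _, _, d in graph.graph.edges(data=True)
              if "speed_um_s" in d]
    return NetworkMetrics(
        mean_corr_all=mean_all,
        mean_corr_adjacent=mean_adj,
        mean_connections_per_cell=(2.0 * e / n) if n else 0.0,
        percent_possible_connections=(100.0 * e / (n * (n - 1))) if n > 1 else 0.0,
        mean_delay_rate=float(np.mean(speeds)) if speeds else None,
        n_cells=n,
        n_edges=e,
    )


def correlation_vs_distance(pairwise: PairwiseCorrelations,
                            bin_width: float = 50.0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair correlation against distance, plus a binned median summary.

    Returns ``(points, binned)``: one point per unordered pair (colocated
    pairs at distance 0 are retained), and the median rho per ``bin_width``-um
    distance bin over occupied bins.
    """
    points = pairwise.table[["cell_a", "cell_b", "distance_um", "rho"]].copy()
    if len(points):
        bins = np.floor(points["distance_um"] / bin_width).astype(int)
        binned = (points.assign(bin=bins)
                  .groupby("bin")["rho"].median().reset_index())
        binned["bin_left_um"] = binned.pop("bin") * bin_width
        binned = binned.rename(columns={"rho": "median_rho"})
        binned = binned[["bin_left_um", "median_rho"]]
    else:
        binned = pd.DataFrame(columns=["bin_left_um", "median_rho"])
    return points, binned


@dataclasses.dataclass
class RecoveryScore:
    """Edge-set recovery of an inferred graph against the planted truth.

    ``precision`` is ``None`` when nothing was inferred; ``delay_error`` is
    the mean absolute difference between inferred lag and true delay over
    true-positive positive-lag edges (``None`` when there are none).
    """

    precision: float | None
    recall: float | None
    f1: float | None
    delay_error: float | None
    n_true: int
    n_inferred: int
    n_correct: int


def evaluate_recovery(inferred: ConnectivityGraph,
                      truth: GroundTruth,
                      cell_ids: list[str] | None = None) -> RecoveryScore:
    """Score inferred directed edges against the ground-truth coupling graph.

    ``cell_ids`` maps ground-truth integer cell indices to graph node labels;
    defaults to the simulator's own labelling.  Raises ``ValueError`` when the
    graphs refer to different cell sets.
    """
    if cell_ids is None:
        cell_ids = TraceSet.default_ids(truth.n_cells)
    if set(cell_ids) != set(inferred.graph.nodes):
        raise ValueError("inferred graph and ground truth refer to "
                         "different cell sets")
    true_edges = {(cell_ids[s], cell_ids[d]) for s, d in truth.edge_set()}
    inferred_edges = inferred.edge_set()
    correct = true_edges & inferred_edges

    precision = len(correct) / len(inferred_edges) if inferred_edges else None
    recall = len(correct) / len(true_edges) if true_edges else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None

    true_delay = {(cell_ids[int(r.src)], cell_ids[int(r.dst)]): float(r.delay_s)
                  for r in truth.edges.itertuples(index=False)}
    errors = []
    for u, v in correct:
        data = inferred.graph.edges[u, v]
        if data["lag_s"] > 0:
            errors.append(abs(data["lag_s"] - true_delay[(u, v)]))
    delay_error = float(np.mean(errors)) if errors else None
    return RecoveryScore(
        precision=precision, recall=recall, f1=f1, delay_error=delay_error,
        n_true=len(true_edges), n_inferred=len(inferred_edges),
        n_correct=len(correct),
    )
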