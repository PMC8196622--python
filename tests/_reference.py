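"""Naive reference implementations used as independent oracles.

Everything here is deliberately brute-force and shares no code with the
package: plain double loops over lags using ``np.corrcoef``, explicit set
arithmetic for recovery scores, and exhaustive rank enumeration for the
Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_lagged_correlation(a: np.ndarray, b: np.ndarray,
                             max_lag_frames: int,
                             sampling_rate: float) -> tuple[float, float]:
    """Max Pearson correlation over integer-frame shifts, brute force.

    Ties break toward the smallest |lag|, then the negative lag, by scanning
    candidates in that priority order and only replacing on a strict
    improvement.
    """
    order = [0]
    for k in range(1, max_lag_frames + 1):
        order.extend((-k, k))
    best_rho, best_k = -np.inf, 0
    for k in order:
        if k >= 0:
            x, y = a[:len(a) - k] if k else a, b[k:]
        else:
            x, y = a[-k:], b[:len(b) + k]
        rho = np.corrcoef(x, y)[0, 1]
        if np.isnan(rho):
            continue
        if rho > best_rho:
            best_rho, best_k = rho, k
    return best_rho, best_k / sampling_rate


def naive_graph_edges(traces: np.ndarray, cell_ids: list[str],
                      sampling_rate: float, max_lag_frames: int,
                      threshold: float = 0.3,
                      margin: float = 0.05) -> set[tuple[str, str]]:
    """Directed edge set by the same rules, derived independently."""
    n = traces.shape[0]
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            rho, lag = naive_lagged_correlation(
                traces[i], traces[j], max_lag_frames, sampling_rate)
            rho0 = np.corrcoef(traces[i], traces[j])[0, 1]
            if not rho > threshold:
                continue
            if lag != 0 and rho - rho0 >= margin:
                if lag > 0:
                    edges.add((cell_ids[i], cell_ids[j]))
                else:
                    edges.add((cell_ids[j], cell_ids[i]))
            else:
                edges.add((cell_ids[i], cell_ids[j]))
                edges.add((cell_ids[j], cell_ids[i]))
    return edges


def set_recovery(inferred: set, truth: set) -> tuple[float | None,
                                                     float | None,
                                                     float | None]:
    """Precision/recall/F1 by explicit set arithmetic."""
    tp = len(inferred & truth)
    precision = tp / len(inferred) if inferred else None
    recall = tp / len(truth) if truth else None
    if precision is None or recall is None or precision + recall == 0:
        return precision, recall, None
    return precision, recall, 2 * precision * recall / (precision + recall)


def exact_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by full rank enumeration.

    Enumerates every assignment of the pooled ranks to the first group and
    counts U statistics at least as extreme as the observed one.
    """
    pooled = sorted(x + y)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # assumes no ties
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            extreme += 1
        total += 1
    assert total == math.comb(n1 + n2, n1)
    return extreme / total
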