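"""End-to-end run orchestration: simulate -> detect -> network -> metrics.

A run directory is a self-describing artifact: every exported table, the
scenario that produced it, and a manifest with the configuration hash, the
seed and a SHA-256 per output file.  Outputs contain no timestamps, so the
same configuration and seed reproduce every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as cio
from .activity import compute_dff, detect_all, summarize_activity
from .network import (build_graph, compute_metrics, correlation_vs_distance,
                      evaluate_recovery, pairwise_lagged_correlations)
from .scenario import SyntheticScenario
from .simulate import simulate_recording

__all__ = ["run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineResult(dict):
    """Dict of in-memory stage results plus the run directory path."""


def run_pipeline(scenario: SyntheticScenario,
                 out_dir: str | Path,
                 edge_threshold: float = 0.3,
                 max_lag: float = 10.0,
                 adjacency_radius: float = 100.0,
                 score_recovery: bool = True) -> PipelineResult:
    """Simulate one recording and run the full analysis, exporting all stages.

    Writes, under ``out_dir``: the scenario, the trace table + sidecar, the
    ground-truth edge list, the event table and activity summary, the
    pairwise-correlation and distance-correlation tables, the connectivity
    graph (GraphML + edge CSV), the five network metrics, the recovery score
    against the planted graph, and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("simulate: %d cells, %.0f s @ %.1f Hz",
                scenario.n_cells, scenario.duration, scenario.sampling_rate)
    trace_set, truth = simulate_recording(scenario)
    scenario.to_file(out / "scenario.json")
    cio.write_trace_table(trace_set, out / "traces.csv")
    truth.edges.assign(
        src=[trace_set.cell_ids[i] for i in truth.edges["src"]],
        dst=[trace_set.cell_ids[i] for i in truth.edges["dst"]],
    ).to_csv(out / "truth_edges.csv", index=False)

    logger.info("activity: normalizing and detecting oscillations")
    dff = compute_dff(trace_set)
    events = detect_all(dff)
    events.to_csv(out / "events.csv", index=False)
    summary = summarize_activity(events, trace_set)
    summary.per_cell.to_csv(out / "activity_per_cell.csv", index=False)
    (out / "activity_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")

    logger.info("network: pairwise lagged correlations and graph")
    pairwise = pairwise_lagged_correlations(dff, max_lag=max_lag)
    pairwise.table.to_csv(out / "pairwise_correlations.csv", index=False)
    graph = build_graph(dff, edge_threshold=edge_threshold, max_lag=max_lag,
                        pairwise=pairwise)
    cio.write_graphml(graph, out / "graph.graphml")
    cio.write_edge_table(graph, out / "edges.csv")
    metrics = compute_metrics(graph, pairwise, adjacency_radius)
    cio.write_metrics(metrics, out / "metrics.json", out / "metrics.csv")
    points, binned = correlation_vs_distance(pairwise)
    points.to_csv(out / "distance_correlation.csv", index=False)
    binned.to_csv(out / "distance_correlation_binned.csv", index=False)

    result = PipelineResult(
        out_dir=out, trace_set=trace_set, truth=truth, dff=dff,
        events=events, activity=summary, pairwise=pairwise, graph=graph,
        metrics=metrics,
    )
    if score_recovery and len(truth.edges):
        recovery = evaluate_recovery(graph, truth, trace_set.cell_ids)
        (out / "recovery.json").write_text(json.dumps({
            "precision": recovery.precision, "recall": recovery.recall,
            "f1": recovery.f1, "delay_error_s": recovery.delay_error,
            "n_true": recovery.n_true, "n_inferred": recovery.n_inferred,
            "n_correct": recovery.n_correct,
        }, indent=2, sort_keys=True) + "\n")
        result["recovery"] = recovery

    config_json = json.dumps(scenario.to_dict(), sort_keys=True)
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": scenario.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": scenario.seed,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %d edges, %d events, outputs in %s",
                metrics.n_edges, len(events), out)
    return result


def compare_runs(metric_files: dict[str, list[Path]],
                 fields: list[str] | None = None) -> pd.DataFrame:
    """Tabulate per-group metric values from exported ``metrics.json`` files."""
    from .network import NetworkMetrics
    if fields is None:
        fields = NetworkMetrics.ordered_fields()
    rows: list[dict[str, Any]] = []
    for group, paths in metric_files.items():
        for path in paths:
            data = json.loads(Path(path).read_text())
            row = {"group": group, "path": str(path)}
            row.update({f: data.get(f) for f in fields})
            rows.append(row)
    return pd.DataFrame(rows)
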