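#!/usr/bin/env python
"""The five network parameters under sham and hypoxia conditions.

Runs the full inference on ten paired seeds per condition, tabulates the five
culture-level network parameters plus the percentage of active cells, and
compares conditions with two-sided Mann-Whitney tests.  Writes
results/network_metrics_by_condition.csv and
results/condition_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from calcinet import (SyntheticScenario, build_graph, compare_groups,
                      compute_dff, compute_metrics, detect_all,
                      format_median_iqr, pairwise_lagged_correlations,
                      simulate_recording, summarize_activity)
from calcinet.network import NetworkMetrics

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(10)
FIELDS = NetworkMetrics.ordered_fields() + ["percent_active"]


def main() -> None:
    rows = []
    for condition in ("sham", "hypoxia"):
        for seed in SEEDS:
            scenario = SyntheticScenario(seed=seed).with_condition(condition)
            trace_set, _ = simulate_recording(scenario)
            dff = compute_dff(trace_set)
            pairwise = pairwise_lagged_correlations(dff)
            graph = build_graph(dff, pairwise=pairwise)
            metrics = compute_metrics(graph, pairwise)
            summary = summarize_activity(detect_all(dff), trace_set)
            row = {"condition": condition, "seed": seed,
                   "percent_active": summary.percent_active}
            row.update({f: getattr(metrics, f)
                        for f in NetworkMetrics.ordered_fields()})
            rows.append(row)
    table = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "network_metrics_by_condition.csv", index=False)

    comparisons = []
    for metric in FIELDS:
        groups = {}
        for condition in ("sham", "hypoxia"):
            values = table.loc[table.condition == condition, metric].dropna()
            groups[condition] = values.tolist()
        if min(len(v) for v in groups.values()) < 3:
            print(f"{metric}: too few defined values for a test")
            continue
        result = compare_groups(groups, test="mannwhitney", metric=metric)
        comparisons.append({
            "metric": metric,
            "sham_median_iqr": format_median_iqr(groups["sham"]),
            "hypoxia_median_iqr": format_median_iqr(groups["hypoxia"]),
            "mannwhitney_p": result.p_value,
        })
        print(f"{metric:32s} sham {comparisons[-1]['sham_median_iqr']:>22s}  "
              f"hypoxia {comparisons[-1]['hypoxia_median_iqr']:>22s}  "
              f"p={result.p_value:.4g}")
    pd.DataFrame(comparisons).to_csv(RESULTS / "condition_comparison.csv",
                                     index=False)
    print(f"wrote {RESULTS / 'condition_comparison.csv'}")


if __name__ == "__main__":
    main()
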