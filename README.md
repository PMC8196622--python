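# calcinet

Calcium-imaging analysis for neuron–glial cultures: oscillation detection and
activity statistics, directed functional-connectivity inference from maximum
lagged correlation, and the five culture-level network parameters — together
with a synthetic calcium-dynamics simulator that provides ground truth for
validating the whole pipeline.

## Who this is for

Groups recording spontaneous Ca²⁺ activity in dissociated neuronal cultures
with a calcium-sensitive dye (e.g. OGB-1 at 2 Hz over a 420 × 420 µm field)
who want a tested, scriptable implementation of the standard analysis chain:
ΔF/F normalization → oscillation detection → per-culture activity statistics
→ pairwise lagged correlation → directed network graph → network parameters →
group comparison. Because public recordings for this preparation are scarce,
the package ships a generative model of such recordings whose planted
connectivity serves as ground truth.

## The model and the statistics

**Activity.** Each trace is normalized as ΔF/F = (F − F₀)/F₀ with F₀ a
rolling 10th-percentile baseline. Oscillations are detected by hysteresis: an
event opens when ΔF/F reaches an onset threshold and closes when it falls
below an offset threshold. Per culture the pipeline reports the percentage of
cells exhibiting Ca²⁺ activity, the mean oscillation duration (s), and the
mean frequency (osc/min), with means conditioned on active cells.

**Connectivity.** For every cell pair, the Pearson correlation of the ΔF/F
traces is evaluated at every integer-frame shift within ±max_lag (default
10 s) on the overlapping segments. The pair's correlation ρ is the maximum
over shifts; a directed edge is drawn from the leading to the lagging cell
whenever ρ > 0.3. The lag is read as the Ca²⁺ wave travel time, so each
positive-lag edge carries a propagation speed = distance/lag (µm/s).
Synchronous supra-threshold pairs (no significant lag) become reciprocal
zero-lag edges. Five parameters summarize the network: mean ρ over all pairs,
mean ρ over adjacent pairs (≤ 100 µm), mean connections per cell
(in+out degree), percentage of existing connections out of all N(N−1) ordered
pairs, and mean propagation speed of delays.

**Simulator.** Cells are scattered uniformly over the field; ordered pairs
within 200 µm are coupled with a fixed probability into a directed graph with
per-edge delays = distance/speed + jitter. Non-silenced cells fire Poisson
spontaneous events; events propagate along edges with a transmission
probability under a per-cell refractory period, are convolved with a
difference-of-exponentials transient kernel, and are read out with Gaussian
imaging noise. Condition presets scale the generative parameters: `sham` is
neutral; `hypoxia` halves the event rate and transmission, silences 30 % more
cells and slows propagation to ~2/3 — degrading every downstream statistic in
the direction observed in post-hypoxic cultures.

## Worked example

```python
from calcinet import (SyntheticScenario, simulate_recording, compute_dff,
                      detect_all, summarize_activity,
                      pairwise_lagged_correlations, build_graph,
                      compute_metrics, evaluate_recovery)

scenario = SyntheticScenario(n_cells=30, duration=600.0,
                             transmit_probability=0.9, noise_sd=0.05, seed=0)
traces, truth = simulate_recording(scenario)

dff = compute_dff(traces)
summary = summarize_activity(detect_all(dff), traces)
pairwise = pairwise_lagged_correlations(dff)
graph = build_graph(dff, edge_threshold=0.3, pairwise=pairwise)
metrics = compute_metrics(graph, pairwise)
score = evaluate_recovery(graph, truth, traces.cell_ids)

print(f"{summary.percent_active:.0f}% active, "
      f"{summary.mean_frequency:.2f} osc/min, "
      f"{summary.mean_duration:.1f} s mean duration")
print(f"{graph.n_edges} edges, mean speed {metrics.mean_delay_rate:.1f} um/s")
print(f"recovery: F1={score.f1:.2f}, delay error {score.delay_error:.2f} s")
```

Output:

```
100% active, 1.07 osc/min, 5.5 s mean duration
9 edges, mean speed 20.6 um/s
recovery: F1=1.00, delay error 0.13 s
```

All 30 cells are active (nothing is silenced under sham), oscillate about
once per minute for ~5 s each; the 9 planted couplings are recovered
exactly, with lags accurate to about a quarter of a frame, and the mean
propagation speed estimate sits near the generative 20 µm/s.

The same chain is scripted in `analysis/01…05` (simulation, activity
statistics, planted-network recovery, sham-vs-hypoxia comparison with
Mann–Whitney tests, correlation-versus-distance), each writing its tables
under `results/`. A `calcinet` command-line tool exposes the stages
(`simulate`, `activity`, `network`, `metrics`, `distance`, `compare`, `run`).

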