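# Methods

This note documents the models, parameters and numerical choices behind
`calcinet`: what the synthetic recordings emulate, how oscillations and
connectivity are inferred, which knobs matter, and what the validation suite
does and does not establish about real data.

## 1. The generative model

A recording is parameterized by a `SyntheticScenario`. The default scenario
emulates a confocal recording of a dissociated cortical culture loaded with a
calcium-sensitive dye: a 420 × 420 µm field of view imaged at 2 Hz
(512 × 512 px when rendered as a movie), with tens of cells and spontaneous
calcium oscillations at around one event per minute per cell.

**Spatial substrate.** `n_cells` (default 30) positions are drawn uniformly
over the square field. Uniformity is deliberate: the analysis makes no use of
spatial clustering, and a homogeneous Poisson scatter has a known
nearest-neighbour law (E[d] = 0.5·√(area/n)) used as a test oracle.

**Coupling graph.** Every ordered pair within `connectivity_radius` (200 µm —
large enough to allow both short- and long-range connections within the
field) is an edge with probability `coupling_probability` (default 0.025).
Each edge carries a fixed true delay = distance / propagation speed plus
truncated Gaussian jitter (SD 0.25 s). The default propagation speed of
20 µm/s puts edge delays in the 0.5–10 s range, i.e. resolvable at 2 Hz
within the lag search window.

The default graph is deliberately *sparse* (mean degree below one). This is
an identifiability requirement, not a claim about cultures: threshold-based
correlation inference cannot distinguish a direct coupling from a two-hop
path or a shared upstream driver, since with high transmission probability
every cell of a connected component inherits most of its component's events.
Recovering a planted graph from pairwise correlations is therefore only a
well-posed exercise when components are small. Real cultures are far denser
and more synchronous; see §5.

**Events.** Each non-silenced cell fires spontaneous events as a homogeneous
Poisson process at `base_event_rate` (default 1.0 events/min). Every accepted
event propagates along each outgoing edge with probability
`transmit_probability` (default 0.5), arriving after the edge's delay;
propagation is transitive, and cascades stay bounded because a cell rejects
any event within `refractory` (2 s) of its previous one. Silenced cells
neither fire nor relay.

**Fluorescence.** Event onsets are convolved with a difference-of-
exponentials kernel K(t) ∝ (1 − e^(−t/τ_rise))·e^(−t/τ_decay), peak-
normalized and scaled to `amplitude` (1.0 ΔF/F), with τ_rise = 0.5 s and
τ_decay = 2.0 s. These time constants put detected oscillation durations near
5.5 s, inside the 5–15 s range typical of such recordings, while keeping the
kernel autocorrelation short — a long-tailed kernel inflates the null
distribution of maximum lagged correlation between *independent* cells and
floods sparse graphs with spurious supra-threshold pairs. Traces are
F = F₀·(1 + ΣK) with additive Gaussian noise of SD `noise_sd`·F₀ (default
5 %); an optional linear photobleaching drift exists and is off by default.
The default `duration` of 1200 s serves the same purpose as the short kernel:
the sampling error of a correlation estimate scales as the square root of the
kernel correlation time over the recording length, and at 1200 s the null
rate of ρ > 0.3 pairs is numerically zero at this problem size.

**Conditions.** A `ConditionScaling` multiplies the base parameterization.
`sham` is neutral. `hypoxia` applies (rate ×0.5, transmit ×0.5, silenced
fraction +0.3, propagation speed ×0.66). The first three factors degrade
activity and connectivity; the speed factor models the slowed calcium-wave
propagation seen in post-hypoxic cultures and is what gives the fifth network
parameter (mean delay rate) its downward direction — without it that metric
has no reason to move. The preset aims at the *direction* of post-hypoxic
network collapse, not its magnitude.

**Seeding.** One master seed is expanded through `numpy.random.SeedSequence`
into fixed per-stage substreams (positions, graph, events, noise, movie), so
any stage can be re-run independently and the full pipeline is a pure
function of (scenario, seed).

## 2. Activity analysis

**Baseline.** F₀ is the centred rolling 10th percentile over a 60 s window,
clamped from below at the cell's global 5th percentile so oscillation-dense
stretches cannot drag the baseline into the transients. Cells whose baseline
is not strictly positive are rejected by name rather than normalized into
nonsense.

**Detection.** Hysteresis thresholding on ΔF/F: an event opens at the onset
threshold and closes below the offset threshold; events shorter than 1 s
(2 frames at 2 Hz) are discarded as single-frame noise. Automatic thresholds
are 4σ (onset) and 2σ (offset), where σ is a robust noise SD from the
differentiated trace (MAD × 1.4826/√2), floored at 0.1/0.05 ΔF/F, and both
are measured *above the trace's median ΔF/F*: a percentile baseline sits
below the noise mean, so a silent cell's ΔF/F is centred slightly above zero
and absolute thresholds would count its noise as activity. Thresholds are
exposed as configuration; event counts are non-increasing in the onset
threshold by construction (the property suite fuzzes this).

**Statistics.** A cell is active iff it has ≥ 1 detected event. Frequency is
events per minute of recording; duration is offset − onset. Culture-level
duration and frequency average over active cells only — reporting them
alongside "% active" implies conditioning on activity — and are reported as
absent (not zero) when no cell is active.

Consecutive events closer than the kernel's decay-to-offset time (~7 s at
default settings) merge into one detected oscillation; validation against
simulated ground truth applies the same merge to the true event lists.

## 3. Connectivity analysis

**Lagged correlation.** For a pair of equal-length ΔF/F traces, Pearson
correlation is computed at every integer-frame shift in [−max_lag, +max_lag]
(default 10 s — ample for propagation across a 420 µm field at plausible wave
speeds) on the overlapping segments, each re-standardized per shift. The
result is the maximum ρ and its lag; exact ties break toward the smallest
|lag|, then toward the negative lag. The pairwise implementation evaluates
one cross-correlation matrix per shift (a single matrix product) and matches
the naive per-pair double loop to 10⁻¹⁰; Spearman is available by rank-
transforming traces first. Pairs containing a zero-variance window are
skipped and logged, never fatal.

**Graph.** An edge is drawn for every pair with ρ > 0.3 (a fixed rule, not a
hypothesis test; no multiple-testing correction). A lag counts as significant
only when the maximum ρ exceeds the zero-lag ρ by ≥ 0.05; significant-lag
pairs become one directed edge from leader to lagger carrying
speed = distance/lag, while synchronous pairs become a reciprocal zero-lag
edge pair with no speed (delay-direction is undefined at lag 0).

**The five parameters.** Mean ρ over all pairs (sub-threshold included); mean
ρ over adjacent pairs — adjacency is spatial, distance ≤ 100 µm, exposed as
configuration since "adjacent" is otherwise conventional; mean connections
per cell (in+out degree, i.e. 2E/N); percentage of existing connections out
of N(N−1) ordered pairs, consistent with an oriented graph; and the mean of
edge speeds over positive-lag edges, in µm/s. Means over empty sets are
reported as absent, not zero. In condition comparisons the delay rate can be
undefined for runs whose graph has no positive-lag edge; medians are then
taken over the runs where it is defined.

The µm/s delay-rate definition is this package's own; printed "signal delay
rate" magnitudes in the literature on this preparation are unit-ambiguous,
so no numeric comparability is claimed (the generative default of 20 µm/s
does land in the same 12–25 numeric range).

**Recovery scoring.** Inferred edges are scored against the planted graph as
ordered pairs (precision, recall, F1), with mean absolute delay error over
true-positive positive-lag edges. Precision of an empty inference and recall
of an empty truth are undefined, not zero.

## 4. Group comparison

Two groups are compared with the two-sided Mann–Whitney U test; more than two
with one-way ANOVA and Tukey's post hoc test (both usages are conventional in
this field, and both are exposed). Summaries are printed as median (Q1; Q3)
with linear-interpolation quartiles. α = 0.05, no correction across metrics.
The n=3 vs n=3 exact case is validated against full rank enumeration
(minimal two-sided p = 2/20 = 0.1).

## 5. What the validation does and does not show

The test suite establishes: exact agreement of the correlation/graph engine
with brute-force references; recovery of a planted sparse network (mean edge
F1 ≈ 0.83, mean delay error ≈ 0.12 s over ten seeds at 30 cells, 600 s,
transmission 0.9, 5 % noise); the qualitative degradation of all five network
parameters and of % active cells under the hypoxia preset; exact behaviour on
analytic fixtures; lossless round-trips; and bit-level determinism.

It does not establish performance on real recordings. The simulator omits
network-wide synchronized bursting (the dominant feature of mature cultures,
which produces the dense, highly correlated graphs seen in vitro), cell-type
heterogeneity, fluorophore photophysics beyond optional linear bleaching,
motion and segmentation errors, and any biophysical calcium dynamics
(buffering, IP₃, channel kinetics). Consequently the absolute magnitudes of
the five network parameters on synthetic data — in particular connection
counts and densities, which are orders of magnitude below those of dense real
networks — are not comparable to published culture values; the package's
claims on real-like regimes are directional, not quantitative.

## 6. Numerical and interface conventions

Problem sizes in the validation suite (30-cell/10–20-minute recordings, ten
seeds per condition) were chosen as the smallest instances at which the
statistical properties above are stable. Coordinates are µm with the origin
at the field's top-left, x rightward, y downward; the µm↔pixel scale is
field/512 for movies. Trace tables are CSV (cell_id + one column per frame)
with a JSON sidecar carrying sampling rate and positions; floats round-trip
bit-exactly. Tables with missing values are rejected naming the cell and
frame — correlation and lag estimation are not robust to silent imputation.
TIFF ingestion is limited to single-channel grayscale stacks. ROI extraction
averages pixels whose centres fall inside each circular ROI. Graphs export to
GraphML and edge-list CSV; the undefined speed of zero-lag edges is omitted
from GraphML and empty in CSV. Run directories contain no timestamps, so
identical configuration and seed reproduce every byte.
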