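"""Ground-truth-annotated synthetic calcium recordings.

The generative model: cells are scattered uniformly over the field of view;
ordered near pairs are coupled into a directed graph with per-edge propagation
delays proportional to distance; each non-silenced cell fires spontaneous
calcium events as a homogeneous Poisson process and every event propagates
along outgoing edges with a fixed transmission probability, subject to a
per-cell refractory period that bounds cascades.  Event times are convolved
with a difference-of-exponentials transient kernel, scaled onto a fluorescence
baseline and corrupted with Gaussian imaging noise.  Optionally the recording
is rendered as a 512 x 512 image stack of Gaussian somata for testing ROI
extraction.
"""

from __future__ import annotations

import dataclasses
import heapq

import numpy as np
import pandas as pd

from .scenario import ScenarioError, SyntheticScenario
from .traces import TraceSet

__all__ = [
    "GroundTruth",
    "generate_positions",
    "generate_ground_truth_graph",
    "simulate_events",
    "render_traces",
    "render_movie",
    "simulate_recording",
    "transient_kernel",
]

#: Columns of the ground-truth edge table.
EDGE_COLUMNS = ["src", "dst", "delay_s", "distance_um"]


@dataclasses.dataclass
class GroundTruth:
    """Everything the analysis is later asked to recover.

    ``edges`` holds one row per directed coupling (integer cell indices) with
    its true propagation delay; ``event_times`` the realized calcium event
    onsets per cell, in seconds; ``silenced`` marks cells that neither fire
    nor relay.
    """

    positions: np.ndarray                  # (n, 2) um
    edges: pd.DataFrame                    # EDGE_COLUMNS
    event_times: list[np.ndarray] | None = None
    silenced: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.edges["src"].astype(int),
                       self.edges["dst"].astype(int)))


def generate_positions(scenario: SyntheticScenario,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Scatter ``n_cells`` uniformly over the square field of view (um)."""
    if rng is None:
        rng = scenario.streams()["positions"]
    return rng.uniform(0.0, scenario.field_size, size=(scenario.n_cells, 2))


def generate_ground_truth_graph(positions: np.ndarray,
                                scenario: SyntheticScenario,
                                rng: np.random.Generator | None = None,
                                ) -> pd.DataFrame:
    """Draw the directed coupling graph over candidate near pairs.

    Every ordered pair within ``connectivity_radius`` becomes an edge with
    probability ``coupling_probability``; the edge's true delay is
    distance / effective propagation speed plus truncated Gaussian jitter.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ScenarioError("need at least 2 cells to build a coupling graph")
    if rng is None:
        rng = scenario.streams()["graph"]
    speed = scenario.effective_propagation_speed
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    rows: list[tuple[int, int, float, float]] = []
    # Deterministic pair order so the draw sequence is reproducible.
    for i in range(n):
        for j in range(n):
            if i == j or dist[i, j] > scenario.connectivity_radius:
                continue
            if rng.random() >= scenario.coupling_probability:
                continue
            jitter = rng.normal(0.0, scenario.delay_jitter_sd) \
                if scenario.delay_jitter_sd > 0 else 0.0
            delay = max(0.0, dist[i, j] / speed + jitter)
            rows.append((i, j, delay, dist[i, j]))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS).astype(
        {"src": int, "dst": int})


def simulate_events(truth: GroundTruth,
                    scenario: SyntheticScenario,
                    rng: np.random.Generator | None = None,
                    spontaneous: list[np.ndarray] | None = None,
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Realize spontaneous firing and propagation on the coupling graph.

    Returns ``(event_times, silenced)`` and stores both on ``truth``.
    ``spontaneous`` may inject pre-drawn per-cell spontaneous onsets (used by
    tests that need a deterministic drive); silencing is then still applied.

    Propagation is transitive: a relayed event is itself relayed.  Cascades
    stay bounded because each cell refuses events closer than ``refractory``
    seconds to its previous accepted event.
    """
    n = truth.n_cells
    if rng is None:
        rng = scenario.streams()["events"]
    rate_hz = scenario.effective_event_rate / 60.0
    silenced = rng.random(n) < scenario.effective_silenced_fraction
    transmit = scenario.effective_transmit_probability

    if spontaneous is None:
        spontaneous = []
        for _ in range(n):
            k = rng.poisson(rate_hz * scenario.duration)
            spontaneous.append(np.sort(rng.uniform(0.0, scenario.duration, k)))
    else:
        spontaneous = [np.sort(np.asarray(t, dtype=float)) for t in spontaneous]
        if len(spontaneous) != n:
            raise ScenarioError("spontaneous event lists do not match n_cells")

    out_edges: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for row in truth.edges.itertuples(index=False):
        out_edges[int(row.src)].append((int(row.dst), float(row.delay_s)))
    for edges in out_edges:
        edges.sort()  # fixed relay order => reproducible RNG consumption

    heap: list[tuple[float, int, int]] = []
    counter = 0
    for cell, times in enumerate(spontaneous):
        if silenced[cell]:
            continue
        for t in times:
            heapq.heappush(heap, (float(t), cell, counter))
            counter += 1

    accepted: list[list[float]] = [[] for _ in range(n)]
    last: list[float] = [-np.inf] * n
    while heap:
        t, cell, _ = heapq.heappop(heap)
        if t >= scenario.duration or silenced[cell]:
            continue
        if t - last[cell] < scenario.refractory:
            continue
        last[cell] = t
        accepted[cell].append(t)
        for dst, delay in out_edges[cell]:
            if transmit >= 1.0 or rng.random() < transmit:
                heapq.heappush(heap, (t + delay, dst, counter))
                counter += 1

    event_times = [np.asarray(times, dtype=float) for times in accepted]
    truth.event_times = event_times
    truth.silenced = silenced
    return event_times, silenced


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float,
                     amplitude: float = 1.0) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalized.

    ``K(t) = (1 - exp(-t/rise)) * exp(-t/decay)`` for t >= 0, scaled so its
    maximum equals ``amplitude``.  The peak sits at
    ``t* = rise * ln(1 + decay/rise)``.
    """
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0,
                   (1.0 - np.exp(-np.maximum(t, 0.0) / rise_tau))
                   * np.exp(-np.maximum(t, 0.0) / decay_tau),
                   0.0)
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return amplitude * raw / peak


def render_traces(event_times: list[np.ndarray],
                  scenario: SyntheticScenario,
                  positions: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> TraceSet:
    """Turn event onsets into noisy fluorescence traces.

    ``F(t) = F0 * (1 - bleach*t) * (1 + sum_events K(t - t_e)) + noise`` with
    ``K`` the peak-normalized transient kernel scaled to the scenario
    amplitude and Gaussian noise of SD ``noise_sd * F0``.
    """
    n_frames = scenario.n_frames
    if n_frames < 2:
        raise ScenarioError("duration x sampling_rate must give >= 2 frames")
    n = len(event_times)
    if rng is None:
        rng = scenario.streams()["noise"]
    if positions is None:
        positions = np.zeros((n, 2))

    times = np.arange(n_frames) / scenario.sampling_rate
    # Kernel support: decay to < 1e-6 of peak.
    support = scenario.decay_tau * 14.0
    support_frames = int(np.ceil(support * scenario.sampling_rate))
    kernel_t = np.arange(support_frames + 1) / scenario.sampling_rate
    dff = np.zeros((n, n_frames))
    for cell, onsets in enumerate(event_times):
        for t0 in np.asarray(onsets, dtype=float):
            start = int(np.ceil((t0 - 1e-12) * scenario.sampling_rate))
            start = max(start, 0)
            if start >= n_frames:
                continue
            stop = min(start + support_frames + 1, n_frames)
            local_t = times[start:stop] - t0
            dff[cell, start:stop] += transient_kernel(
                local_t, scenario.rise_tau, scenario.decay_tau,
                scenario.amplitude)

    baseline = scenario.baseline_f0 * np.maximum(
        1.0 - scenario.bleach_rate * times, 0.0)
    fluor = baseline[None, :] * (1.0 + dff)
    if scenario.noise_sd > 0:
        fluor = fluor + rng.normal(
            0.0, scenario.noise_sd * scenario.baseline_f0, size=fluor.shape)
    return TraceSet(
        fluorescence=fluor,
        sampling_rate=scenario.sampling_rate,
        positions=np.asarray(positions, dtype=float),
        cell_ids=TraceSet.default_ids(n),
    )


def render_movie(trace_set: TraceSet,
                 scenario: SyntheticScenario,
                 blob_sigma_um: float = 3.0,
                 pixel_noise_sd: float = 0.0,
                 image_size: int = 512,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render traces as a grayscale image stack of Gaussian somata.

    Each cell contributes a unit-peak Gaussian blob at its position scaled by
    its instantaneous fluorescence; overlapping blobs sum.  Returns a
    ``(n_frames, image_size, image_size)`` float32 stack.
    """
    if rng is None:
        rng = scenario.streams()["movie"]
    scale = scenario.field_size / image_size  # um per pixel
    sigma_px = blob_sigma_um / scale
    half = max(int(np.ceil(4 * sigma_px)), 1)

    stack = np.zeros((trace_set.n_frames, image_size, image_size),
                     dtype=np.float32)
    for cell in range(trace_set.n_cells):
        x_um, y_um = trace_set.positions[cell]
        col = x_um / scale - 0.5
        row = y_um / scale - 0.5
        r0 = max(int(np.floor(row)) - half, 0)
        r1 = min(int(np.ceil(row)) + half + 1, image_size)
        c0 = max(int(np.floor(col)) - half, 0)
        c1 = min(int(np.ceil(col)) + half + 1, image_size)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
        blob = np.exp(-((rr - row) ** 2 + (cc - col) ** 2)
                      / (2.0 * sigma_px ** 2)).astype(np.float32)
        trace = trace_set.fluorescence[cell].astype(np.float32)
        stack[:, r0:r1, c0:c1] += trace[:, None, None] * blob[None, :, :]
    if pixel_noise_sd > 0:
        stack += rng.normal(0.0, pixel_noise_sd, size=stack.shape
                            ).astype(np.float32)
    return stack


def simulate_recording(scenario: SyntheticScenario
                       ) -> tuple[TraceSet, GroundTruth]:
    """Run the full generative pipeline for one scenario.

    Convenience wrapper chaining positions -> coupling graph -> events ->
    traces with the scenario's per-stage random substreams.
    """
    streams = scenario.streams()
    positions = generate_positions(scenario, streams["positions"])
    if scenario.n_cells >= 2:
        edges = generate_ground_truth_graph(positions, scenario,
                                            streams["graph"])
    else:
        edges = pd.DataFrame(columns=EDGE_COLUMNS).astype(
            {"src": int, "dst": int})
    truth = GroundTruth(positions=positions, edges=edges)
    event_times, _ = simulate_events(truth, scenario, streams["events"])
    trace_set = render_traces(event_times, scenario, positions,
                              streams["noise"])
    return trace_set, truth
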