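"""Trace normalization, calcium-oscillation detection and activity statistics.

The per-culture readouts mirror the standard calcium-imaging triple: the
percentage of cells exhibiting Ca2+ activity, the mean oscillation duration
(onset to offset, seconds) and the mean oscillation frequency (oscillations
per minute), with culture means conditioned on active cells.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd

from .traces import TraceSet

__all__ = [
    "DegenerateBaselineError",
    "OscillationEvent",
    "ActivitySummary",
    "compute_dff",
    "auto_thresholds",
    "detect_oscillations",
    "detect_all",
    "summarize_activity",
]

#: Columns of the per-event table produced by :func:`detect_all`.
EVENT_COLUMNS = ["cell_id", "onset_s", "offset_s", "duration_s"]


class DegenerateBaselineError(ValueError):
    """Raised when a cell's fluorescence baseline is not positive."""


class OscillationEvent(NamedTuple):
    """One detected calcium oscillation of one cell."""

    cell_id: str
    onset: float      # s
    offset: float     # s
    duration: float   # s, exactly offset - onset


def compute_dff(trace_set: TraceSet, window_s: float = 60.0) -> TraceSet:
    """Normalize to dF/F against a rolling-percentile baseline.

    F0 is the centred rolling 10th percentile over ``window_s`` seconds,
    clamped from below at the cell's global 5th percentile so that
    oscillation-dense stretches cannot drag the baseline into the transients.
    """
    frames = max(int(round(window_s * trace_set.sampling_rate)), 1)
    fluor = trace_set.fluorescence
    df = pd.DataFrame(fluor.T)
    f0 = df.rolling(frames, min_periods=1, center=True).quantile(0.1).to_numpy().T
    floor = np.percentile(fluor, 5, axis=1, keepdims=True)
    f0 = np.maximum(f0, floor)
    bad = np.where(np.min(f0, axis=1) <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"non-positive baseline for cell {trace_set.cell_ids[bad[0]]}")
    return trace_set.with_fluorescence((fluor - f0) / f0)


def auto_thresholds(dff: np.ndarray) -> tuple[float, float]:
    """Data-driven hysteresis thresholds for one dF/F trace.

    The noise scale is a robust SD estimated from the differentiated trace
    (MAD x 1.4826 / sqrt(2)); onset = 4 sigma and offset = 2 sigma, floored at
    0.1 / 0.05 dF/F so that noiseless traces keep sane thresholds.  Both are
    measured above the trace's median dF/F: the percentile baseline sits below
    the noise mean, so a silent cell's dF/F is centred slightly above zero and
    absolute thresholds would mistake its noise for activity.
    """
    dff = np.asarray(dff, dtype=float)
    diff = np.diff(dff)
    sigma = 1.4826 * np.median(np.abs(diff - np.median(diff))) / np.sqrt(2.0)
    base = float(np.median(dff))
    return base + max(4.0 * sigma, 0.1), base + max(2.0 * sigma, 0.05)


def detect_oscillations(dff: np.ndarray,
                        sampling_rate: float,
                        onset_threshold: float | None = None,
                        offset_threshold: float | None = None,
                        min_duration: float = 1.0,
                        cell_id: str = "cell") -> list[OscillationEvent]:
    """Hysteresis event detection on one normalized trace.

    An event opens when dF/F reaches ``onset_threshold`` from below and closes
    when it falls below ``offset_threshold``; events shorter than
    ``min_duration`` seconds are discarded.  An event still open at the end of
    the recording closes at the last frame.
    """
    dff = np.asarray(dff, dtype=float)
    if onset_threshold is None or offset_threshold is None:
        auto_on, auto_off = auto_thresholds(dff)
        onset_threshold = auto_on if onset_threshold is None else onset_threshold
        offset_threshold = auto_off if offset_threshold is None else offset_threshold
    if onset_threshold <= offset_threshold:
        raise ValueError("onset_threshold must exceed offset_threshold")

    dt = 1.0 / sampling_rate
    events: list[OscillationEvent] = []
    open_at: int | None = None
    for i, value in enumerate(dff):
        if open_at is None:
            if value >= onset_threshold:
                open_at = i
        elif value < offset_threshold:
            _append_event(events, open_at, i, dt, min_duration, cell_id)
            open_at = None
    if open_at is not None:
        _append_event(events, open_at, len(dff) - 1, dt, min_duration, cell_id)
    return events


def _append_event(events: list[OscillationEvent], start: int, stop: int,
                  dt: float, min_duration: float, cell_id: str) -> None:
    onset, offset = start * dt, stop * dt
    if offset - onset >= min_duration:
        events.append(OscillationEvent(cell_id, onset, offset, offset - onset))


def detect_all(trace_set: TraceSet,
               onset_threshold: float | None = None,
               offset_threshold: float | None = None,
               min_duration: float = 1.0) -> pd.DataFrame:
    """Detect oscillations for every cell of a normalized trace set.

    Returns a tidy event table (``cell_id, onset_s, offset_s, duration_s``).
    Thresholds default to per-cell automatic values.
    """
    rows = []
    for i in range(trace_set.n_cells):
        for ev in detect_oscillations(
                trace_set.fluorescence[i], trace_set.sampling_rate,
                onset_threshold, offset_threshold, min_duration,
                cell_id=trace_set.cell_ids[i]):
            rows.append(ev)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else \
        pd.DataFrame(columns=EVENT_COLUMNS)


@dataclasses.dataclass
class ActivitySummary:
    """Per-cell and culture-level activity statistics.

    Culture-level ``mean_duration`` / ``mean_frequency`` are averaged over
    active cells only and are ``None`` when no cell is active.
    """

    per_cell: pd.DataFrame          # cell_id, n_events, frequency_per_min,
                                    # mean_duration_s, active
    percent_active: float           # %
    mean_duration: float | None     # s
    mean_frequency: float | None    # osc/min
    recording_duration: float       # s

    def to_dict(self) -> dict:
        return {
            "percent_active": self.percent_active,
            "mean_duration_s": self.mean_duration,
            "mean_frequency_per_min": self.mean_frequency,
            "n_cells": int(len(self.per_cell)),
            "recording_duration_s": self.recording_duration,
        }


def summarize_activity(events: pd.DataFrame,
                       trace_set: TraceSet) -> ActivitySummary:
    """Fold an event table into the three culture-level activity statistics.

    A cell is active iff it has at least one detected event; frequency is
    events per minute of recording.
    """
    duration_min = trace_set.duration / 60.0
    if duration_min <= 0:
        raise ValueError("recording duration must be positive")
    rows = []
    grouped = events.groupby("cell_id") if len(events) else None
    for cell_id in trace_set.cell_ids:
        if grouped is not None and cell_id in grouped.groups:
            cell_events = grouped.get_group(cell_id)
            n = len(cell_events)
            mean_dur = float(cell_events["duration_s"].mean())
        else:
            n, mean_dur = 0, np.nan
        rows.append({
            "cell_id": cell_id,
            "n_events": n,
            "frequency_per_min": n / duration_min,
            "mean_duration_s": mean_dur,
            "active": n >= 1,
        })
    per_cell = pd.DataFrame(rows)
    active = per_cell[per_cell["active"]]
    percent_active = 100.0 * len(active) / len(per_cell)
    mean_duration = float(active["mean_duration_s"].mean()) if len(active) else None
    mean_frequency = float(active["frequency_per_min"].mean()) if len(active) else None
    return ActivitySummary(
        per_cell=per_cell,
        percent_active=percent_active,
        mean_duration=mean_duration,
        mean_frequency=mean_frequency,
        recording_duration=trace_set.duration,
    )
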