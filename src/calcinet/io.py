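"""Readers and writers for trace tables, ROIs, image stacks and graphs.

Conventions: CSV is comma-separated UTF-8 with a mandatory header row and '.'
decimals; trace tables have ``cell_id`` first and one column per frame, with
sampling rate and cell coordinates in a JSON sidecar; spatial coordinates are
um with the origin at the top-left of the field, x rightward, y downward.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .network import ConnectivityGraph, NetworkMetrics
from .traces import TraceSet

__all__ = [
    "RoiSet",
    "read_trace_table",
    "write_trace_table",
    "read_tiff_stack",
    "write_tiff_stack",
    "rois_from_positions",
    "extract_roi_traces",
    "write_edge_table",
    "write_graphml",
    "write_metrics",
]


# --------------------------------------------------------------------------
# trace tables

def write_trace_table(trace_set: TraceSet, path: str | Path,
                      sidecar: str | Path | None = None) -> None:
    """Write a trace table CSV plus its JSON sidecar.

    The sidecar (default: same stem with ``.json``) stores ``sampling_rate``
    and per-cell positions; floats round-trip bit-exactly.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    frame_cols = [f"f{idx}" for idx in range(trace_set.n_frames)]
    df = pd.DataFrame(trace_set.fluorescence, columns=frame_cols)
    df.insert(0, "cell_id", trace_set.cell_ids)
    df.to_csv(path, index=False)  # str() floats: shortest round-trip repr
    meta = {
        "sampling_rate": trace_set.sampling_rate,
        "positions": {cid: [float(x), float(y)]
                      for cid, (x, y) in zip(trace_set.cell_ids,
                                             trace_set.positions)},
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_trace_table(path: str | Path,
                     sidecar: str | Path | None = None) -> TraceSet:
    """Read a trace table CSV and its JSON sidecar into a :class:`TraceSet`.

    Tables with missing values are rejected with the offending cell and frame
    named; the sidecar must carry ``sampling_rate`` and a position for every
    cell.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'cell_id' column")
    cell_ids = df["cell_id"].astype(str).tolist()
    values = df.drop(columns="cell_id")
    if values.isna().any().any():
        row, col = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value for cell {cell_ids[row]} in frame "
            f"column {values.columns[col]!r}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate", "positions"):
        if key not in meta:
            raise ValueError(f"{sidecar}: sidecar missing key {key!r}")
    try:
        positions = np.array([meta["positions"][cid] for cid in cell_ids],
                             dtype=float)
    except KeyError as exc:
        raise ValueError(f"{sidecar}: no position for cell {exc}") from None
    return TraceSet(
        fluorescence=values.to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate"]),
        positions=positions,
        cell_ids=cell_ids,
    )


# --------------------------------------------------------------------------
# image stacks and ROI extraction

def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (frames, height, width) stack as a multi-page grayscale TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF; multi-channel input is rejected."""
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack, got shape "
            f"{stack.shape}")
    return np.asarray(stack)


@dataclasses.dataclass
class RoiSet:
    """Circular regions of interest: per-cell centre (um) and radius (um)."""

    centers: np.ndarray   # (n, 2) um, (x, y)
    radii: np.ndarray     # (n,) um

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (self.centers.shape[0],)
        ).copy()
        if (self.radii <= 0).any():
            raise ValueError("ROI radii must be positive")

    def __len__(self) -> int:
        return self.centers.shape[0]


def rois_from_positions(positions: np.ndarray, radius: float = 6.0) -> RoiSet:
    """Build one circular ROI per cell centre with a common radius (um)."""
    return RoiSet(centers=np.asarray(positions, dtype=float), radii=radius)


def extract_roi_traces(stack: np.ndarray,
                       roi_set: RoiSet,
                       field_size: float,
                       sampling_rate: float,
                       cell_ids: list[str] | None = None) -> TraceSet:
    """Mean pixel intensity per frame inside each circular ROI.

    Pixel membership is centre-in-circle; the um-to-pixel scale is
    ``field_size / image_size``.  ROIs extending outside the field are
    rejected, naming their index.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    n_frames, height, width = stack.shape
    if height != width:
        raise ValueError("only square frames are supported")
    scale = field_size / width
    # Pixel-centre coordinates in um.
    px = (np.arange(width) + 0.5) * scale
    py = (np.arange(height) + 0.5) * scale

    bad = [i for i, ((x, y), r) in enumerate(zip(roi_set.centers,
                                                 roi_set.radii))
           if x - r < 0 or y - r < 0 or x + r > field_size or y + r > field_size]
    if bad:
        raise ValueError(f"ROI(s) outside the field of view: indices {bad}")

    flat = stack.reshape(n_frames, -1)
    traces = np.empty((len(roi_set), n_frames))
    for i, ((x, y), r) in enumerate(zip(roi_set.centers, roi_set.radii)):
        mask = ((px[None, :] - x) ** 2 + (py[:, None] - y) ** 2) <= r ** 2
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"ROI {i} covers no pixel centre")
        traces[i] = flat[:, idx].mean(axis=1)
    if cell_ids is None:
        cell_ids = TraceSet.default_ids(len(roi_set))
    return TraceSet(fluorescence=traces, sampling_rate=sampling_rate,
                    positions=roi_set.centers.copy(), cell_ids=cell_ids)


# --------------------------------------------------------------------------
# graphs and metrics

def write_edge_table(graph: ConnectivityGraph, path: str | Path) -> None:
    """Edge list CSV: ``src, dst, rho, lag_s, distance_um, speed_um_s``.

    Zero-lag edges have an empty speed field.
    """
    graph.edge_table().to_csv(Path(path), index=False)


def write_graphml(graph: ConnectivityGraph, path: str | Path) -> None:
    """GraphML export; the undefined speed of zero-lag edges is omitted."""
    nx.write_graphml(graph.graph, Path(path))


def write_metrics(metrics: NetworkMetrics, json_path: str | Path,
                  csv_path: str | Path | None = None) -> None:
    """Write the five network parameters as JSON (and optionally one-row CSV)."""
    data = metrics.to_dict()
    Path(json_path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        pd.DataFrame([data]).to_csv(Path(csv_path), index=False)
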