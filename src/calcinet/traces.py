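"""The trace container shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = ["TraceSet"]


@dataclasses.dataclass
class TraceSet:
    """Per-cell fluorescence time series with geometry and timing.

    Attributes
    ----------
    fluorescence : (n_cells, n_frames) float array
        Raw or normalized signal, one row per cell.
    sampling_rate : float
        Frames per second.
    positions : (n_cells, 2) float array
        Cell centres in um; origin at the top-left of the field, x rightward,
        y downward.
    cell_ids : list of str
        Stable labels, one per row.
    """

    fluorescence: np.ndarray
    sampling_rate: float
    positions: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a 2-D cells x frames array")
        if self.fluorescence.shape[1] < 2:
            raise ValueError("a trace set needs at least 2 frames")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.fluorescence.shape[0]
        if self.positions.shape != (n, 2):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} cells")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match trace count")
        if np.isnan(self.fluorescence).any():
            bad = np.argwhere(np.isnan(self.fluorescence))[0]
            raise ValueError(
                f"NaN in trace of cell {self.cell_ids[bad[0]]} "
                f"at frame {bad[1]}")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.sampling_rate

    def with_fluorescence(self, fluorescence: np.ndarray) -> "TraceSet":
        """Copy of this trace set with the signal matrix replaced."""
        return TraceSet(
            fluorescence=np.asarray(fluorescence, dtype=float),
            sampling_rate=self.sampling_rate,
            positions=self.positions.copy(),
            cell_ids=list(self.cell_ids),
        )

    def subset(self, indices: Sequence[int]) -> "TraceSet":
        idx = np.asarray(indices, dtype=int)
        return TraceSet(
            fluorescence=self.fluorescence[idx],
            sampling_rate=self.sampling_rate,
            positions=self.positions[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    @staticmethod
    def default_ids(n: int) -> list[str]:
        width = max(3, len(str(max(n - 1, 0))))
        return [f"cell_{i:0{width}d}" for i in range(n)]
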