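import numpy as np
import pytest

from calcinet import SyntheticScenario, TraceSet, simulate_recording


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A fast-to-simulate culture used across unit tests."""
    return SyntheticScenario(n_cells=8, duration=240.0, seed=3)


@pytest.fixture(scope="session")
def small_recording(small_scenario):
    return simulate_recording(small_scenario)


def make_traceset(matrix, sampling_rate=2.0, positions=None) -> TraceSet:
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if positions is None:
        positions = np.zeros((n, 2))
    return TraceSet(fluorescence=matrix, sampling_rate=sampling_rate,
                    positions=positions, cell_ids=TraceSet.default_ids(n))


def boxcar_trace(n_frames, pulses, level=0.5, sampling_rate=2.0):
    """dF/F trace that is ``level`` inside each (start_s, stop_s) pulse."""
    trace = np.zeros(n_frames)
    t = np.arange(n_frames) / sampling_rate
    for start, stop in pulses:
        trace[(t >= start) & (t < stop)] = level
    return trace
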