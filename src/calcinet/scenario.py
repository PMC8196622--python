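"""Generative scenario for synthetic calcium recordings.

A :class:`SyntheticScenario` fixes every knob of the simulator: the spatial
substrate (cells scattered over a square field of view), the directed coupling
graph, event kinetics, the fluorescence transient kernel, imaging noise, and a
multiplicative condition scaling that turns the sham parameterization into a
degraded ("hypoxia") one.  Identical scenario + seed reproduces every stage
bit-for-bit; per-stage random substreams are derived from one master seed so
stages can be rerun independently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "ScenarioError",
    "ConditionScaling",
    "SyntheticScenario",
    "SHAM",
    "HYPOXIA",
    "PRESETS",
]


class ScenarioError(ValueError):
    """Raised when a scenario is not a valid simulator parameterization."""


@dataclasses.dataclass(frozen=True)
class ConditionScaling:
    """Multiplicative condition factors applied on top of the base scenario.

    ``rate_factor`` scales the spontaneous event rate, ``transmit_factor`` the
    edge transmission probability, ``silenced_offset`` is added to the silenced
    fraction, and ``speed_factor`` scales the calcium-wave propagation speed
    (hypoxic cultures propagate signals more slowly as well as less often).
    """

    rate_factor: float = 1.0
    transmit_factor: float = 1.0
    silenced_offset: float = 0.0
    speed_factor: float = 1.0

    def validate(self) -> None:
        if self.rate_factor < 0 or self.transmit_factor < 0 or self.speed_factor <= 0:
            raise ScenarioError("condition factors must be positive")
        if not -1.0 <= self.silenced_offset <= 1.0:
            raise ScenarioError("silenced_offset must lie in [-1, 1]")


#: Untreated control condition: all factors neutral.
SHAM = ConditionScaling()

#: Post-hypoxic degradation: halved event rate and transmission, 30 % more
#: silenced cells, and calcium waves slowed to ~2/3 of control speed.
HYPOXIA = ConditionScaling(
    rate_factor=0.5, transmit_factor=0.5, silenced_offset=0.3, speed_factor=0.66
)

PRESETS: dict[str, ConditionScaling] = {"sham": SHAM, "hypoxia": HYPOXIA}

# Substream names, in a fixed order so seeds never migrate between stages.
_STREAMS = ("positions", "graph", "events", "noise", "movie")


@dataclasses.dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic recording.

    Defaults emulate a confocal recording of a dissociated cortical culture:
    2 Hz frame rate over a 420 x 420 um field of view, spontaneous calcium
    oscillations at a fraction of an event per minute, and signal propagation
    along a sparse directed coupling graph at ~20 um/s.
    """

    n_cells: int = 30
    field_size: float = 420.0          # um, square side
    sampling_rate: float = 2.0         # Hz
    duration: float = 1200.0           # s
    base_event_rate: float = 1.0       # spontaneous events / min / cell
    silenced_fraction: float = 0.0
    coupling_probability: float = 0.025
    connectivity_radius: float = 200.0  # um, candidate-edge radius
    transmit_probability: float = 0.5
    propagation_speed: float = 20.0    # um/s
    delay_jitter_sd: float = 0.25      # s, per-edge
    refractory: float = 2.0            # s, per-cell dead time
    amplitude: float = 1.0             # dF/F at transient peak
    rise_tau: float = 0.5              # s
    decay_tau: float = 2.0             # s
    baseline_f0: float = 100.0         # a.u.
    noise_sd: float = 0.05             # fraction of baseline
    bleach_rate: float = 0.0           # fractional baseline loss / s, off by default
    condition: ConditionScaling = SHAM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ScenarioError("n_cells must be >= 1")
        if self.field_size <= 0:
            raise ScenarioError("field_size must be positive")
        for name in ("sampling_rate", "duration", "rise_tau", "decay_tau",
                     "baseline_f0", "propagation_speed", "amplitude"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be strictly positive")
        for name in ("base_event_rate", "delay_jitter_sd", "noise_sd",
                     "refractory", "bleach_rate", "connectivity_radius"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be non-negative")
        for name in ("silenced_fraction", "coupling_probability",
                     "transmit_probability"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ScenarioError(f"{name} must lie in [0, 1]")
        if self.decay_tau <= self.rise_tau:
            raise ScenarioError("decay_tau must exceed rise_tau")
        self.condition.validate()

    # ---- effective (condition-scaled) parameters -------------------------

    @property
    def effective_event_rate(self) -> float:
        """Spontaneous rate after condition scaling, events/min."""
        return self.base_event_rate * self.condition.rate_factor

    @property
    def effective_transmit_probability(self) -> float:
        return float(np.clip(
            self.transmit_probability * self.condition.transmit_factor, 0.0, 1.0))

    @property
    def effective_silenced_fraction(self) -> float:
        return float(np.clip(
            self.silenced_fraction + self.condition.silenced_offset, 0.0, 1.0))

    @property
    def effective_propagation_speed(self) -> float:
        return self.propagation_speed * self.condition.speed_factor

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    # ---- seeding ---------------------------------------------------------

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent per-stage generators derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(child)
                for name, child in zip(_STREAMS, children)}

    # ---- (de)serialization ----------------------------------------------

    def replace(self, **changes: Any) -> "SyntheticScenario":
        return dataclasses.replace(self, **changes)

    def with_condition(self, condition: "ConditionScaling | str") -> "SyntheticScenario":
        if isinstance(condition, str):
            try:
                condition = PRESETS[condition]
            except KeyError:
                raise ScenarioError(
                    f"unknown condition preset {condition!r}; "
                    f"known: {sorted(PRESETS)}") from None
        return self.replace(condition=condition)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for name, preset in PRESETS.items():
            if self.condition == preset:
                out["condition"] = name
                break
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SyntheticScenario":
        data = dict(data)
        condition = data.pop("condition", "sham")
        if isinstance(condition, str):
            if condition not in PRESETS:
                raise ScenarioError(f"unknown condition preset {condition!r}")
            condition = PRESETS[condition]
        elif isinstance(condition, Mapping):
            condition = ConditionScaling(**condition)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(condition=condition, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticScenario":
        """Load a scenario from a flat JSON or YAML mapping."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ScenarioError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
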