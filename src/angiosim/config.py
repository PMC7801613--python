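"""Configuration loading and study presets.

``paper_scale`` is the published study's geometry (200^3 points over 1 cm,
33 steps/day, 60 days); ``desk_scale`` is the package's reduced geometry
for interactive work and the test/acceptance suites (32^3 by default, same
clock).  Biological parameters are identical between the two; only the
lattice resolution changes, with lengths still reported in mm through the
grid spacing.
"""

from __future__ import annotations

import yaml

from .engine import SimulationConfig
from .therapy import DoseSchedule

__all__ = ["load_config", "dump_config", "paper_scale", "desk_scale",
           "dosing_window"]


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def paper_scale(**overrides) -> SimulationConfig:
    """Full published geometry: 200^3 points, 60 days, 33 steps/day."""
    return SimulationConfig(points_per_axis=200, **overrides)


def desk_scale(points_per_axis: int = 32, **overrides) -> SimulationConfig:
    """Reduced geometry with the same clock and biology."""
    return SimulationConfig(points_per_axis=points_per_axis, **overrides)


def dosing_window(start_day: float, end_day: float, dose_rate: float = 40.0,
                  pattern: str = "continuous") -> DoseSchedule:
    """Single-window administration schedule."""
    return DoseSchedule(((float(start_day), float(end_day)),), pattern,
                        dose_rate)
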