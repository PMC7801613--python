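"""Anti-VEGF drug (bevacizumab) field: scheduled release, binding, decay.

The drug ``d`` is released from perfused vessel points at rate
``dv(t) * R_i * W`` during scheduled administration windows, diffuses and
convects like the other species, decays at ``lambda_d`` and binds VEGF at
rate ``B = min(d*c, d, c)`` per step; the bound amount is removed from
both the drug and the VEGF fields within the same step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from math import floor

import numpy as np

from .fields import Grid, ScalarField, VectorField, step_field

__all__ = ["DoseSchedule", "DrugParams", "dose_rate_at", "binding", "step_drug"]


@dataclass(frozen=True)
class DrugParams:
    D_d: float = 4.0        # diffusion, grid-step^2/day
    lambda_d: float = 1.0   # decay rate, 1/day

    def __post_init__(self) -> None:
        if self.D_d < 0 or self.lambda_d < 0:
            raise ValueError("D_d and lambda_d must be >= 0")


@dataclass(frozen=True)
class DoseSchedule:
    """Administration windows as half-open day intervals [start, end).

    ``pattern`` is ``continuous`` (drug released throughout each window) or
    ``alternate_day`` (released on the 1st, 3rd, ... day of each window).
    ``dose_rate`` is the dimensionless release-rate scale dv(t) while on.
    """

    windows: tuple[tuple[float, float], ...] = ()
    pattern: str = "continuous"
    dose_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in ("continuous", "alternate_day"):
            raise ValueError(f"pattern: unknown pattern {self.pattern!r}")
        if self.dose_rate < 0:
            raise ValueError("dose_rate must be >= 0")
        prev_end = -np.inf
        for start, end in self.windows:
            if not start < end:
                raise ValueError(f"window ({start}, {end}): start must be < end")
            if start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = end

    @property
    def empty(self) -> bool:
        return not self.windows or self.dose_rate == 0.0


def dose_rate_at(t: float, schedule: DoseSchedule) -> float:
    """Release-rate scale dv(t) at simulation time t (days)."""
    for start, end in schedule.windows:
        if start <= t < end:
            if schedule.pattern == "alternate_day":
                if (floor(t) - floor(start)) % 2 != 0:
                    return 0.0
            return schedule.dose_rate
    return 0.0


def binding(d: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-point VEGF-drug binding ``B = min(d*c, d, c)``."""
    return np.minimum(d * c, np.minimum(d, c))


def step_drug(
    d: ScalarField,
    u: VectorField | None,
    vessel_RW: np.ndarray,
    B: np.ndarray | float,
    schedule: DoseSchedule,
    params: DrugParams,
    grid: Grid,
    t: float,
    D_physical: float | None = None,
    allow_unstable: bool = False,
) -> ScalarField:
    """One explicit step of the drug field.

    ``vessel_RW`` is R_i*W at vessel points (0 elsewhere); ``B`` is the
    binding computed from the pre-step d and c (the engine subtracts the
    same B from the VEGF update).
    """
    D = params.D_d * grid.spacing ** 2 if D_physical is None else D_physical
    release = dose_rate_at(t, schedule) * vessel_RW
    sink = B + params.lambda_d * d.values
    return step_field(d, D, release, sink, u, grid, allow_unstable=allow_unstable)
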