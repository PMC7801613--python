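"""Species-specific reaction terms coupling agents to the chemical fields.

Rate laws
---------
* tumour cell activity      ``A = n/(n+1) * exp(-5 (w-1)^4)``
* O2 secretion at vessels   ``rho_n0 * R_i * W``
* O2 consumption by tumour  ``lambda_n0 * A``
* VEGF secretion by tumour  ``rho_c0 * max(0, 1-n)``  (hypoxia-driven)
* VEGF removal at TECs      ``lambda_c0 * R_i``
* vessel radius             ``R_i = Age/(Age+k_AR2) * k_AR1``
* Ang1 secretion at ECs     ``rho_a1_0 * theta_EC``; removal
  ``lambda_a1_0 * (a1 - 1)`` (signed, relaxes a1 toward its baseline 1)
* Ang2 secretion at TECs/branch candidates ``rho_a2_0 * theta_TEC``;
  first-order removal ``lambda_a2_0 * a2`` at all vessel points.

CO2 is handled like VEGF, with independent constants: tumour cells
secrete it both glycolytically under hypoxia (``rho_w0 * max(0, 1-n)``)
and through respiration in proportion to O2 uptake (``rho_w1 * n/(1+n)``);
perfused vessels clear it at ``lambda_w0 * R_i * W``.  Only the process list - diffusion,
convection, tumour secretion, vascular removal - is fixed by the model
family; the functional forms are a documented modelling choice.

Diffusion coefficients are expressed in grid-step^2 per day (the lattice
convention of the normalized model); the engine converts them to physical
units with the grid spacing before calling the PDE stepper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .fields import Grid, ScalarField, VectorField, step_field

__all__ = [
    "KineticParams",
    "cell_activity",
    "oxygen_secretion",
    "oxygen_consumption",
    "vegf_secretion",
    "vegf_consumption",
    "vessel_radius",
    "endothelial_density",
    "ang1_rates",
    "ang2_rates",
    "step_co2",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants for the six chemical species.

    Diffusion coefficients (``D_*``) are in grid-step^2/day; all other
    rates are per day on the dimensionless concentration scales.
    """

    # diffusion (grid-step^2 / day); stability needs D*dt <= 1/6 step^2
    D_n: float = 5.0
    D_w: float = 5.0
    D_c: float = 4.0
    D_a1: float = 0.05
    D_a2: float = 0.01

    # oxygen
    rho_n0: float = 60.0
    lambda_n0: float = 500.0

    # carbon dioxide (glycolytic + respiratory secretion)
    rho_w0: float = 20.0
    rho_w1: float = 20.0
    lambda_w0: float = 20.0

    # VEGF
    rho_c0: float = 150.0
    lambda_c0: float = 50.0

    # vessel radius law (dimensionless radius, age in days)
    k_AR1: float = 1.0
    k_AR2: float = 2.0

    # angiopoietins
    rho_a1_0: float = 10.0
    lambda_a1_0: float = 10.0
    rho_a2_0: float = 40.0
    lambda_a2_0: float = 0.1

    def __post_init__(self) -> None:
        if self.k_AR2 <= 0:
            raise ValueError("k_AR2 must be > 0")
        for name in ("D_n", "D_w", "D_c", "D_a1", "D_a2", "rho_n0",
                     "lambda_n0", "rho_w0", "rho_w1", "lambda_w0", "rho_c0",
                     "lambda_c0", "k_AR1", "rho_a1_0", "lambda_a1_0",
                     "rho_a2_0", "lambda_a2_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def cell_activity(n, w):
    """Tumour cell activity ``A = n/(n+1) * exp(-5 (w-1)^4)`` in [0, 1).

    Activity needs both oxygen (n >= 1 for the first factor to reach 1/2)
    and a waste level near the tissue baseline w = 1.
    """
    n = np.asarray(n, dtype=float)
    w = np.asarray(w, dtype=float)
    out = n / (n + 1.0) * np.exp(-5.0 * (w - 1.0) ** 4)
    return out if out.ndim else float(out)


def oxygen_secretion(R_i, W, params: KineticParams):
    """O2 supply rate at vessel points: rho_n0 * R_i * W."""
    return params.rho_n0 * R_i * W


def oxygen_consumption(A_i, params: KineticParams):
    """O2 consumption rate at tumour points: lambda_n0 * A_i."""
    return params.lambda_n0 * A_i


def vegf_secretion(n, params: KineticParams):
    """Hypoxia-driven VEGF secretion: rho_c0 * (1 - n), clamped at 0."""
    return params.rho_c0 * np.maximum(1.0 - np.asarray(n, dtype=float), 0.0)


def vegf_consumption(R_i, params: KineticParams):
    """VEGF removal at tip endothelial cells: lambda_c0 * R_i."""
    return params.lambda_c0 * R_i


def co2_secretion(n, params: KineticParams):
    """CO2 secretion by tumour cells: glycolytic under hypoxia plus
    respiratory in proportion to O2 uptake.

    ``rho_w0 * max(0, 1-n) + rho_w1 * n/(1+n)``
    """
    n = np.asarray(n, dtype=float)
    return (params.rho_w0 * np.maximum(1.0 - n, 0.0)
            + params.rho_w1 * n / (1.0 + n))


def vessel_radius(age, params: KineticParams):
    """Saturating radius growth: age/(age+k_AR2) * k_AR1.

    Zero at sprouting, half-saturated at age = k_AR2 days, approaching the
    mature radius k_AR1.
    """
    age = np.asarray(age, dtype=float)
    out = age / (age + params.k_AR2) * params.k_AR1
    return out if out.ndim else float(out)


def endothelial_density(occupancy: np.ndarray, k_neigh: int) -> np.ndarray:
    """Occupied fraction theta of the (2k+1)^3 cube around each point."""
    return uniform_filter(occupancy.astype(float), size=2 * k_neigh + 1,
                          mode="constant", cval=0.0)


def ang1_rates(theta_EC, a1, params: KineticParams):
    """(secretion, consumption) for Ang1 at endothelial cells.

    Consumption is signed: ``lambda_a1_0 * (a1 - 1)`` acts as a sink above
    the baseline a1 = 1 and as a source below it.
    """
    secretion = params.rho_a1_0 * np.asarray(theta_EC, dtype=float)
    consumption = params.lambda_a1_0 * (np.asarray(a1, dtype=float) - 1.0)
    return secretion, consumption


def ang2_rates(theta_TEC, a2, params: KineticParams):
    """(secretion, consumption) for Ang2: secreted at TECs, decays at vessels."""
    secretion = params.rho_a2_0 * np.asarray(theta_TEC, dtype=float)
    consumption = params.lambda_a2_0 * np.asarray(a2, dtype=float)
    return secretion, consumption


def step_co2(
    w: ScalarField,
    u: VectorField | None,
    tumour_source: np.ndarray,
    vessel_RW: np.ndarray,
    params: KineticParams,
    grid: Grid,
    D_physical: float | None = None,
    allow_unstable: bool = False,
) -> ScalarField:
    """One explicit step of the CO2 field.

    ``tumour_source`` is the secretion rate at tumour-occupied points
    (``co2_secretion(n) * occupancy``) and 0 elsewhere; ``vessel_RW`` is
    R_i*W at vessel points and 0 elsewhere.  ``D_physical`` overrides the
    lattice-convention diffusion coefficient (used by the engine, which
    pre-scales by spacing^2).
    """
    D = params.D_w * grid.spacing ** 2 if D_physical is None else D_physical
    sink = params.lambda_w0 * vessel_RW
    return step_field(w, D, tumour_source, sink, u, grid,
                      allow_unstable=allow_unstable)
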