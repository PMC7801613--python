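"""Tumour interstitial pressure: CTP, VTP, wall factor W and the gradient.

Cell-induced tumour pressure (CTP) at a point is the sum of contributions
from tumour-occupied points inside the (2k+1)^3 cube around it; vascular
perfusion-induced tumour pressure (VTP) is computed the same way from
vessel-occupied points.  The per-pair kernel is uniform, ``p0/N`` (resp.
``pV/N``) per occupied neighbour, so a fully occupied cube yields exactly
``p0`` (``pV``) at its centre.  The total pressure ``p = CTP + VTP`` sets
the trans-wall factor ``W = max(pV - p, 0)/pV`` and, through its gradient,
the convection field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .fields import Grid, VectorField

__all__ = [
    "PressureParams",
    "compute_ctp",
    "compute_vtp",
    "total_pressure",
    "wall_gradient_W",
    "pressure_gradient",
]


@dataclass(frozen=True)
class PressureParams:
    """Pressure scales (mmHg) and neighbourhood half-width k (N=(2k+1)^3)."""

    p0: float = 60.0       # tumour pressure scale, mmHg
    pV: float = 30.0       # capillary pressure, mmHg
    k_neigh: int = 1

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.pV <= 0:
            raise ValueError("p0 and pV must be > 0")
        if self.k_neigh < 1:
            raise ValueError("k_neigh must be >= 1")


def _box_sum_fraction(occupancy: np.ndarray, k: int) -> np.ndarray:
    """Fraction of the (2k+1)^3 cube occupied, zero outside the domain."""
    return uniform_filter(occupancy.astype(float), size=2 * k + 1,
                          mode="constant", cval=0.0)


def compute_ctp(tumour_occupancy: np.ndarray,
                params: PressureParams) -> np.ndarray:
    """CTP in mmHg: p0/N per tumour-occupied point in the cube."""
    return params.p0 * _box_sum_fraction(tumour_occupancy, params.k_neigh)


def compute_vtp(vessel_occupancy: np.ndarray,
                params: PressureParams) -> np.ndarray:
    """VTP in mmHg: pV/N per vessel-occupied point in the cube."""
    return params.pV * _box_sum_fraction(vessel_occupancy, params.k_neigh)


def total_pressure(ctp: np.ndarray, vtp: np.ndarray) -> np.ndarray:
    return ctp + vtp


def wall_gradient_W(pV: float, p: np.ndarray | float) -> np.ndarray | float:
    """Dimensionless trans-wall pressure factor.

    ``W = (pV - p)/pV`` where the capillary pressure exceeds the local
    pressure, 0 otherwise; lies in [0, 1] for any non-negative ``p``.
    """
    return np.maximum(pV - p, 0.0) / pV


def pressure_gradient(p: np.ndarray, grid: Grid) -> VectorField:
    """grad(p) in mmHg per grid step: central differences, one-sided at faces."""
    gx, gy, gz = np.gradient(p, 1.0)
    return VectorField(np.stack([gx, gy, gz]))
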