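"""Cubic grid, scalar/vector fields and explicit finite-difference operators.

All chemical species (oxygen ``n``, carbon dioxide ``w``, VEGF ``c``,
angiopoietin-1 ``a1``, angiopoietin-2 ``a2`` and the anti-VEGF drug ``d``)
live as dimensionless concentrations on one shared cubic grid.  They evolve
by an explicit forward-Euler step of a reaction-diffusion-convection
equation::

    df/dt = D * lap(f) - div(u f) + source - sink

discretised with a 7-point Laplacian and first-order upwind convection.
Boundaries are Dirichlet on all six faces, with per-species boundary values
re-imposed after every update, and fields are clamped to be non-negative
(a concentration driven below zero by a sink is reset to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import StabilityError

__all__ = [
    "Grid",
    "ScalarField",
    "VectorField",
    "laplacian",
    "advection",
    "step_field",
    "clamp_nonnegative",
]


@dataclass(frozen=True)
class Grid:
    """Uniform cubic lattice.

    Parameters
    ----------
    points_per_axis:
        Number of lattice points along each axis (>= 3).
    domain_edge:
        Physical edge length of the cubic domain in cm (default 1 cm).
    dt:
        Time step in days (default 1/33 day, i.e. 33 steps per day).
    """

    points_per_axis: int
    domain_edge: float = 1.0
    dt: float = 1.0 / 33.0

    def __post_init__(self) -> None:
        if self.points_per_axis < 3:
            raise ValueError("points_per_axis must be >= 3")
        if self.domain_edge <= 0:
            raise ValueError("domain_edge must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def spacing(self) -> float:
        """Lattice spacing in cm (domain_edge / points_per_axis)."""
        return self.domain_edge / self.points_per_axis

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.points_per_axis
        return (n, n, n)

    def centre(self) -> tuple[int, int, int]:
        m = self.points_per_axis // 2
        return (m, m, m)


@dataclass
class ScalarField:
    """A named dimensionless concentration with a Dirichlet boundary value."""

    name: str
    values: np.ndarray
    boundary_value: float = 0.0

    @classmethod
    def full(cls, name: str, grid: Grid, value: float,
             boundary_value: float | None = None) -> "ScalarField":
        bv = value if boundary_value is None else boundary_value
        return cls(name, np.full(grid.shape, float(value)), bv)

    def apply_boundary(self) -> None:
        """Re-impose the Dirichlet value on all six faces."""
        v = self.values
        bv = self.boundary_value
        v[0, :, :] = bv
        v[-1, :, :] = bv
        v[:, 0, :] = bv
        v[:, -1, :] = bv
        v[:, :, 0] = bv
        v[:, :, -1] = bv

    def copy(self) -> "ScalarField":
        return ScalarField(self.name, self.values.copy(), self.boundary_value)


@dataclass
class VectorField:
    """Three per-point components stacked as an array of shape (3, n, n, n)."""

    components: np.ndarray

    @classmethod
    def zeros(cls, grid: Grid) -> "VectorField":
        return cls(np.zeros((3,) + grid.shape))


def clamp_nonnegative(values: np.ndarray) -> np.ndarray:
    """Clip negative entries to zero in place and return the array."""
    np.maximum(values, 0.0, out=values)
    return values


def _padded(field: ScalarField) -> np.ndarray:
    """Field values with a one-point ghost layer at the Dirichlet value."""
    return np.pad(field.values, 1, mode="constant",
                  constant_values=field.boundary_value)


def laplacian(field: ScalarField, grid: Grid) -> np.ndarray:
    """7-point Laplacian, Dirichlet ghost cells at the boundary value."""
    g = _padded(field)
    c = g[1:-1, 1:-1, 1:-1]
    out = (
        g[2:, 1:-1, 1:-1] + g[:-2, 1:-1, 1:-1]
        + g[1:-1, 2:, 1:-1] + g[1:-1, :-2, 1:-1]
        + g[1:-1, 1:-1, 2:] + g[1:-1, 1:-1, :-2]
        - 6.0 * c
    )
    out /= grid.spacing ** 2
    return out


def advection(field: ScalarField, u: VectorField, grid: Grid) -> np.ndarray:
    """First-order upwind evaluation of ``-div(u f)``.

    The flux ``F = u_axis * f`` is differenced one-sidedly per axis, the
    side chosen by the sign of the local velocity component; ghost fluxes
    are edge-replicated (faces are overwritten by the Dirichlet condition
    after each step, so only interior values matter).
    """
    h = grid.spacing
    out = np.zeros_like(field.values)
    for axis in range(3):
        ua = u.components[axis]
        flux = ua * field.values
        gf = np.pad(flux, 1, mode="edge")[
            tuple(slice(1, -1) if a != axis else slice(None) for a in range(3))
        ]
        sl_lo = tuple(slice(None) if a != axis else slice(0, -2) for a in range(3))
        sl_mid = tuple(slice(None) if a != axis else slice(1, -1) for a in range(3))
        sl_hi = tuple(slice(None) if a != axis else slice(2, None) for a in range(3))
        backward = (gf[sl_mid] - gf[sl_lo]) / h
        forward = (gf[sl_hi] - gf[sl_mid]) / h
        dflux = np.where(ua > 0.0, backward, forward)
        out -= dflux
    return out


def step_field(
    field: ScalarField,
    D: float,
    source: np.ndarray | float,
    sink: np.ndarray | float,
    u: VectorField | None,
    grid: Grid,
    allow_unstable: bool = False,
) -> ScalarField:
    """Advance one explicit Euler step in place and return the field.

    Checks the diffusive stability bound ``D*dt/h^2 <= 1/6`` unless
    ``allow_unstable`` is set; after the update the field is clamped to be
    non-negative and the Dirichlet boundary is re-imposed.
    """
    h2 = grid.spacing ** 2
    if not allow_unstable and D * grid.dt / h2 > 1.0 / 6.0 + 1e-12:
        raise StabilityError(
            f"field '{field.name}': D*dt/h^2 = {D * grid.dt / h2:.4g} > 1/6; "
            "reduce dt or D, or set allow_unstable"
        )
    rhs = D * laplacian(field, grid)
    if u is not None:
        rhs += advection(field, u, grid)
    rhs += source
    rhs -= sink
    field.values += grid.dt * rhs
    clamp_nonnegative(field.values)
    field.apply_boundary()
    return field
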