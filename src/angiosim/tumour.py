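"""Tumour-cell agents: activity classification, CVE dynamics, division.

Each lattice point holds at most one cell.  A living cell is *active* when
its activity ``A_i >= 0.5`` (which requires n >= 1 and waste w near the
baseline 1) and *quiescent* otherwise; the switch is reversible.  Cell
Vital Energy (CVE, ``V_i``) integrates ``A/(A+1)*k_active`` while active
and drains at ``k_quiescent`` while quiescent; crossing the threshold
``t_CVE`` triggers division into the lowest-pressure free Moore-26
neighbour, and ``V_i <= 0`` triggers irreversible necrosis.

The population is stored as dense per-grid arrays (state/A/V) for speed;
``TumourCell`` plus the scalar update helpers expose the same rules on a
single cell for clarity and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import cell_activity

__all__ = [
    "EMPTY", "ACTIVE", "QUIESCENT", "NECROTIC",
    "TumourParams", "TumourCell", "TumourCellPopulation",
    "update_state", "update_cve",
]

EMPTY, ACTIVE, QUIESCENT, NECROTIC = 0, 1, 2, 3

# Moore-26 neighbourhood offsets in lexicographic order (deterministic
# iteration order matters for seeded tie-breaking).
_MOORE26 = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=int,
)


@dataclass(frozen=True)
class TumourParams:
    k_active: float = 0.8       # CVE gain rate while active, 1/day
    k_quiescent: float = 0.015   # CVE drain rate while quiescent, 1/day
    t_cve: float = 1.0          # division threshold
    v_init: float = 1.0         # CVE of seeded cells
    daughter_v: float = 0.5     # CVE granted to a newborn daughter

    def __post_init__(self) -> None:
        if min(self.k_active, self.k_quiescent, self.t_cve) <= 0:
            raise ValueError("k_active, k_quiescent and t_cve must be > 0")
        if self.daughter_v < 0:
            raise ValueError("daughter_v must be >= 0")


@dataclass
class TumourCell:
    """Single-cell view used by the per-cell update helpers."""

    position: tuple[int, int, int]
    state: int = QUIESCENT
    A_i: float = 0.0
    V_i: float = 0.0


def update_state(cell: TumourCell, n_at_cell: float, w_at_cell: float) -> TumourCell:
    """Recompute activity and re-classify; necrotic cells are untouched."""
    if cell.state == NECROTIC:
        return cell
    cell.A_i = cell_activity(n_at_cell, w_at_cell)
    cell.state = ACTIVE if cell.A_i >= 0.5 else QUIESCENT
    return cell


def update_cve(cell: TumourCell, dt: float, params: TumourParams) -> TumourCell:
    """Forward-Euler CVE update; V_i <= 0 switches irreversibly to necrosis."""
    if cell.state == NECROTIC:
        return cell
    if cell.state == ACTIVE:
        cell.V_i += dt * cell.A_i / (cell.A_i + 1.0) * params.k_active
    else:
        cell.V_i -= dt * params.k_quiescent
    if cell.V_i <= 0.0:
        cell.V_i = 0.0
        cell.state = NECROTIC
    return cell


class TumourCellPopulation:
    """Dense-array population with one-cell-per-point occupancy."""

    def __init__(self, shape: tuple[int, int, int], params: TumourParams):
        self.params = params
        self.state = np.zeros(shape, dtype=np.uint8)
        self.A = np.zeros(shape, dtype=float)
        self.V = np.zeros(shape, dtype=float)

    # -- occupancy views ---------------------------------------------------
    @property
    def occupied(self) -> np.ndarray:
        """All tumour-occupied points, necrotic included (they keep volume)."""
        return self.state != EMPTY

    @property
    def alive(self) -> np.ndarray:
        return (self.state == ACTIVE) | (self.state == QUIESCENT)

    # -- lifecycle ---------------------------------------------------------
    def seed(self, positions) -> None:
        for pos in positions:
            pos = tuple(int(i) for i in pos)
            if self.state[pos] != EMPTY:
                raise ValueError(f"duplicate tumour seed at {pos}")
            self.state[pos] = QUIESCENT
            self.V[pos] = self.params.v_init

    def update_states(self, n: np.ndarray, w: np.ndarray) -> None:
        """Vectorised activity recomputation and active/quiescent switch."""
        alive = self.alive
        if not alive.any():
            return
        A = cell_activity(n, w)
        self.A[alive] = A[alive]
        self.state[alive & (A >= 0.5)] = ACTIVE
        self.state[alive & (A < 0.5)] = QUIESCENT

    def update_cve(self, dt: float) -> None:
        p = self.params
        act = self.state == ACTIVE
        qui = self.state == QUIESCENT
        self.V[act] += dt * self.A[act] / (self.A[act] + 1.0) * p.k_active
        self.V[qui] -= dt * p.k_quiescent
        dead = (act | qui) & (self.V <= 0.0)
        self.V[dead] = 0.0
        self.state[dead] = NECROTIC

    def attempt_divisions(self, pressure: np.ndarray, blocked: np.ndarray,
                          rng: np.random.Generator) -> int:
        """Divide every active cell with V > t_CVE into its lowest-pressure
        free Moore-26 neighbour.

        ``blocked`` is the union occupancy of all containers (tumour +
        vessels).  Cells are processed in lexicographic order; pressure ties
        are broken uniformly at random.  A boxed-in cell keeps its energy
        capped at t_CVE.  Returns the number of daughters placed.
        """
        p = self.params
        eligible = (self.state == ACTIVE) & (self.V > p.t_cve)
        if not eligible.any():
            return 0
        shape = self.state.shape
        born = 0
        occ = blocked | self.occupied
        for pos in np.argwhere(eligible):
            pos = tuple(int(i) for i in pos)
            if self.V[pos] <= p.t_cve or self.state[pos] != ACTIVE:
                continue
            neigh = _MOORE26 + pos
            inside = np.all((neigh >= 0) & (neigh < shape), axis=1)
            neigh = neigh[inside]
            free = ~occ[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
            neigh = neigh[free]
            if neigh.size == 0:
                self.V[pos] = p.t_cve
                continue
            pvals = pressure[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
            best = np.flatnonzero(pvals == pvals.min())
            choice = best[0] if best.size == 1 else rng.choice(best)
            target = tuple(int(i) for i in neigh[choice])
            self.state[target] = QUIESCENT
            self.A[target] = 0.0
            self.V[target] = p.daughter_v
            self.V[pos] -= p.t_cve
            occ[target] = True
            born += 1
        return born

    def census(self) -> dict[str, int]:
        active = int((self.state == ACTIVE).sum())
        quiescent = int((self.state == QUIESCENT).sum())
        necrotic = int((self.state == NECROTIC).sum())
        return {
            "active": active,
            "quiescent": quiescent,
            "necrotic": necrotic,
            "alive": active + quiescent,
        }
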