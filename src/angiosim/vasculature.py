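"""Vessel network: sprouting, tip-cell extension, regression, length.

The vasculature is a forest of lattice nodes anchored on *existing*
vessels.  Angiogenesis proceeds in stages:

1. ordinary vessel nodes stochastically become *branch candidates* with
   probability ``p_BH = (l/l_max)^f * k_BH_0 * alpha_BH^log10(c)`` driven
   by local VEGF ``c`` and distance ``l`` from the initial tumour centroid;
   candidates start secreting Ang2;
2. a candidate *sprouts* once the angiopoietin balance destabilises the
   wall (``a2 > h * a1``): a tip endothelial cell (TEC) appears at the
   free orthogonal neighbour with the highest VEGF;
3. the TEC extends up the VEGF gradient, one lattice step per extension
   cycle ``tau = k_v * alpha_v^dp`` (dp = trans-wall pressure difference);
4. once a sprout is older than ``regression_min_age`` days and Ang2 still
   dominates at the branch point it sprang from (the anchor's Ang2
   accumulates in place, while a migrating tip constantly outruns its own
   trail), the distal branch regresses (is pruned back to the nearest
   upstream branch point or existing-vessel anchor) with probability
   ``p_rg = (1 - l/l_max)^g * k_rg_0 * alpha_rg^log10(c)`` evaluated from
   the VEGF seen by the tip.

With ``alpha_BH > 1`` and ``alpha_rg < 1`` rising VEGF simultaneously
promotes branching and protects young vessels from regression, which is
what produces the proliferative / regressive / re-proliferative phases of
the total new-vessel length.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigError
from .fields import Grid

__all__ = [
    "SproutParams",
    "VesselNode",
    "VesselNetwork",
    "generate_initial_vasculature",
    "branching_probability",
    "regression_probability",
    "instability_condition",
    "extension_cycle",
    "total_new_length",
]

_ORTHO6 = np.array(
    [(-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0)],
    dtype=int,
)


@dataclass(frozen=True)
class SproutParams:
    """Constants of the branching/regression probability laws and tip kinetics."""

    k_BH_0: float = 0.004    # branching probability scale, per step
    alpha_BH: float = 3.0      # VEGF gain of branching (>1: more VEGF, more branching)
    f: float = 1.0             # distance exponent of branching prefactor
    h: float = 3.0             # wall-destabilisation threshold: sprout iff a2 > h*a1
    k_rg_0: float = 0.6        # regression probability scale, per step
    alpha_rg: float = 0.03     # VEGF gain of regression (<1: VEGF protects)
    g: float = 1.0             # distance exponent of regression prefactor
    regression_min_age: float = 3.0   # days a sprout is immune to regression
    k_v: float = 0.25          # extension cycle scale, days
    alpha_v: float = 0.98      # pressure sensitivity: high outside pressure slows tips
    c_ext_min: float = 0.05    # minimal VEGF a TEC needs to migrate
    log_base: float = 10.0     # base of the log in the probability laws
    c_floor: float = 1e-12     # VEGF below this: p_BH = 0, log argument floored

    def __post_init__(self) -> None:
        if self.alpha_BH <= 0 or self.alpha_rg <= 0:
            raise ValueError("alpha_BH and alpha_rg must be > 0")
        if self.regression_min_age < 0:
            raise ValueError("regression_min_age must be >= 0")
        if self.k_v <= 0 or self.alpha_v <= 0:
            raise ValueError("k_v and alpha_v must be > 0")


@dataclass
class VesselNode:
    position: tuple[int, int, int]
    kind: str = "existing"            # "existing" | "new"
    is_tec: bool = False
    is_candidate: bool = False
    is_ang2_source: bool = False      # set at candidacy, persists after sprouting
    sprout_id: int = -1               # -1 for existing vessels
    parent: tuple[int, int, int] | None = None
    ext_elapsed: float = 0.0          # days since last TEC extension


def branching_probability(c_i, l, params: SproutParams, l_max: float):
    """Sprouting/branching probability, clamped to [0, 1]; 0 below c_floor."""
    c = np.asarray(c_i, dtype=float)
    l = np.asarray(l, dtype=float)
    logc = np.log(np.maximum(c, params.c_floor)) / np.log(params.log_base)
    p = (l / l_max) ** params.f * params.k_BH_0 * params.alpha_BH ** logc
    p = np.where(c > params.c_floor, p, 0.0)
    out = np.clip(p, 0.0, 1.0)
    return out if out.ndim else float(out)


def regression_probability(c_i, l, params: SproutParams, l_max: float):
    """Regression probability, clamped to [0, 1]; decreasing in l and, for
    alpha_rg < 1, in VEGF."""
    c = np.asarray(c_i, dtype=float)
    l = np.asarray(l, dtype=float)
    logc = np.log(np.maximum(c, params.c_floor)) / np.log(params.log_base)
    p = (1.0 - l / l_max) ** params.g * params.k_rg_0 * params.alpha_rg ** logc
    out = np.clip(p, 0.0, 1.0)
    return out if out.ndim else float(out)


def instability_condition(a1, a2, h: float):
    """Wall destabilisation: Ang2 strictly dominates, ``a2 > h * a1``."""
    return np.asarray(a2) > h * np.asarray(a1)


def extension_cycle(delta_p, params: SproutParams):
    """Time (days) a TEC needs before its next one-step extension."""
    out = params.k_v * params.alpha_v ** np.asarray(delta_p, dtype=float)
    return out if out.ndim else float(out)


class VesselNetwork:
    """Forest of vessel nodes on the lattice with occupancy bookkeeping."""

    def __init__(self, shape: tuple[int, int, int]):
        self.shape = shape
        self.nodes: dict[tuple[int, int, int], VesselNode] = {}
        self.children: dict[tuple[int, int, int], set] = {}
        self.occupancy = np.zeros(shape, dtype=bool)
        self.sprout_birth: dict[int, float] = {}
        self.sprout_anchor: dict[int, tuple[int, int, int]] = {}
        self._next_sprout_id = 0
        # incremental masks mirroring per-node flags (kept in sync by the
        # mutators below; the flags on the nodes stay authoritative)
        self._tec_mask = np.zeros(shape, dtype=bool)
        self._candidate_mask = np.zeros(shape, dtype=bool)
        self._ang2_mask = np.zeros(shape, dtype=bool)
        self._existing_mask = np.zeros(shape, dtype=bool)
        # sprout birth day per occupied point (existing vessels: -inf)
        self._birth_grid = np.full(shape, np.nan)

    # -- bookkeeping -------------------------------------------------------
    def add_node(self, node: VesselNode) -> None:
        pos = node.position
        if self.occupancy[pos]:
            raise ValueError(f"vessel node already at {pos}")
        self.nodes[pos] = node
        self.occupancy[pos] = True
        self._tec_mask[pos] = node.is_tec
        self._candidate_mask[pos] = node.is_candidate
        self._ang2_mask[pos] = node.is_ang2_source
        self._existing_mask[pos] = node.kind == "existing"
        if node.kind == "existing":
            self._birth_grid[pos] = -np.inf
        else:
            self._birth_grid[pos] = self.sprout_birth.get(node.sprout_id, 0.0)
        self.children.setdefault(pos, set())
        if node.parent is not None:
            self.children.setdefault(node.parent, set()).add(pos)

    def _remove_node(self, pos) -> None:
        node = self.nodes.pop(pos)
        self.occupancy[pos] = False
        self._tec_mask[pos] = False
        self._candidate_mask[pos] = False
        self._ang2_mask[pos] = False
        self._existing_mask[pos] = False
        self._birth_grid[pos] = np.nan
        self.children.pop(pos, None)
        if node.parent is not None and node.parent in self.children:
            self.children[node.parent].discard(pos)

    def _set_tec(self, pos, value: bool) -> None:
        self.nodes[pos].is_tec = value
        self._tec_mask[pos] = value

    def _set_candidate(self, pos, value: bool) -> None:
        node = self.nodes[pos]
        node.is_candidate = value
        self._candidate_mask[pos] = value
        if value:
            node.is_ang2_source = True
            self._ang2_mask[pos] = True

    # -- views -------------------------------------------------------------
    def positions(self, *, kind=None, tec=None, candidate=None) -> list:
        """Lexicographically sorted node positions matching the filters."""
        mask = self.occupancy.copy()
        if kind is not None:
            mask &= self._existing_mask if kind == "existing" \
                else ~self._existing_mask
        if tec is not None:
            mask &= self._tec_mask if tec else ~self._tec_mask
        if candidate is not None:
            mask &= self._candidate_mask if candidate else ~self._candidate_mask
        return [tuple(int(i) for i in row) for row in np.argwhere(mask)]

    def ec_occupancy(self) -> np.ndarray:
        """Occupancy of ordinary (non-tip) endothelial cells."""
        return self.occupancy & ~self._tec_mask

    def tec_occupancy(self, include_candidates: bool = True) -> np.ndarray:
        """Occupancy of Ang2-secreting sites: TECs and (by default) branch
        points -- current candidates and anchors that have already
        sprouted.  Once wall destabilisation marks a node it keeps
        expressing Ang2 for as long as it exists."""
        occ = np.zeros(self.shape, dtype=bool)
        for pos, node in self.nodes.items():
            if node.is_tec or (include_candidates and node.is_ang2_source):
                occ[pos] = True
        return occ

    def branch_points(self) -> list:
        """Lexicographically sorted positions of Ang2-expressing branch
        points (candidates plus sprouted anchors)."""
        return [pos for pos in sorted(self.nodes)
                if self.nodes[pos].is_ang2_source]

    def radius_map(self, now: float, k_AR1: float, k_AR2: float) -> np.ndarray:
        """Dimensionless radius R_i per vessel point; existing vessels are
        mature (R = k_AR1), new vessels follow the saturating age law."""
        with np.errstate(invalid="ignore"):
            age = np.maximum(now - self._birth_grid, 0.0)
            R = np.where(np.isinf(self._birth_grid), k_AR1,
                         age / (age + k_AR2) * k_AR1)
        R[~self.occupancy] = 0.0
        return R

    def sprout_age(self, node: VesselNode, now: float) -> float:
        return now - self.sprout_birth[node.sprout_id]

    def n_new(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "new")

    # -- angiogenesis operations --------------------------------------------
    def _free_ortho_neighbours(self, pos, blocked: np.ndarray) -> np.ndarray:
        neigh = _ORTHO6 + pos
        inside = np.all((neigh >= 0) & (neigh < self.shape), axis=1)
        neigh = neigh[inside]
        free = ~blocked[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
        return neigh[free]

    def mark_candidates(self, c: np.ndarray, l: np.ndarray, l_max: float,
                        blocked: np.ndarray, rng: np.random.Generator,
                        params: SproutParams) -> int:
        """Bernoulli-draw new branch candidates over all eligible nodes.

        Eligible: non-TEC, non-candidate nodes with at least one free
        orthogonal neighbour.  Draws proceed in lexicographic node order so
        that a single seed reproduces the trajectory.  Returns the number
        of new candidates.
        """
        pool_mask = self.occupancy & ~self._tec_mask & ~self._candidate_mask
        P = np.argwhere(pool_mask)
        if P.size == 0:
            return 0
        has_free = np.zeros(len(P), dtype=bool)
        dims = np.array(self.shape)
        for off in _ORTHO6:
            Q = P + off
            inside = np.all((Q >= 0) & (Q < dims), axis=1)
            Qc = np.clip(Q, 0, dims - 1)
            has_free |= inside & ~blocked[Qc[:, 0], Qc[:, 1], Qc[:, 2]]
        if not has_free.any():
            return 0
        P = P[has_free]
        cv = c[P[:, 0], P[:, 1], P[:, 2]]
        lv = l[P[:, 0], P[:, 1], P[:, 2]]
        p = branching_probability(cv, lv, params, l_max)
        hits = rng.random(len(P)) < p
        for row in P[hits]:
            self._set_candidate(tuple(int(i) for i in row), True)
        return int(hits.sum())

    def sprout(self, pos, c: np.ndarray, blocked: np.ndarray,
               rng: np.random.Generator, now: float) -> tuple | None:
        """Turn a destabilised candidate into a sprout: place a TEC at the
        free orthogonal neighbour with the highest VEGF (ties random).

        The caller has already checked the instability condition.  With no
        free neighbour the candidate is retained and nothing happens.
        Returns the new tip position, or None.
        """
        node = self.nodes[pos]
        free = self._free_ortho_neighbours(pos, blocked)
        if free.size == 0:
            return None
        cv = c[free[:, 0], free[:, 1], free[:, 2]]
        best = np.flatnonzero(cv == cv.max())
        choice = best[0] if best.size == 1 else rng.choice(best)
        target = tuple(int(i) for i in free[choice])
        sid = self._next_sprout_id
        self._next_sprout_id += 1
        self.sprout_birth[sid] = now
        self.sprout_anchor[sid] = pos
        self.add_node(VesselNode(target, kind="new", is_tec=True,
                                 sprout_id=sid, parent=pos))
        self._set_candidate(pos, False)
        self._ang2_mask[pos] = True   # anchors keep expressing Ang2
        node.is_ang2_source = True
        return target

    def extend_tec(self, pos, c: np.ndarray, blocked: np.ndarray,
                   rng: np.random.Generator,
                   c_min: float = 0.0) -> tuple | None:
        """Advance a TEC one step up the VEGF field (ties random).

        The TEC flag moves to the new node; the old tip becomes an ordinary
        new-vessel EC.  Returns the new tip position, or None if boxed in
        or if no reachable point offers at least ``c_min`` VEGF (tip
        migration is VEGF chemotaxis; without ligand the tip stalls).
        """
        node = self.nodes[pos]
        free = self._free_ortho_neighbours(pos, blocked)
        if free.size == 0:
            return None
        cv = c[free[:, 0], free[:, 1], free[:, 2]]
        if cv.max() < c_min:
            return None
        best = np.flatnonzero(cv == cv.max())
        choice = best[0] if best.size == 1 else rng.choice(best)
        target = tuple(int(i) for i in free[choice])
        self.add_node(VesselNode(target, kind="new", is_tec=True,
                                 sprout_id=node.sprout_id, parent=pos,
                                 ext_elapsed=0.0))
        self._set_tec(pos, False)
        return target

    def regress_branch(self, tec_pos) -> int:
        """Remove the branch ending at ``tec_pos`` back to (exclusive) the
        nearest upstream branch point or existing-vessel anchor.

        Returns the number of nodes removed.  Sibling branches hanging off
        the anchor are untouched.
        """
        removed = 0
        pos = tec_pos
        while pos is not None:
            node = self.nodes[pos]
            if node.kind == "existing":
                break
            if len(self.children.get(pos, ())) > 0:
                break  # upstream branch point feeding a sibling
            parent = node.parent
            self._remove_node(pos)
            removed += 1
            pos = parent
        return removed


def total_new_length(network: VesselNetwork, grid: Grid) -> float:
    """Total length of new vessels in mm: one lattice spacing per new node."""
    return network.n_new() * grid.spacing * 10.0


def generate_initial_vasculature(spec: dict | None, grid: Grid,
                                 rng: np.random.Generator,
                                 tumour_seeds=()) -> VesselNetwork:
    """Build the pre-existing vasculature fixture.

    ``spec`` options (dict):

    * ``{"kind": "parallel_lines", "count": 2, "offset": <steps>}`` -
      straight vessels running along y near two opposite x-faces at
      mid-height z (default);
    * ``{"kind": "nodes", "positions": [...]}`` - explicit node list;
    * ``None`` or ``{"kind": "empty"}`` - no vessels.

    Raises ConfigError if a vessel node collides with a tumour seed.
    """
    net = VesselNetwork(grid.shape)
    spec = dict(spec or {"kind": "parallel_lines"})
    kind = spec.get("kind", "parallel_lines")
    n = grid.points_per_axis
    positions: list[tuple[int, int, int]] = []
    if kind == "empty":
        pass
    elif kind == "nodes":
        positions = [tuple(int(i) for i in p) for p in spec["positions"]]
    elif kind == "parallel_lines":
        count = int(spec.get("count", 2))
        offset = int(spec.get("offset", max(2, n // 8)))
        z = int(spec.get("z", n // 2))
        xs = [offset, n - 1 - offset][:count]
        for x in xs:
            for y in range(n):
                positions.append((x, y, z))
    else:
        raise ConfigError(f"vasculature.kind: unknown kind {kind!r}")
    seeds = {tuple(int(i) for i in s) for s in tumour_seeds}
    for pos in positions:
        if pos in seeds:
            raise ConfigError(
                f"vasculature: vessel node {pos} collides with a tumour seed")
        if any(not (0 <= pos[i] < n) for i in range(3)):
            raise ConfigError(f"vasculature: node {pos} outside the grid")
        net.add_node(VesselNode(pos, kind="existing"))
    return net
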