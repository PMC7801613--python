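"""Simulation orchestration: configuration, initialization, the step loop.

Each step executes, in order:

1. **pressure** - CTP and VTP from the current occupancies, total pressure
   ``p``, its gradient, the Darcy convection velocity ``u = -K grad(p)``
   and the trans-wall factor ``W``;
2. **fields** - explicit updates of O2, CO2, VEGF (minus drug binding when
   therapy is active), Ang1, Ang2 and the drug, all from the same pre-step
   snapshot of the fields;
3. **angiogenesis** - branch-candidate marking, Ang-gated sprouting, tip
   extension along the VEGF field (gated by the extension cycle tau) and
   Ang-gated regression;
4. **tumour** - activity reclassification, CVE integration with necrosis,
   and pressure-directed divisions;
5. **metrics** - one record row.

A single integer seed feeds one ``numpy.random.Generator``; all stochastic
draws (candidates in lexicographic node order, then sprouts, then
extensions, then regressions, then divisions) consume it in a fixed order,
so a seed fully determines a trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd

from . import kinetics, pressure as pressure_mod, therapy as therapy_mod
from .errors import ConfigError, InvariantViolation
from .fields import Grid, ScalarField, VectorField, step_field
from .kinetics import KineticParams, endothelial_density
from .pressure import PressureParams
from .therapy import DoseSchedule, DrugParams, binding
from .tumour import QUIESCENT, TumourCellPopulation, TumourParams
from .vasculature import (
    SproutParams,
    VesselNetwork,
    extension_cycle,
    generate_initial_vasculature,
    instability_condition,
    regression_probability,
    total_new_length,
)

__all__ = ["SimulationConfig", "SimulationState", "RunRecord",
           "initialize", "step", "run", "default_tumour_seeds"]


def default_tumour_seeds(points_per_axis: int) -> tuple:
    """Five cells near the centre: the centre point plus its four axial
    neighbours in the central z-plane."""
    m = points_per_axis // 2
    return ((m, m, m), (m - 1, m, m), (m + 1, m, m), (m, m - 1, m), (m, m + 1, m))


@dataclass(frozen=True)
class SimulationConfig:
    """Full declarative description of one run."""

    points_per_axis: int = 32
    domain_edge: float = 1.0          # cm
    steps_per_day: int = 33
    total_days: float = 60.0

    pressure: PressureParams = dc_field(default_factory=PressureParams)
    kinetics: KineticParams = dc_field(default_factory=KineticParams)
    tumour: TumourParams = dc_field(default_factory=TumourParams)
    sprout: SproutParams = dc_field(default_factory=SproutParams)
    drug: DrugParams = dc_field(default_factory=DrugParams)
    schedule: DoseSchedule | None = None

    tumour_seeds: tuple | None = None          # None -> default 5 near centre
    vasculature: Any = None                    # fixture spec dict; None -> default

    angiopoietin_enabled: bool = True
    regression_enabled: bool = True
    vegf_source: str = "all_tumour"            # or "quiescent_only"
    ang2_source: str = "tec_and_candidates"    # or "tec_only"
    darcy_mobility: float = 0.1                # grid-step^2 / (mmHg * day)
    allow_unstable: bool = False

    record_every: int = 1                      # steps between record rows
    invariant_check_every: int = 33            # steps; 0 disables

    def __post_init__(self) -> None:
        if self.total_days < 0:
            raise ConfigError("total_days: must be >= 0")
        if self.steps_per_day < 1:
            raise ConfigError("steps_per_day: must be >= 1")
        if self.points_per_axis < 3:
            raise ConfigError("points_per_axis: must be >= 3")
        if self.vegf_source not in ("all_tumour", "quiescent_only"):
            raise ConfigError(f"vegf_source: unknown value {self.vegf_source!r}")
        if self.ang2_source not in ("tec_and_candidates", "tec_only"):
            raise ConfigError(f"ang2_source: unknown value {self.ang2_source!r}")
        if self.darcy_mobility < 0:
            raise ConfigError("darcy_mobility: must be >= 0")

    @property
    def grid(self) -> Grid:
        return Grid(self.points_per_axis, self.domain_edge,
                    1.0 / self.steps_per_day)

    @property
    def n_steps(self) -> int:
        return int(round(self.total_days * self.steps_per_day))

    def seeds_or_default(self) -> tuple:
        if self.tumour_seeds is not None:
            return tuple(tuple(int(i) for i in s) for s in self.tumour_seeds)
        return default_tumour_seeds(self.points_per_axis)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        blocks = {"pressure": PressureParams, "kinetics": KineticParams,
                  "tumour": TumourParams, "sprout": SproutParams,
                  "drug": DrugParams}
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in blocks and isinstance(val, dict):
                kwargs[key] = blocks[key](**val)
            elif key == "schedule" and isinstance(val, dict):
                windows = tuple(tuple(wi) for wi in val.get("windows", ()))
                kwargs[key] = DoseSchedule(windows, val.get("pattern", "continuous"),
                                           val.get("dose_rate", 0.0))
            elif key == "tumour_seeds" and val is not None:
                kwargs[key] = tuple(tuple(s) for s in val)
            else:
                kwargs[key] = val
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class RunRecord:
    """Per-step metric time series plus the provenance of the run."""

    frame: pd.DataFrame
    config: dict
    seed: int | None = None

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class SimulationState:
    """All mutable containers of one running simulation."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.grid = config.grid
        self.rng = rng
        self.step_index = 0
        shape = self.grid.shape

        self.n = ScalarField.full("n", self.grid, 1.0)
        self.w = ScalarField.full("w", self.grid, 0.0)
        self.c = ScalarField.full("c", self.grid, 0.0)
        self.a1 = ScalarField.full("a1", self.grid, 1.0)
        self.a2 = ScalarField.full("a2", self.grid, 0.0)
        self.d = ScalarField.full("d", self.grid, 0.0)

        self.pop = TumourCellPopulation(shape, config.tumour)
        self.network = VesselNetwork(shape)

        # distance (grid steps) from the initial tumour centroid; l_max is
        # the distance to the farthest domain corner
        self.l_grid = np.zeros(shape)
        self.l_max = 1.0

        self.records: list[dict] = []
        # scratch diagnostics refreshed every step
        self.p = np.zeros(shape)
        self.W = np.zeros(shape)

    @property
    def day(self) -> float:
        return self.step_index * self.grid.dt

    def fields(self) -> dict[str, ScalarField]:
        return {f.name: f for f in (self.n, self.w, self.c, self.a1, self.a2, self.d)}


def _distance_grid(shape, centroid) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    return np.sqrt(sum((idx[i] - centroid[i]) ** 2 for i in range(3)))


def initialize(config: SimulationConfig,
               rng: np.random.Generator | None = None) -> SimulationState:
    """Build the initial state: n=1 and a1=1 everywhere, all other fields 0,
    tumour seeds placed, pre-existing vasculature generated."""
    rng = rng if rng is not None else np.random.default_rng(0)
    state = SimulationState(config, rng)
    n_axis = config.points_per_axis

    seeds = config.seeds_or_default()
    for s in seeds:
        if len(s) != 3 or any(not (0 <= v < n_axis) for v in s):
            raise ConfigError(f"tumour_seeds: seed {s} outside the grid")
    state.pop.seed(seeds)

    state.network = generate_initial_vasculature(
        config.vasculature, state.grid, rng, tumour_seeds=seeds)

    centroid = np.mean(np.array(seeds, dtype=float), axis=0) if seeds else \
        np.array([n_axis / 2.0] * 3)
    state.l_grid = _distance_grid(state.grid.shape, centroid)
    corners = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
                        [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]) * (n_axis - 1)
    state.l_max = float(max(np.linalg.norm(corner - centroid) for corner in corners))

    _record(state)
    return state


def _branch_ang_ratio(state: SimulationState) -> float:
    from .metrics import branch_ang_ratio
    return branch_ang_ratio(state.network, state.a1.values, state.a2.values)


def _record(state: SimulationState) -> None:
    census = state.pop.census()
    state.records.append({
        "step": state.step_index,
        "day": state.day,
        "length_mm": total_new_length(state.network, state.grid),
        "n_new_nodes": state.network.n_new(),
        "n_tec": len(state.network.positions(tec=True)),
        "n_candidates": len(state.network.positions(candidate=True)),
        "active": census["active"],
        "quiescent": census["quiescent"],
        "necrotic": census["necrotic"],
        "alive": census["alive"],
        "branch_ang_ratio": _branch_ang_ratio(state),
    })


def _check_invariants(state: SimulationState) -> None:
    overlap = state.pop.occupied & state.network.occupancy
    if overlap.any():
        where = tuple(int(i) for i in np.argwhere(overlap)[0])
        raise InvariantViolation(f"tumour and vessel both occupy {where}")
    tecs = sum(1 for node in state.network.nodes.values() if node.is_tec)
    if tecs != len(state.network.positions(tec=True)):
        raise InvariantViolation("TEC bookkeeping out of sync")


def step(state: SimulationState) -> SimulationState:
    cfg = state.config
    grid = state.grid
    dt = grid.dt
    h2 = grid.spacing ** 2
    kp = cfg.kinetics
    net = state.network
    pop = state.pop
    rng = state.rng
    now = state.day

    occ_T = pop.occupied
    occ_V = net.occupancy
    alive = pop.alive

    # (1) pressure, convection velocity and wall factor
    ctp = pressure_mod.compute_ctp(occ_T, cfg.pressure)
    vtp = pressure_mod.compute_vtp(occ_V, cfg.pressure)
    p = pressure_mod.total_pressure(ctp, vtp)
    W = pressure_mod.wall_gradient_W(cfg.pressure.pV, p)
    state.p, state.W = p, W
    if cfg.darcy_mobility > 0.0:
        gradp = pressure_mod.pressure_gradient(p, grid)
        # velocity in cm/day: mobility (step^2/(mmHg day)) * grad (mmHg/step)
        u = VectorField(-cfg.darcy_mobility * gradp.components * grid.spacing)
    else:
        u = None

    # (2) chemical fields, all sources from the pre-step snapshot
    R = net.radius_map(now, kp.k_AR1, kp.k_AR2)
    RW = R * W
    A_map = np.where(alive, pop.A, 0.0)
    n_pre = state.n.values.copy()
    c_pre = state.c.values.copy()
    d_pre = state.d.values.copy()

    therapy_on = cfg.schedule is not None and not cfg.schedule.empty
    B = binding(d_pre, c_pre) if therapy_on else 0.0

    step_field(state.n, kp.D_n * h2,
               kinetics.oxygen_secretion(R, W, kp),
               kinetics.oxygen_consumption(A_map, kp),
               u, grid, cfg.allow_unstable)
    kinetics.step_co2(state.w, u, kinetics.co2_secretion(n_pre, kp) * alive,
                      RW, kp, grid, D_physical=kp.D_w * h2,
                      allow_unstable=cfg.allow_unstable)

    if cfg.vegf_source == "quiescent_only":
        vegf_occ = pop.state == QUIESCENT
    else:
        vegf_occ = alive
    tec_only_occ = net.tec_occupancy(include_candidates=False)
    c_source = kinetics.vegf_secretion(n_pre, kp) * vegf_occ
    c_sink = kinetics.vegf_consumption(R, kp) * tec_only_occ + B
    step_field(state.c, kp.D_c * h2, c_source, c_sink, u, grid,
               cfg.allow_unstable)

    if cfg.angiopoietin_enabled:
        ec_occ = net.ec_occupancy()
        ang2_occ = net.tec_occupancy(
            include_candidates=(cfg.ang2_source == "tec_and_candidates"))
        theta_ec = endothelial_density(ec_occ, cfg.pressure.k_neigh)
        theta_tec = endothelial_density(ang2_occ, cfg.pressure.k_neigh)
        a1_sec, a1_con = kinetics.ang1_rates(theta_ec, state.a1.values, kp)
        step_field(state.a1, kp.D_a1 * h2, a1_sec * ec_occ, a1_con * ec_occ,
                   u, grid, cfg.allow_unstable)
        a2_sec, a2_con = kinetics.ang2_rates(theta_tec, state.a2.values, kp)
        step_field(state.a2, kp.D_a2 * h2, a2_sec * ang2_occ, a2_con * occ_V,
                   u, grid, cfg.allow_unstable)

    if therapy_on:
        therapy_mod.step_drug(state.d, u, RW, B, cfg.schedule, cfg.drug,
                              grid, now, D_physical=cfg.drug.D_d * h2,
                              allow_unstable=cfg.allow_unstable)

    # (3) angiogenesis: candidates -> sprouts -> extension -> regression
    blocked = occ_T | net.occupancy
    cv = state.c.values
    net.mark_candidates(cv, state.l_grid, state.l_max, blocked, rng, cfg.sprout)

    for pos in net.positions(candidate=True):
        if cfg.angiopoietin_enabled and not bool(instability_condition(
                state.a1.values[pos], state.a2.values[pos], cfg.sprout.h)):
            continue
        target = net.sprout(pos, cv, blocked, rng, now)
        if target is not None:
            blocked[target] = True

    for pos in net.positions(tec=True):
        node = net.nodes.get(pos)
        if node is None or not node.is_tec:
            continue
        node.ext_elapsed += dt
        tau = extension_cycle(cfg.pressure.pV - p[pos], cfg.sprout)
        if node.ext_elapsed >= tau:
            target = net.extend_tec(pos, cv, blocked, rng,
                                    c_min=cfg.sprout.c_ext_min)
            if target is not None:
                blocked[target] = True

    if cfg.regression_enabled and cfg.angiopoietin_enabled:
        for pos in net.positions(tec=True):
            node = net.nodes.get(pos)
            if node is None or not node.is_tec:
                continue
            if net.sprout_age(node, now) <= cfg.sprout.regression_min_age:
                continue
            anchor = net.sprout_anchor.get(node.sprout_id, pos)
            if not bool(instability_condition(
                    state.a1.values[anchor], state.a2.values[anchor],
                    cfg.sprout.h)):
                continue
            p_rg = regression_probability(cv[pos], state.l_grid[pos],
                                          cfg.sprout, state.l_max)
            if rng.random() < p_rg:
                net.regress_branch(pos)

    # (4) tumour agents
    pop.update_states(state.n.values, state.w.values)
    pop.update_cve(dt)
    pop.attempt_divisions(p, net.occupancy, rng)

    # (5) clock, metrics, invariants
    state.step_index += 1
    if cfg.record_every and state.step_index % cfg.record_every == 0:
        _record(state)
    if cfg.invariant_check_every and \
            state.step_index % cfg.invariant_check_every == 0:
        _check_invariants(state)
    return state


def run(config: SimulationConfig, seed: int | None = None,
        state_out: list | None = None) -> RunRecord:
    """Run a full simulation and return its RunRecord.

    ``state_out``, if given, receives the final SimulationState (appended),
    for callers that want the raw containers as well as the record.
    """
    rng = np.random.default_rng(seed)
    state = initialize(config, rng)
    for _ in range(config.n_steps):
        step(state)
    if state_out is not None:
        state_out.append(state)
    return RunRecord(pd.DataFrame(state.records), config.to_dict(), seed)
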