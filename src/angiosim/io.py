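"""Snapshots, checkpoints and tabular export.

Snapshots store the six chemical fields, the pressure, the tumour arrays
and a node table of the vessel network in one HDF5 file.  Checkpoints add
the RNG state and step counter and restore bit-exactly: a run checkpointed
at a day boundary and resumed reproduces the uninterrupted trajectory.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .engine import SimulationConfig, SimulationState
from .vasculature import VesselNetwork, VesselNode

__all__ = ["save_snapshot", "save_checkpoint", "load_checkpoint",
           "network_tables", "population_table"]


def network_tables(network: VesselNetwork) -> pd.DataFrame:
    """Vessel nodes as a flat table (x, y, z, kind, flags, sprout, parent)."""
    rows = []
    for pos in sorted(network.nodes):
        node = network.nodes[pos]
        parent = node.parent if node.parent is not None else (-1, -1, -1)
        rows.append({
            "x": pos[0], "y": pos[1], "z": pos[2],
            "kind": node.kind, "is_tec": node.is_tec,
            "is_candidate": node.is_candidate,
            "is_ang2_source": node.is_ang2_source, "sprout_id": node.sprout_id,
            "parent_x": parent[0], "parent_y": parent[1], "parent_z": parent[2],
            "ext_elapsed": node.ext_elapsed,
        })
    columns = ["x", "y", "z", "kind", "is_tec", "is_candidate",
               "is_ang2_source", "sprout_id",
               "parent_x", "parent_y", "parent_z", "ext_elapsed"]
    return pd.DataFrame(rows, columns=columns)


def population_table(state: SimulationState) -> pd.DataFrame:
    """Tumour cells as a flat table (x, y, z, state, A_i, V_i)."""
    pos = np.argwhere(state.pop.state != 0)
    return pd.DataFrame({
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "state": state.pop.state[pos[:, 0], pos[:, 1], pos[:, 2]],
        "A_i": state.pop.A[pos[:, 0], pos[:, 1], pos[:, 2]],
        "V_i": state.pop.V[pos[:, 0], pos[:, 1], pos[:, 2]],
    })


def _write_network(h5: h5py.Group, network: VesselNetwork) -> None:
    table = network_tables(network)
    grp = h5.create_group("network")
    for col in table.columns:
        data = table[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        grp.create_dataset(col, data=data)
    sids = sorted(network.sprout_birth)
    grp.create_dataset("sprout_ids", data=np.array(sids, dtype=np.int64))
    grp.create_dataset("sprout_birth",
                       data=np.array([network.sprout_birth[s] for s in sids]))
    anchors = np.array([network.sprout_anchor.get(s, (-1, -1, -1))
                        for s in sids], dtype=np.int64).reshape(len(sids), 3)
    grp.create_dataset("sprout_anchor", data=anchors)
    grp.attrs["next_sprout_id"] = network._next_sprout_id


def _read_network(h5: h5py.Group, shape) -> VesselNetwork:
    grp = h5["network"]
    net = VesselNetwork(tuple(shape))
    kinds = [k.decode() for k in grp["kind"][()]]
    xs, ys, zs = grp["x"][()], grp["y"][()], grp["z"][()]
    px, py, pz = grp["parent_x"][()], grp["parent_y"][()], grp["parent_z"][()]
    for i in range(len(xs)):
        parent = (int(px[i]), int(py[i]), int(pz[i]))
        node = VesselNode(
            position=(int(xs[i]), int(ys[i]), int(zs[i])),
            kind=kinds[i],
            is_tec=bool(grp["is_tec"][i]),
            is_candidate=bool(grp["is_candidate"][i]),
            is_ang2_source=bool(grp["is_ang2_source"][i]),
            sprout_id=int(grp["sprout_id"][i]),
            parent=None if parent == (-1, -1, -1) else parent,
            ext_elapsed=float(grp["ext_elapsed"][i]),
        )
        net.add_node(node)
    anchors = grp["sprout_anchor"][()] if "sprout_anchor" in grp else None
    for i, (sid, birth) in enumerate(zip(grp["sprout_ids"][()],
                                         grp["sprout_birth"][()])):
        net.sprout_birth[int(sid)] = float(birth)
        if anchors is not None and tuple(anchors[i]) != (-1, -1, -1):
            net.sprout_anchor[int(sid)] = tuple(int(v) for v in anchors[i])
    net._next_sprout_id = int(grp.attrs["next_sprout_id"])
    return net


def save_snapshot(state: SimulationState, path) -> None:
    """Write fields, tumour arrays and the vessel node table to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.attrs["day"] = state.day
        h5.attrs["step_index"] = state.step_index
        for name, field in state.fields().items():
            ds = h5.create_dataset(f"fields/{name}", data=field.values)
            ds.attrs["boundary_value"] = field.boundary_value
        h5.create_dataset("pressure", data=state.p)
        h5.create_dataset("tumour/state", data=state.pop.state)
        h5.create_dataset("tumour/A", data=state.pop.A)
        h5.create_dataset("tumour/V", data=state.pop.V)
        _write_network(h5, state.network)


def save_checkpoint(state: SimulationState, path) -> None:
    """Snapshot plus RNG state and config: exact resume point."""
    save_snapshot(state, path)
    with h5py.File(path, "a") as h5:
        h5.attrs["config"] = json.dumps(state.config.to_dict())
        h5.attrs["rng_state"] = json.dumps(
            state.rng.bit_generator.state,
            default=int,
        )


def load_checkpoint(path) -> SimulationState:
    """Rebuild a SimulationState that resumes bit-exactly."""
    from .engine import initialize

    with h5py.File(path, "r") as h5:
        config = SimulationConfig.from_dict(json.loads(h5.attrs["config"]))
        state = initialize(config, np.random.default_rng(0))
        state.records.clear()
        state.step_index = int(h5.attrs["step_index"])
        for name, field in state.fields().items():
            field.values[...] = h5[f"fields/{name}"][()]
        state.p = h5["pressure"][()]
        state.pop.state[...] = h5["tumour/state"][()]
        state.pop.A[...] = h5["tumour/A"][()]
        state.pop.V[...] = h5["tumour/V"][()]
        state.network = _read_network(h5, config.grid.shape)
        rng_state = json.loads(h5.attrs["rng_state"])
        state.rng.bit_generator.state = rng_state
    return state
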