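"""Persistence: HDF5 containers for networks and results, text exports."""

from __future__ import annotations

import json

import h5py
import numpy as np
import scipy.io
import scipy.sparse as sp

from .engine import SimulationResult
from .network import BLOCKS, Connectivity, Network, NetworkConfig, PopulationSpec

__all__ = [
    "save_network",
    "load_network",
    "save_result",
    "load_result",
    "export_spikes_text",
    "export_block_mtx",
]


def save_network(net: Network, path) -> None:
    """Write population table, per-block edge lists and config to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(net.config.to_dict())
        pops = f.create_group("populations")
        for name, spec in net.populations.items():
            g = pops.create_group(name)
            g.attrs["size"] = spec.size
            g.attrs["model_kind"] = spec.model_kind
            g.attrs["cell_class"] = spec.cell_class
        edges = f.create_group("edges")
        for (src, tgt), block in net.blocks.items():
            coo = block.adjacency.tocoo()
            g = edges.create_group(f"{src}__{tgt}")
            g.create_dataset("source", data=coo.row.astype(np.int32))
            g.create_dataset("target", data=coo.col.astype(np.int32))
            g.attrs["p"] = block.p
            g.attrs["n_source"] = block.n_source
            g.attrs["n_target"] = block.n_target


def load_network(path) -> Network:
    with h5py.File(path, "r") as f:
        cfg = NetworkConfig(**json.loads(f.attrs["config"]))
        pops = {}
        for name, g in f["populations"].items():
            pops[name] = PopulationSpec(
                name=name, size=int(g.attrs["size"]),
                model_kind=str(g.attrs["model_kind"]),
                cell_class=str(g.attrs["cell_class"]),
            )
        blocks = {}
        for (src, tgt) in BLOCKS:
            g = f["edges"][f"{src}__{tgt}"]
            shape = (int(g.attrs["n_source"]), int(g.attrs["n_target"]))
            row = g["source"][:]
            col = g["target"][:]
            adj = sp.csr_matrix(
                (np.ones(row.size, dtype=np.int8), (row, col)), shape=shape)
            blocks[(src, tgt)] = Connectivity(
                source=src, target=tgt, p=float(g.attrs["p"]),
                adjacency=adj, seed=cfg.connectivity_seed)
    return Network(config=cfg, populations=pops, blocks=blocks)


def save_result(result: SimulationResult, path) -> None:
    """Persist spikes, sampled potentials, drive trace and config echo."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(result.config_echo)
        f.attrs["duration"] = result.duration
        f.attrs["dt"] = result.dt
        sg = f.create_group("spikes")
        for pop, (ids, times) in result.spikes.items():
            g = sg.create_group(pop)
            g.create_dataset("id", data=ids)
            g.create_dataset("t", data=times)
        vg = f.create_group("vm")
        vg.create_dataset("t", data=result.vm_times)
        for pop, arr in result.vm.items():
            vg.create_dataset(pop, data=arr)
        dg = f.create_group("drive")
        dg.create_dataset("t", data=result.drive_times)
        dg.create_dataset("rate", data=result.drive_rate)


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        spikes = {pop: (g["id"][:], g["t"][:]) for pop, g in f["spikes"].items()}
        vm = {pop: d[:] for pop, d in f["vm"].items() if pop != "t"}
        return SimulationResult(
            spikes=spikes,
            vm=vm,
            vm_times=f["vm"]["t"][:],
            drive_times=f["drive"]["t"][:],
            drive_rate=f["drive"]["rate"][:],
            duration=float(f.attrs["duration"]),
            dt=float(f.attrs["dt"]),
            config_echo=json.loads(f.attrs["config"]),
        )


def export_spikes_text(result: SimulationResult, path) -> None:
    """Two-column plain-text spike list: time_ms neuron_global_id.

    Global ids: RS first, then FS, then EXT.
    """
    n_rs = result.config_echo["populations"]["RS"]
    n_fs = result.config_echo["populations"]["FS"]
    offsets = {"RS": 0, "FS": n_rs, "EXT": n_rs + n_fs}
    rows = []
    for pop, (ids, times) in result.spikes.items():
        if ids.size:
            rows.append(np.column_stack([times, ids + offsets[pop]]))
    data = np.vstack(rows) if rows else np.empty((0, 2))
    data = data[np.argsort(data[:, 0], kind="stable")]
    np.savetxt(path, data, fmt="%.3f %d")


def export_block_mtx(net: Network, source: str, target: str, path) -> None:
    """Matrix Market export of one connectivity block (interoperability)."""
    scipy.io.mmwrite(path, net.block(source, target).adjacency.tocoo())
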