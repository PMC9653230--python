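"""Snapshot and table I/O.

Runs are stored in HDF5: one group per snapshot holding a rod table
(id, x, y, phi, l_rest, l, gamma), a contact table (id_k, id_l, dx, dy,
Fx, Fy) and a scalar time; the file attributes carry the full resolved
configuration.  A CSV export of the rod table is provided for
interoperability, and run configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import RunConfig, RunResult, Snapshot

__all__ = ["write_run", "read_run", "snapshot_to_frame", "export_csv",
           "load_config", "save_config"]

_ROD_COLS = ("id", "x", "y", "phi", "l_rest", "l", "gamma")


def write_run(result: RunResult, path) -> None:
    with h5py.File(path, "w") as f:
        for key, val in asdict(result.config).items():
            f.attrs[key] = val
        f.attrs["n_halvings"] = result.n_halvings
        f.attrs["max_overlap"] = result.max_overlap
        for k, snap in enumerate(result.snapshots):
            grp = f.create_group(f"snapshot_{k:05d}")
            grp.attrs["time"] = snap.time
            rods = np.column_stack([snap.ids, snap.x, snap.y, snap.phi,
                                    snap.l_rest, snap.l, snap.gamma])
            grp.create_dataset("rods", data=rods)
            contacts = np.column_stack([
                snap.ids[snap.c_i], snap.ids[snap.c_j],
                snap.c_dx, snap.c_dy, snap.c_fx, snap.c_fy])
            grp.create_dataset("contacts", data=contacts)
            # raw indices let readers rebuild r_kl without an id lookup
            grp.create_dataset("contact_index",
                               data=np.column_stack([snap.c_i, snap.c_j]))


def read_run(path) -> RunResult:
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        n_halvings = int(attrs.pop("n_halvings", 0))
        max_overlap = float(attrs.pop("max_overlap", 0.0))
        cfg_fields = set(RunConfig.__dataclass_fields__)
        cfg_kwargs = {}
        for k, v in attrs.items():
            if k not in cfg_fields:
                continue
            if k in ("geometry",):
                cfg_kwargs[k] = str(v)
            elif k == "gamma_range":
                cfg_kwargs[k] = tuple(np.asarray(v, dtype=float))
            elif k in ("seed", "n_initial"):
                cfg_kwargs[k] = int(v)
            else:
                cfg_kwargs[k] = float(v)
        config = RunConfig(**cfg_kwargs)
        snaps = []
        for key in sorted(f.keys()):
            grp = f[key]
            rods = grp["rods"][()]
            contacts = grp["contacts"][()]
            idx = grp["contact_index"][()]
            snaps.append(Snapshot(
                time=float(grp.attrs["time"]),
                ids=rods[:, 0].astype(np.int64),
                x=rods[:, 1], y=rods[:, 2], phi=rods[:, 3],
                l_rest=rods[:, 4], l=rods[:, 5], gamma=rods[:, 6],
                c_i=idx[:, 0].astype(np.int64),
                c_j=idx[:, 1].astype(np.int64),
                c_dx=contacts[:, 2], c_dy=contacts[:, 3],
                c_fx=contacts[:, 4], c_fy=contacts[:, 5]))
    return RunResult(config=config, snapshots=snaps,
                     n_halvings=n_halvings, max_overlap=max_overlap)


def snapshot_to_frame(snap: Snapshot) -> pd.DataFrame:
    return pd.DataFrame({
        "id": snap.ids, "x": snap.x, "y": snap.y, "phi": snap.phi,
        "l_rest": snap.l_rest, "l": snap.l, "gamma": snap.gamma})


def export_csv(result: RunResult, path) -> None:
    """Rod tables of all snapshots, stacked with a time column."""
    frames = []
    for snap in result.snapshots:
        df = snapshot_to_frame(snap)
        df.insert(0, "time", snap.time)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "gamma_range" in raw:
        raw["gamma_range"] = tuple(raw["gamma_range"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = asdict(config)
    data["gamma_range"] = list(data["gamma_range"])
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)
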