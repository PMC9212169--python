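"""Trajectory/event persistence and run manifests.

Two interchangeable on-disk forms: CSV (one row per sample / per event,
metadata embedded as a JSON comment header) for interchange, and an HDF5
container for ensembles.  Both are lossless for every recorded field,
including seeds and the full configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import pandas as pd

from .engine import TrajectoryRecord, EventLog

__all__ = [
    "FORMAT_VERSION",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_events_csv",
    "read_events_csv",
    "write_ensemble_h5",
    "read_ensemble_h5",
    "RunManifest",
    "write_manifest",
    "read_manifest",
]

FORMAT_VERSION = 1


def _meta_header(meta: dict) -> str:
    return "# fluidcargo-meta " + json.dumps(
        {"format_version": FORMAT_VERSION, **meta}
    )


def _read_meta_header(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# fluidcargo-meta "):
        raise ValueError(f"{path}: not a fluidcargo CSV (missing meta header)")
    meta = json.loads(first[len("# fluidcargo-meta "):])
    version = meta.pop("format_version", None)
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path}: format version {version} != supported {FORMAT_VERSION}"
        )
    return meta


def trajectory_to_frame(traj: TrajectoryRecord) -> pd.DataFrame:
    """Flatten a trajectory to one row per sample."""
    N = traj.bound.shape[1]
    cols = {"t": traj.t, "x": traj.X[:, 0], "y": traj.X[:, 1],
            "z": traj.X[:, 2], "n_bound": traj.n_bound}
    for i in range(N):
        cols[f"bound_{i}"] = traj.bound[:, i].astype(int)
        cols[f"head_x_{i}"] = traj.head_x[:, i]
        if traj.anchors is not None:
            for c, ax in enumerate("xyz"):
                cols[f"anchor_{ax}_{i}"] = traj.anchors[:, i, c]
        if traj.forces is not None:
            for c, ax in enumerate("xyz"):
                cols[f"force_{ax}_{i}"] = traj.forces[:, i, c]
    if traj.orientation is not None:
        for a in range(3):
            for b in range(3):
                cols[f"orient_{a}{b}"] = traj.orientation[:, a, b]
    return pd.DataFrame(cols)


def write_trajectory_csv(traj: TrajectoryRecord, path) -> None:
    frame = trajectory_to_frame(traj)
    with open(path, "w") as fh:
        fh.write(_meta_header(traj.meta) + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_trajectory_csv(path) -> TrajectoryRecord:
    meta = _read_meta_header(path)
    frame = pd.read_csv(path, comment="#")
    if frame.empty and "t" not in frame.columns:
        raise ValueError(f"{path}: truncated or empty trajectory file")
    N = sum(1 for c in frame.columns if c.startswith("bound_"))
    bound = np.column_stack([frame[f"bound_{i}"] for i in range(N)]).astype(bool)
    head_x = np.column_stack([frame[f"head_x_{i}"] for i in range(N)])
    anchors = forces = orientation = None
    if "anchor_x_0" in frame.columns:
        anchors = np.stack(
            [np.column_stack([frame[f"anchor_{ax}_{i}"] for ax in "xyz"])
             for i in range(N)], axis=1,
        )
    if "force_x_0" in frame.columns:
        forces = np.stack(
            [np.column_stack([frame[f"force_{ax}_{i}"] for ax in "xyz"])
             for i in range(N)], axis=1,
        )
    if "orient_00" in frame.columns:
        orientation = np.stack(
            [np.column_stack([frame[f"orient_{a}{b}"] for b in range(3)])
             for a in range(3)], axis=1,
        )
    return TrajectoryRecord(
        t=frame["t"].to_numpy(),
        X=frame[["x", "y", "z"]].to_numpy(),
        n_bound=frame["n_bound"].to_numpy(),
        bound=bound,
        head_x=head_x,
        anchors=anchors,
        forces=forces,
        orientation=orientation,
        meta=meta,
    )


def write_events_csv(events: EventLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(events.meta) + "\n")
        pd.DataFrame({"t": events.t, "motor": events.motor,
                      "kind": events.kind}).to_csv(
            fh, index=False, lineterminator="\n")


def read_events_csv(path) -> EventLog:
    meta = _read_meta_header(path)
    frame = pd.read_csv(path, comment="#")
    return EventLog(
        t=frame["t"].to_numpy(dtype=float),
        motor=frame["motor"].to_numpy(dtype=np.int32),
        kind=frame["kind"].to_numpy(dtype=np.int8),
        meta=meta,
    )


def write_ensemble_h5(runs, path) -> None:
    """Store [(TrajectoryRecord, EventLog), ...] in one HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["n_runs"] = len(runs)
        for k, (traj, events) in enumerate(runs):
            g = h5.create_group(f"run_{k:05d}")
            g.attrs["meta"] = json.dumps(traj.meta)
            g.create_dataset("t", data=traj.t)
            g.create_dataset("X", data=traj.X)
            g.create_dataset("n_bound", data=traj.n_bound)
            g.create_dataset("bound", data=traj.bound.astype(np.int8))
            g.create_dataset("head_x", data=traj.head_x)
            if traj.anchors is not None:
                g.create_dataset("anchors", data=traj.anchors)
            if traj.forces is not None:
                g.create_dataset("forces", data=traj.forces)
            if traj.orientation is not None:
                g.create_dataset("orientation", data=traj.orientation)
            g.create_dataset("ev_t", data=events.t)
            g.create_dataset("ev_motor", data=events.motor)
            g.create_dataset("ev_kind", data=events.kind)


def read_ensemble_h5(path) -> list[tuple[TrajectoryRecord, EventLog]]:
    runs = []
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"{path}: format version {version} != {FORMAT_VERSION}"
            )
        for k in range(int(h5.attrs["n_runs"])):
            g = h5[f"run_{k:05d}"]
            meta = json.loads(g.attrs["meta"])
            traj = TrajectoryRecord(
                t=g["t"][...],
                X=g["X"][...],
                n_bound=g["n_bound"][...],
                bound=g["bound"][...].astype(bool),
                head_x=g["head_x"][...],
                anchors=g["anchors"][...] if "anchors" in g else None,
                forces=g["forces"][...] if "forces" in g else None,
                orientation=(g["orientation"][...]
                             if "orientation" in g else None),
                meta=meta,
            )
            events = EventLog(
                t=g["ev_t"][...],
                motor=g["ev_motor"][...],
                kind=g["ev_kind"][...],
                meta=meta,
            )
            runs.append((traj, events))
    return runs


@dataclass
class RunManifest:
    """Everything needed to reproduce a command's outputs exactly."""

    command: str
    config: dict
    master_seed: int
    child_seeds: list
    outputs: list
    package_version: str
    created_unix: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def write_manifest(path, command: str, config: dict, master_seed: int,
                   child_seeds, outputs) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config,
        master_seed=int(master_seed),
        child_seeds=[int(s) for s in child_seeds],
        outputs=[str(o) for o in outputs],
        package_version=__version__,
        created_unix=time.time(),
    )
    with open(path, "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def read_manifest(path) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))
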