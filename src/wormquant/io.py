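"""Columnar readers and writers for trajectories, sessions and counts.

Trajectories and fluorescence sessions travel as tidy CSV (one row per
frame) or HDF5; count matrices as gene x sample TSV with a sample-metadata
TSV; ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .locomotion import Trajectory
from .simulate import CountMatrix, SimTruth

__all__ = [
    "trajectory_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_truth_json",
]

_COORD_COLS = [
    "head_x", "head_y", "tail_x", "tail_y", "centroid_x", "centroid_y",
]


def trajectory_frame(
    traj: Trajectory,
    gcamp: np.ndarray | None = None,
    rfp: np.ndarray | None = None,
    laser_on: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per frame: frame, t_s, coordinates, optional channels/epochs."""
    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "t_s": traj.t_s,
            "head_x": traj.head[:, 0],
            "head_y": traj.head[:, 1],
            "tail_x": traj.tail[:, 0],
            "tail_y": traj.tail[:, 1],
            "centroid_x": traj.centroid[:, 0],
            "centroid_y": traj.centroid[:, 1],
        }
    )
    if gcamp is not None:
        df["gcamp"] = gcamp
    if rfp is not None:
        df["rfp"] = rfp
    if laser_on is not None:
        df["laser_on"] = np.asarray(laser_on).astype(int)
    return df


def write_trajectory_csv(path: str | Path, traj: Trajectory, **channels) -> None:
    trajectory_frame(traj, **channels).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, fps: float) -> tuple[Trajectory, pd.DataFrame]:
    """Read a per-frame CSV back into a Trajectory plus the full frame table."""
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file lacks column(s): {missing}")
    traj = Trajectory(
        fps=fps,
        head=df[["head_x", "head_y"]].to_numpy(),
        tail=df[["tail_x", "tail_y"]].to_numpy(),
        centroid=df[["centroid_x", "centroid_y"]].to_numpy(),
    )
    return traj, df


def write_trajectory_h5(path: str | Path, traj: Trajectory, **channels) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fps"] = traj.fps
        f.create_dataset("head", data=traj.head)
        f.create_dataset("tail", data=traj.tail)
        f.create_dataset("centroid", data=traj.centroid)
        if traj.midline is not None:
            f.create_dataset("midline", data=traj.midline)
        for name, data in channels.items():
            if data is not None:
                f.create_dataset(name, data=np.asarray(data))


def read_trajectory_h5(path: str | Path) -> tuple[Trajectory, dict]:
    with h5py.File(path, "r") as f:
        traj = Trajectory(
            fps=float(f.attrs["fps"]),
            head=f["head"][...],
            tail=f["tail"][...],
            centroid=f["centroid"][...],
            midline=f["midline"][...] if "midline" in f else None,
        )
        extra = {
            k: f[k][...]
            for k in f
            if k not in ("head", "tail", "centroid", "midline")
        }
    return traj, extra


def write_counts_tsv(
    prefix: str | Path, cm: CountMatrix
) -> tuple[Path, Path]:
    """Write ``<prefix>.counts.tsv`` (gene x sample) and ``<prefix>.meta.tsv``."""
    prefix = Path(prefix)
    counts_path = prefix.with_suffix(".counts.tsv")
    meta_path = prefix.with_suffix(".meta.tsv")
    cm.counts.to_csv(counts_path, sep="\t")
    cm.meta.to_csv(meta_path, sep="\t")
    return counts_path, meta_path


def read_counts_tsv(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, meta=meta)


def write_truth_json(path: str | Path, truth: SimTruth) -> None:
    """Ground-truth sidecar; arrays become lists, None fields are dropped."""
    doc = {}
    for k, v in vars(truth).items():
        if v is None:
            continue
        if isinstance(v, np.ndarray):
            doc[k] = v.tolist()
        elif isinstance(v, list):
            doc[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        else:
            doc[k] = v
    Path(path).write_text(json.dumps(doc) + "\n")
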