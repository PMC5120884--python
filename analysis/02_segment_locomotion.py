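#!/usr/bin/env python
"""Segment the two locomotion cohorts and compare their motility metrics.

For ten control and ten neuron-loss animals the trajectories are reduced
to signed body-axis velocity, segmented into forward/reversal/pause bouts,
and summarised by the four behavioural metrics (time fraction, initiation
frequency, bout duration, bout velocity).  Cohorts are compared per metric
with the two-sided Mann-Whitney U test.  Writes
results/locomotion_metrics.tsv and results/locomotion_stats.json, plus a
curvature kymogram figure for a synthetic crawler.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from wormquant import simulate as sim
from wormquant.locomotion import (
    SegmentationConfig,
    Trajectory,
    body_axis_velocity,
    bout_metrics,
    curvature_kymogram,
    segment_states,
)
from wormquant.stats import compare_groups

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
N_ANIMALS = 10


def cohort_metrics(make, label):
    cfg = SegmentationConfig()
    rows = []
    for k in range(N_ANIMALS):
        traj, _ = sim.simulate_trajectory(make(seed=k))
        seg = segment_states(body_axis_velocity(traj, cfg), traj.fps, cfg)
        m = bout_metrics(seg)
        rows.append(
            {
                "cohort": label,
                "animal": k,
                "fraction_F": m.fraction["F"],
                "fraction_R": m.fraction["R"],
                "fraction_P": m.fraction["P"],
                "init_F_per_min": m.initiations_per_min["F"],
                "init_R_per_min": m.initiations_per_min["R"],
                "dur_F_s": m.mean_duration_s["F"],
                "vel_F_um_s": m.mean_velocity["F"],
            }
        )
    return pd.DataFrame(rows)


def kymogram_figure(path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # sinusoidal traveling wave midline: stripes propagate at the wave speed
    n_frames, n_pts, fps = 300, 25, 10.0
    s = np.linspace(0, 1, n_pts)
    t = np.arange(n_frames) / fps
    midline = np.empty((n_frames, n_pts, 2))
    for i, ti in enumerate(t):
        midline[i, :, 0] = s * 1000.0
        midline[i, :, 1] = 50.0 * np.sin(2 * np.pi * (2 * s - 0.5 * ti))
    traj = Trajectory(
        fps=fps, head=midline[:, 0], tail=midline[:, -1],
        centroid=midline[:, n_pts // 2], midline=midline,
    )
    kym = curvature_kymogram(traj)
    fig, ax = plt.subplots(figsize=(7, 2.5))
    im = ax.imshow(kym, aspect="auto", cmap="RdBu_r",
                   extent=[0, t[-1], 1, 0])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body position (head to tail)")
    fig.colorbar(im, label="bending angle (rad)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df = pd.concat(
        [
            cohort_metrics(sim.LocomotionSimSpec, "control"),
            cohort_metrics(sim.rid_ablated_spec, "ablated"),
        ]
    )
    df.to_csv(RESULTS / "locomotion_metrics.tsv", sep="\t", index=False)

    stats = {}
    for metric in ("fraction_F", "init_F_per_min", "dur_F_s", "vel_F_um_s"):
        groups = {
            c: df.loc[df.cohort == c, metric].to_numpy()
            for c in ("control", "ablated")
        }
        out = compare_groups(groups, metric=metric)
        stats[metric] = {
            "control_mean": float(np.mean(groups["control"])),
            "ablated_mean": float(np.mean(groups["ablated"])),
            "test": out.test,
            "p": out.p,
        }
    (RESULTS / "locomotion_stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True) + "\n"
    )
    (RESULTS / "figures").mkdir(exist_ok=True)
    kymogram_figure(RESULTS / "figures" / "kymogram.png")

    f = stats["fraction_F"]
    print(
        f"forward time fraction: control {f['control_mean']:.3f} vs "
        f"neuron-loss {f['ablated_mean']:.3f} ({f['test']} p = {f['p']:.2e})"
    )
    d = stats["dur_F_s"]
    print(
        f"forward bout duration: {d['control_mean']:.1f} s vs "
        f"{d['ablated_mean']:.1f} s (p = {d['p']:.2e})"
    )
    print(f"wrote {RESULTS/'locomotion_metrics.tsv'} and locomotion_stats.json")


if __name__ == "__main__":
    main()
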