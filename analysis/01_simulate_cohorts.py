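#!/usr/bin/env python
"""Generate the synthetic study cohorts and write them as columnar files.

Four data kinds are produced under scratch/data/: free-crawling
trajectories for a control cohort and a cohort emulating loss of the
forward-sustaining neuron; pad-constrained calcium-imaging sessions
(trajectory + two fluorescence channels); optogenetic sessions with a
3-min on / 3-min off laser cycle; and the two-genotype sorted-cell count
design.  Every file has a ground-truth JSON sidecar.  Downstream drivers
re-simulate deterministically from the same presets, so this step is a
demonstration of the I/O layer rather than a dependency.
"""

from pathlib import Path

import numpy as np

from wormquant import io as wio
from wormquant import simulate as sim

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
N_ANIMALS = 10


def main() -> None:
    for cohort, make in (
        ("control", sim.LocomotionSimSpec),
        ("ablated", sim.rid_ablated_spec),
    ):
        d = OUT / cohort
        d.mkdir(parents=True, exist_ok=True)
        for k in range(N_ANIMALS):
            spec = make(seed=k) if make is sim.rid_ablated_spec else make(seed=k)
            traj, truth = sim.simulate_trajectory(spec)
            wio.write_trajectory_csv(d / f"animal{k:02d}.csv", traj)
            wio.write_truth_json(d / f"animal{k:02d}.truth.json", truth)
        print(f"{cohort}: {N_ANIMALS} tracked animals -> {d}")

    d = OUT / "calcium"
    d.mkdir(parents=True, exist_ok=True)
    for k in range(N_ANIMALS):
        traj, truth = sim.simulate_trajectory(sim.calcium_session_spec(seed=k))
        trace = sim.simulate_calcium_session(
            truth, sim.CalciumSimSpec(seed=1000 + k)
        )
        wio.write_trajectory_csv(
            d / f"session{k:02d}.csv", traj, gcamp=trace.gcamp, rfp=trace.rfp
        )
        wio.write_truth_json(d / f"session{k:02d}.truth.json", truth)
    print(f"calcium: {N_ANIMALS} two-channel sessions -> {d}")

    d = OUT / "opto"
    d.mkdir(parents=True, exist_ok=True)
    for k in range(5):
        spec = sim.LocomotionSimSpec(fps=30.0, duration_s=1800.0, seed=k)
        traj, laser, truth = sim.simulate_opto_session(
            spec, on_effect=(2.0, 1.5), seed=k, mean_run_s=20.0
        )
        wio.write_trajectory_csv(d / f"session{k:02d}.csv", traj, laser_on=laser)
        wio.write_truth_json(d / f"session{k:02d}.truth.json", truth)
    print(f"opto: 5 thirty-minute sessions (ON: runs x2, speed x1.5) -> {d}")

    d = OUT / "counts"
    d.mkdir(parents=True, exist_ok=True)
    cm, truth = sim.simulate_counts(sim.CountSimSpec(seed=0))
    wio.write_counts_tsv(d / "design", cm)
    wio.write_truth_json(d / "truth.json", truth)
    n_planted = len(truth.planted_genes)
    print(
        f"counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples, "
        f"{n_planted} planted target-specific genes -> {d}"
    )


if __name__ == "__main__":
    main()
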