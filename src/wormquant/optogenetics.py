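"""Run/turn segmentation and laser-epoch statistics for crawling assays.

Free-crawling trajectories recorded under an on/off stimulation cycle are
segmented into forward runs separated by sharp reorientations: a frame is a
turn when the centroid heading changes by more than a threshold (default
60 degrees) across a centred 1-s window.  Runs are binned by the laser
epoch of their start, and the phasic velocity change around ON switches is
quantified with a matched-pairs comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import paired_test

__all__ = [
    "OptoConfig",
    "Run",
    "RunTurnSegmentation",
    "compute_heading",
    "detect_turns",
    "segment_runs",
    "epoch_run_stats",
    "phasic_velocity_change",
    "circular_diff_deg",
]


@dataclass
class OptoConfig:
    """Turn criterion, epoch cycle and phasic-window parameters.

    ``turn_threshold_deg`` over ``turn_window_s`` is the turn criterion
    (default >60 degrees over a centred 1-s window).  ``epoch_period_s`` is
    the half-period of the stimulation cycle (default 3 min ON / 3 min OFF).
    ``phasic_window_s`` is the span of continuous forward movement required
    and averaged before and after a switch (default 10 s; 4 s for slow
    strains).  The centroid is box-smoothed over ``smooth_s`` seconds before
    heading computation; displacements below ``min_step_um`` leave the
    heading undefined.
    """

    turn_threshold_deg: float = 60.0
    turn_window_s: float = 1.0
    epoch_period_s: float = 180.0
    phasic_window_s: float = 10.0
    fps: float = 30.0
    smooth_s: float = 0.5
    min_step_um: float = 0.1

    def __post_init__(self) -> None:
        if self.turn_threshold_deg <= 0 or self.turn_window_s <= 0:
            raise ValueError("turn threshold and window must be positive")
        if self.epoch_period_s <= 0 or self.phasic_window_s <= 0:
            raise ValueError("epoch period and phasic window must be positive")


@dataclass
class Run:
    """A maximal turn-free interval: half-open frames, duration, path, speed."""

    start: int
    end: int
    duration_s: float
    path_length_um: float
    mean_speed_um_s: float
    laser_on: bool | None = None


@dataclass
class RunTurnSegmentation:
    """Headings, turn flags/intervals, runs and epoch labels of a session."""

    heading_deg: np.ndarray
    turn_flags: np.ndarray
    turn_intervals: list[tuple[int, int]]
    runs: list[Run]
    laser_on: np.ndarray | None = None
    fps: float = 30.0
    config: OptoConfig = field(default_factory=OptoConfig)


def circular_diff_deg(a: float | np.ndarray, b: float | np.ndarray):
    """Signed circular difference a - b mapped to (-180, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def _box_smooth_2d(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    out = np.empty_like(x, dtype=float)
    for c in range(x.shape[1]):
        padded = np.concatenate(
            [np.full(pad, x[0, c]), x[:, c], np.full(pad, x[-1, c])]
        )
        out[:, c] = np.convolve(padded, kernel, mode="valid")
    return out


def compute_heading(
    centroid: np.ndarray, cfg: OptoConfig | None = None
) -> np.ndarray:
    """Direction of centroid motion per frame, degrees in (-180, 180].

    The centroid is box-smoothed first; the heading of frame i is the
    atan2 direction of the displacement from frame i to i+1 (last frame
    repeats).  Frames whose displacement is below the noise floor are NaN.
    Raises if no frame moves.
    """
    cfg = cfg or OptoConfig()
    centroid = np.asarray(centroid, dtype=float)
    if len(centroid) < 2:
        raise ValueError("need at least 2 frames")
    sm = _box_smooth_2d(centroid, int(round(cfg.smooth_s * cfg.fps)))
    disp = np.diff(sm, axis=0)
    step = np.linalg.norm(disp, axis=1)
    heading = np.degrees(np.arctan2(disp[:, 1], disp[:, 0]))
    heading[step < cfg.min_step_um] = np.nan
    heading = np.append(heading, heading[-1])
    if np.all(np.isnan(heading)):
        raise ValueError("trajectory is stationary; heading undefined")
    return heading


def detect_turns(
    heading: np.ndarray, cfg: OptoConfig | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flag frames whose heading change across the turn window exceeds the
    threshold.

    Frame i is flagged when |circular difference between the headings at the
    endpoints of the centred window| > threshold.  Window endpoints outside
    the recording, or undefined headings, leave the frame unflagged.
    Contiguous flagged frames merge into turn intervals.
    """
    cfg = cfg or OptoConfig()
    heading = np.asarray(heading, dtype=float)
    n = len(heading)
    w = int(round(cfg.turn_window_s * cfg.fps))
    if n <= w:
        raise ValueError("recording shorter than the turn window")
    half_lo = w // 2
    half_hi = w - half_lo
    flags = np.zeros(n, dtype=bool)
    idx = np.arange(half_lo, n - half_hi)
    a = heading[idx + half_hi]
    b = heading[idx - half_lo]
    ok = np.isfinite(a) & np.isfinite(b)
    d = np.abs(circular_diff_deg(a[ok], b[ok]))
    flags[idx[ok]] = d > cfg.turn_threshold_deg

    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return flags, intervals


def segment_runs(
    turn_flags: np.ndarray,
    centroid: np.ndarray,
    fps: float,
    laser_on: np.ndarray | None = None,
    cfg: OptoConfig | None = None,
) -> RunTurnSegmentation:
    """Runs are the maximal unflagged intervals between turns.

    Each run carries its duration, path length (summed centroid step
    lengths) and mean speed, and — when epoch labels are supplied — the
    laser state at the run's start.
    """
    cfg = cfg or OptoConfig()
    turn_flags = np.asarray(turn_flags, dtype=bool)
    centroid = np.asarray(centroid, dtype=float)
    n = len(turn_flags)
    step = np.linalg.norm(np.diff(centroid, axis=0), axis=1)

    runs: list[Run] = []
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not turn_flags[i]:
            j = i
            while j < n and not turn_flags[j]:
                j += 1
            dur = (j - i) / fps
            path = float(step[i : j - 1].sum()) if j - i > 1 else 0.0
            runs.append(
                Run(
                    start=i,
                    end=j,
                    duration_s=dur,
                    path_length_um=path,
                    mean_speed_um_s=path / dur if dur > 0 else 0.0,
                    laser_on=bool(laser_on[i]) if laser_on is not None else None,
                )
            )
            i = j
        else:
            j = i
            while j < n and turn_flags[j]:
                j += 1
            intervals.append((i, j))
            i = j

    heading = np.full(n, np.nan)
    return RunTurnSegmentation(
        heading_deg=heading,
        turn_flags=turn_flags,
        turn_intervals=intervals,
        runs=runs,
        laser_on=None if laser_on is None else np.asarray(laser_on, bool),
        fps=fps,
        config=cfg,
    )


def epoch_run_stats(seg: RunTurnSegmentation) -> dict:
    """Run-duration and path-length distributions per laser epoch class.

    All runs during ON and OFF phases are included; a class with no runs
    reports NaN means and is flagged.  Also reports the ON/OFF mean-duration
    ratio when both classes are populated.
    """
    if seg.laser_on is None:
        raise ValueError("segmentation carries no epoch labels")
    out: dict = {}
    for label, flag in (("on", True), ("off", False)):
        rs = [r for r in seg.runs if r.laser_on is flag]
        durs = [r.duration_s for r in rs]
        paths = [r.path_length_um for r in rs]
        out[label] = {
            "n_runs": len(rs),
            "durations_s": durs,
            "path_lengths_um": paths,
            "mean_duration_s": float(np.mean(durs)) if rs else float("nan"),
            "mean_path_um": float(np.mean(paths)) if rs else float("nan"),
            "empty": not rs,
        }
    if not out["on"]["empty"] and not out["off"]["empty"]:
        off = out["off"]["mean_duration_s"]
        out["on_off_duration_ratio"] = (
            out["on"]["mean_duration_s"] / off if off > 0 else float("nan")
        )
    return out


def phasic_velocity_change(
    velocity: np.ndarray,
    switch_frames: np.ndarray,
    cfg: OptoConfig | None = None,
    turn_flags: np.ndarray | None = None,
) -> dict:
    """Velocity before vs after each ON switch, Wilcoxon matched pairs.

    Only switches flanked by the configured seconds of continuous forward
    movement on both sides qualify (no turn in the window when flags are
    given, strictly positive velocity otherwise); excluded switches are
    listed.  Returns per-switch (pre mean, post mean, delta) and the
    two-sided matched-pairs signed-rank test across switches.
    """
    cfg = cfg or OptoConfig()
    velocity = np.asarray(velocity, dtype=float)
    w = int(round(cfg.phasic_window_s * cfg.fps))
    n = len(velocity)
    rows, excluded = [], []
    for s in np.asarray(switch_frames, dtype=int):
        if s - w < 0 or s + w > n:
            excluded.append(int(s))
            continue
        window = slice(s - w, s + w)
        if turn_flags is not None and np.asarray(turn_flags)[window].any():
            excluded.append(int(s))
            continue
        if turn_flags is None and not (velocity[window] > 0).all():
            excluded.append(int(s))
            continue
        pre = float(velocity[s - w : s].mean())
        post = float(velocity[s : s + w].mean())
        rows.append({"switch": int(s), "pre": pre, "post": post,
                     "delta": post - pre})
    if not rows:
        raise ValueError("no switch qualifies for the phasic comparison")
    pre = np.array([r["pre"] for r in rows])
    post = np.array([r["post"] for r in rows])
    if len(rows) >= 2:
        stat, p, flag = paired_test(pre, post)
    else:
        stat, p, flag = float("nan"), float("nan"), "single-switch"
    return {
        "switches": rows,
        "excluded": excluded,
        "mean_delta": float((post - pre).mean()),
        "wilcoxon_stat": stat,
        "p": p,
        "flag": flag,
    }
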