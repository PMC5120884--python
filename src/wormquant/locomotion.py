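"""Locomotion state segmentation and bout-level motility metrics.

Tracked C. elegans trajectories (head, tail, centroid per frame) are reduced
to a signed body-axis velocity, segmented into forward (F), reversal (R) and
pause (P) bouts under a minimum-bout rule, and summarised by four metrics:
fractional time per state, initiation frequency, bout duration and bout
velocity.  A curvature kymogram (body position x time matrix of local bending
angles) is provided for midline trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "SegmentationConfig",
    "Bout",
    "StateSegmentation",
    "MotilityMetrics",
    "body_axis_velocity",
    "segment_states",
    "bout_metrics",
    "curvature_kymogram",
]

UNTRACKED = "U"
STATES = ("F", "R", "P")


@dataclass
class Trajectory:
    """Per-frame body landmark coordinates, in micrometres, stage-corrected.

    Parameters
    ----------
    fps
        Acquisition rate, frames per second.
    head, tail, centroid
        Arrays of shape ``(n_frames, 2)``.
    midline
        Optional array of shape ``(n_frames, n_points, 2)``, ordered
        anterior to posterior.
    """

    fps: float
    head: np.ndarray
    tail: np.ndarray
    centroid: np.ndarray
    midline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        n = len(self.centroid)
        if not (len(self.head) == len(self.tail) == n):
            raise ValueError("head, tail and centroid must have equal length")
        if self.midline is not None:
            self.midline = np.asarray(self.midline, dtype=float)
            if len(self.midline) != n:
                raise ValueError("midline length must match other coordinates")

    @property
    def n_frames(self) -> int:
        return len(self.centroid)

    @property
    def t_s(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class SegmentationConfig:
    """Parameters of the bout segmentation.

    The minimum-bout rule accepts a candidate bout if it is longer than
    ``min_bout_frames`` frames *or* lasts at least ``min_bout_s`` seconds
    (disjunctive; at 10 fps both readings give 3 frames).  ``pause_speed_um_s``
    is the |velocity| threshold below which a frame counts as paused.
    ``short_bout_mode`` controls where sub-minimum bouts go: ``"absorb"``
    merges them into the flanking state when both flanks agree (edge bouts
    join their single neighbour) and into P otherwise; ``"pause"`` always
    relabels them P.
    """

    min_bout_frames: int = 3
    min_bout_s: float = 0.3
    pause_speed_um_s: float = 20.0
    smoothing_window: int = 5
    short_bout_mode: str = "absorb"

    def __post_init__(self) -> None:
        if self.min_bout_frames < 1:
            raise ValueError("min_bout_frames must be >= 1")
        if self.pause_speed_um_s < 0:
            raise ValueError("pause threshold must be >= 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.short_bout_mode not in ("absorb", "pause"):
            raise ValueError(f"unknown short_bout_mode {self.short_bout_mode!r}")

    def min_frames(self, fps: float) -> int:
        """Smallest accepted bout length in frames at a given frame rate."""
        by_frames = self.min_bout_frames + 1          # "> min_bout_frames"
        by_time = int(np.ceil(self.min_bout_s * fps))  # ">= min_bout_s"
        return max(1, min(by_frames, by_time))


@dataclass
class Bout:
    """One maximal interval of a single locomotor state.

    Frame interval is half-open ``[start, end)``; duration in seconds; mean
    signed velocity in um/s; displacement = integral of signed velocity, um.
    """

    state: str
    start: int
    end: int
    duration_s: float
    mean_velocity: float
    displacement: float

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class StateSegmentation:
    """Per-frame state labels plus the ordered bout table.

    ``labels`` holds one of ``F``/``R``/``P``/``U`` per frame; bouts are
    disjoint, ordered, and exactly tile the tracked (non-``U``) frames.
    """

    labels: np.ndarray
    bouts: list[Bout]
    fps: float
    all_untracked: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def bouts_of(self, state: str) -> list[Bout]:
        return [b for b in self.bouts if b.state == state]


@dataclass
class MotilityMetrics:
    """The four behavioural read-outs, per state."""

    fraction: dict[str, float]
    initiations_per_min: dict[str, float]
    mean_duration_s: dict[str, float]
    mean_velocity: dict[str, float]
    durations_s: dict[str, list[float]] = field(default_factory=dict)
    velocities: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "initiations_per_min": self.initiations_per_min,
            "mean_duration_s": self.mean_duration_s,
            "mean_velocity": self.mean_velocity,
        }


def _box_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centred moving average; window forced odd."""
    if window <= 1:
        return x
    if window % 2 == 0:
        window += 1
    valid = np.isfinite(x)
    xf = np.where(valid, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(xf, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    out = np.full_like(x, np.nan, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    out[~valid] = np.nan
    return out


def body_axis_velocity(
    traj: Trajectory, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Signed per-frame velocity along the tail-to-head body axis, um/s.

    The centroid displacement between consecutive frames is projected on the
    unit tail->head axis of the earlier frame and scaled by the frame rate;
    positive values are forward movement.  Frames with a degenerate body axis
    (head == tail) are returned as NaN (untracked).  The final frame repeats
    the last defined velocity so the series has one value per frame.
    """
    cfg = cfg or SegmentationConfig()
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute velocity")
    axis = traj.head - traj.tail
    norm = np.linalg.norm(axis, axis=1)
    ok = norm > 0
    unit = np.zeros_like(axis)
    unit[ok] = axis[ok] / norm[ok, None]

    disp = np.diff(traj.centroid, axis=0)
    v = np.einsum("ij,ij->i", disp, unit[:-1]) * traj.fps
    v = np.append(v, v[-1])
    v[~ok] = np.nan
    return _box_smooth(v, cfg.smoothing_window)


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of identical labels as (label, start, end) half-open."""
    out: list[tuple[str, int, int]] = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((str(labels[i]), i, j))
        i = j
    return out


def segment_states(
    velocity: np.ndarray, fps: float, cfg: SegmentationConfig | None = None
) -> StateSegmentation:
    """Segment a signed velocity series into F/R/P bouts.

    Frames with |v| <= pause threshold are paused; otherwise the sign of v
    gives F or R.  Candidate bouts failing the minimum-bout rule are absorbed
    per ``cfg.short_bout_mode`` until every bout satisfies the rule, so that
    single-frame jitter does not register as an initiation.  Untracked (NaN)
    frames break bouts and are excluded.
    """
    cfg = cfg or SegmentationConfig()
    velocity = np.asarray(velocity, dtype=float)
    n = len(velocity)
    labels = np.full(n, UNTRACKED, dtype="<U1")
    tracked = np.isfinite(velocity)
    labels[tracked & (np.abs(velocity) <= cfg.pause_speed_um_s)] = "P"
    labels[tracked & (velocity > cfg.pause_speed_um_s)] = "F"
    labels[tracked & (velocity < -cfg.pause_speed_um_s)] = "R"

    if not tracked.any():
        return StateSegmentation(labels, [], fps, all_untracked=True)

    min_frames = cfg.min_frames(fps)

    # Absorb sub-minimum bouts in simultaneous rounds: every short bout is
    # relabelled against the same snapshot of its neighbours, which keeps
    # the outcome symmetric under time reversal.  Untracked frames are hard
    # boundaries.  A short pause remnant between unlike states has no
    # resolution and is accepted as-is.
    while True:
        runs = _runs(labels)
        updates: list[tuple[int, int, str]] = []
        for k, (state, i, j) in enumerate(runs):
            if state == UNTRACKED or (j - i) >= min_frames:
                continue
            prev_state = runs[k - 1][0] if k > 0 else None
            next_state = runs[k + 1][0] if k + 1 < len(runs) else None
            prev_state = None if prev_state == UNTRACKED else prev_state
            next_state = None if next_state == UNTRACKED else next_state
            if cfg.short_bout_mode == "pause":
                new = "P"
            elif prev_state is not None and next_state is not None:
                new = prev_state if prev_state == next_state else "P"
            elif prev_state is not None or next_state is not None:
                new = prev_state if prev_state is not None else next_state
            else:
                # isolated short block between untracked gaps: call it a pause
                new = "P"
            if new != state:
                updates.append((i, j, new))
        if not updates:
            break
        for i, j, new in updates:
            labels[i:j] = new

    dt = 1.0 / fps
    bouts: list[Bout] = []
    for state, i, j in _runs(labels):
        if state == UNTRACKED:
            continue
        seg_v = velocity[i:j]
        bouts.append(
            Bout(
                state=state,
                start=i,
                end=j,
                duration_s=(j - i) * dt,
                mean_velocity=float(np.nanmean(seg_v)),
                displacement=float(np.nansum(seg_v) * dt),
            )
        )
    return StateSegmentation(labels, bouts, fps)


def bout_metrics(
    seg: StateSegmentation, recording_span_s: float | None = None
) -> MotilityMetrics:
    """Fractional time, initiation frequency, duration and velocity per state.

    Fractions are over tracked (labelled) frames and sum to one; initiation
    frequency counts bout starts of each state per minute of tracked time.
    ``recording_span_s`` overrides the tracked-time denominator when the
    recording extends beyond the labelled frames.
    """
    labelled = [b for b in seg.bouts]
    if not labelled:
        raise ValueError("segmentation has no labelled frames")
    n_labelled = sum(b.n_frames for b in labelled)
    span_s = (
        recording_span_s
        if recording_span_s is not None
        else n_labelled / seg.fps
    )
    span_min = span_s / 60.0

    fraction: dict[str, float] = {}
    initiations: dict[str, float] = {}
    mean_dur: dict[str, float] = {}
    mean_vel: dict[str, float] = {}
    durations: dict[str, list[float]] = {}
    velocities: dict[str, list[float]] = {}
    for s in STATES:
        bs = seg.bouts_of(s)
        frames = sum(b.n_frames for b in bs)
        fraction[s] = frames / n_labelled
        initiations[s] = len(bs) / span_min
        durations[s] = [b.duration_s for b in bs]
        velocities[s] = [b.mean_velocity for b in bs]
        mean_dur[s] = float(np.mean(durations[s])) if bs else float("nan")
        mean_vel[s] = float(np.mean(velocities[s])) if bs else float("nan")
    return MotilityMetrics(
        fraction, initiations, mean_dur, mean_vel, durations, velocities
    )


def curvature_kymogram(traj: Trajectory) -> np.ndarray:
    """Local bending angle along the body over time.

    For each frame the signed angle (radians) between successive midline
    tangent vectors is computed, giving a matrix of shape
    ``(n_points - 2, n_frames)`` whose stripes visualise propagating
    locomotor waves.
    """
    if traj.midline is None:
        raise ValueError("trajectory carries no midline")
    if traj.midline.shape[1] < 3:
        raise ValueError("need at least 3 midline points per frame")
    tangents = np.diff(traj.midline, axis=1)  # (n_frames, m-1, 2)
    a, b = tangents[:, :-1, :], tangents[:, 1:, :]
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = np.einsum("fkj,fkj->fk", a, b)
    return np.arctan2(cross, dot).T
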