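"""Synthetic data generators with known ground truth.

Four generators emulate the four input kinds of the analysis pipeline:

* :func:`simulate_trajectory` — a three-state (forward / reversal / pause)
  semi-Markov locomotion process with state-dependent speeds, rendered as
  head / tail / centroid coordinates at a fixed frame rate;
* :func:`simulate_calcium_session` — a two-channel (GCaMP, RFP) fluorescence
  recording whose underlying activity is a lagged low-pass response to the
  forward state, with a multiplicative motion artifact shared by both
  channels;
* :func:`simulate_opto_session` — a run/turn crawling trajectory whose run
  durations and speed are modulated during laser-ON epochs of a fixed
  on/off cycle;
* :func:`simulate_counts` — gene x sample negative-binomial count matrices
  for a subtractive sorted-cell design: AllCells is a mixture of many
  cell-type profiles, GFP+ a five-type sub-mixture, and the mutant design
  lacks one target cell type carrying planted cell-specific transcripts.

Every generator is deterministic given its seed and returns a
:class:`SimTruth` record of the quantities a downstream stage should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .locomotion import Trajectory

__all__ = [
    "LocomotionSimSpec",
    "CalciumSimSpec",
    "CountSimSpec",
    "SimTruth",
    "CountMatrix",
    "stationary_fractions",
    "simulate_trajectory",
    "simulate_calcium_session",
    "simulate_opto_session",
    "simulate_counts",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

def _default_dwell() -> dict[str, float]:
    return {"F": 40.0, "R": 2.0, "P": 2.0}


def _default_transition() -> dict[str, dict[str, float]]:
    return {
        "F": {"R": 0.5, "P": 0.5},
        "R": {"F": 0.9, "P": 0.1},
        "P": {"F": 0.9, "R": 0.1},
    }


def _default_speed() -> dict[str, float]:
    return {"F": 150.0, "R": 100.0, "P": 0.0}


@dataclass
class LocomotionSimSpec:
    """Semi-Markov locomotion process parameters.

    Dwell times are exponential with the given per-state means (seconds);
    the embedded transition matrix has no self-transitions and rows summing
    to one.  Speeds are per-state means in um/s (pause ~ 0) with Gaussian
    per-frame noise; the heading performs Brownian rotation with the stated
    degrees-per-root-second diffusion.  Defaults mimic an exploring
    wild-type-like regime with a forward time fraction near 0.95.
    """

    fps: float = 10.0
    duration_s: float = 180.0
    dwell_mean_s: dict[str, float] = field(default_factory=_default_dwell)
    transition: dict[str, dict[str, float]] = field(
        default_factory=_default_transition
    )
    dwell_shape: float = 1.0
    speed_mean_um_s: dict[str, float] = field(default_factory=_default_speed)
    speed_noise_sd: float = 10.0
    speed_modulation: float = 0.2
    heading_diffusion_deg: float = 15.0
    body_length_um: float = 600.0
    position_noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        for s, d in self.dwell_mean_s.items():
            if d <= 0:
                raise ValueError(f"dwell time for state {s!r} must be > 0")
        if self.dwell_shape <= 0:
            raise ValueError("dwell_shape must be positive")
        for s, v in self.speed_mean_um_s.items():
            if v < 0:
                raise ValueError(f"speed for state {s!r} must be >= 0")
        for s, row in self.transition.items():
            if s in row:
                raise ValueError(f"self-transition not allowed for state {s!r}")
            if row and not np.isclose(sum(row.values()), 1.0):
                raise ValueError(f"transition row for {s!r} must sum to 1")

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.dwell_mean_s)


@dataclass
class CalciumSimSpec:
    """Two-channel fluorescence model parameters.

    The latent activity a(t) is a first-order low-pass (time constant
    ``tau_s``, indicator-dye kinetics) of the movement drive delayed by the
    onset lag ``lag_s``.  The default drive is graded (rectified normalised
    forward velocity), so the activity peak trails the locomotor transition
    by the time it takes the within-bout speed envelope to crest — several
    seconds — plus the sensor delay.  GCaMP = F0 (1 + alpha a) m(t) + noise;
    RFP = R0 m(t) + noise, where m(t) is a shared multiplicative motion
    artifact, so the channel ratio is artifact-free in the noiseless limit.
    """

    alpha: float = 1.0
    tau_s: float = 1.5
    lag_s: float = 0.5
    drive: str = "graded"
    f0: float = 100.0
    r0: float = 100.0
    noise_sd: float = 1.0
    artifact_amplitude: float = 0.1
    artifact_freq_hz: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError(f"tau must be positive, got {self.tau_s}")
        if self.f0 <= 0 or self.r0 <= 0:
            raise ValueError("baseline F0 and R0 must be positive")
        if self.drive not in ("graded", "indicator"):
            raise ValueError(f"unknown drive mode {self.drive!r}")


def rid_ablated_spec(
    seed: int = 0, duration_s: float = 180.0
) -> LocomotionSimSpec:
    """Locomotion preset emulating loss of the forward-sustaining neuron.

    Sustained forward runs are replaced by shorter, slower ones with more
    frequent reversals and pauses: forward dwell 4 s (vs 40 s), reversal /
    pause dwells 2.5 s, forward speed 100 um/s (vs 150) — a regime with
    roughly 60% / 20% / 20% forward / reversal / pause time.
    """
    return LocomotionSimSpec(
        duration_s=duration_s,
        dwell_mean_s={"F": 4.0, "R": 2.5, "P": 2.5},
        speed_mean_um_s={"F": 100.0, "R": 80.0, "P": 0.0},
        seed=seed,
    )


def calcium_session_spec(
    seed: int = 0, duration_s: float = 180.0
) -> LocomotionSimSpec:
    """Locomotion preset for calcium-imaging sessions.

    Animals recorded on a wet agar pad change direction far more often than
    free crawlers: forward / reversal / pause dwell means of 20 / 8 / 2 s
    with gamma-shaped (shape 3) dwell durations — bout durations have a
    refractory rise, so sub-second reversals are rare.
    """
    return LocomotionSimSpec(
        duration_s=duration_s,
        dwell_mean_s={"F": 20.0, "R": 8.0, "P": 2.0},
        dwell_shape=3.0,
        seed=seed,
    )


@dataclass
class CountSimSpec:
    """Subtractive sorted-cell count-matrix design.

    ``n_cell_types`` cell-type expression profiles share a per-gene
    gamma-drawn baseline; ``type_heterogeneity_sd`` (log-normal sd) adds
    between-type variation (default 0, so non-planted genes have a true
    GFP+/AllCells ratio of exactly 1).  A planted set of target-type-specific
    genes is expressed at ``effect_size`` x baseline in the target type and
    at ``off_target_level`` x baseline elsewhere.  The GFP+ fraction is a
    five-type sub-mixture in which the target type has weight
    ``gfp_target_weight``; AllCells mixes all types with target weight
    ``all_target_weight``.  The mutant design removes the target type from
    both mixtures (weights renormalised).  Counts are negative-binomial with
    per-gene dispersion around mixture means scaled by per-sample library
    size factors.
    """

    n_genes: int = 2000
    n_cell_types: int = 12
    n_gfp_types: int = 5
    gfp_target_weight: float = 0.3
    all_target_weight: float = 0.04
    baseline_shape: float = 0.7
    baseline_scale: float = 100.0
    type_heterogeneity_sd: float = 0.0
    n_planted: int = 50
    effect_size: float = 5.0
    off_target_level: float = 0.02
    planted_base_shape: float = 2.0
    planted_base_scale: float = 100.0
    dispersion: float = 0.1
    libsize_sd: float = 0.3
    replicates_wt: int = 3
    replicates_mut: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_wt < 1 or self.replicates_mut < 1:
            raise ValueError("need at least 1 replicate per condition")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_planted < 1:
            raise ValueError("planted gene set must be nonempty")
        if not (0 < self.gfp_target_weight < 1):
            raise ValueError("gfp_target_weight must be in (0, 1)")
        if not (0 < self.all_target_weight < 1):
            raise ValueError("all_target_weight must be in (0, 1)")
        if self.n_gfp_types > self.n_cell_types:
            raise ValueError("GFP+ sub-mixture larger than the type set")


@dataclass
class SimTruth:
    """Ground truth emitted alongside synthetic data."""

    fps: float | None = None
    labels: np.ndarray | None = None          # per-frame state
    transition_frames: np.ndarray | None = None
    transition_times_s: np.ndarray | None = None
    activity: np.ndarray | None = None        # true Ca activity a(t)
    headings_deg: np.ndarray | None = None
    speeds_um_s: np.ndarray | None = None
    planted_genes: list[str] | None = None
    true_ratio_wt: np.ndarray | None = None
    true_ratio_mut: np.ndarray | None = None
    run_starts: np.ndarray | None = None      # opto: frame index per run
    run_durations_s: np.ndarray | None = None
    run_laser_on: np.ndarray | None = None
    run_multipliers: np.ndarray | None = None
    turn_intervals: list[tuple[int, int]] | None = None


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample metadata.

    ``meta`` carries one row per sample with columns ``genotype``
    (wt / mut), ``fraction`` (GFP+ / AllCells) and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count columns and metadata rows must align")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def select(self, genotype: str | None = None, fraction: str | None = None):
        m = self.meta
        keep = pd.Series(True, index=m.index)
        if genotype is not None:
            keep &= m["genotype"] == genotype
        if fraction is not None:
            keep &= m["fraction"] == fraction
        return self.counts.loc[:, keep[keep].index]


# ---------------------------------------------------------------------------
# Locomotion
# ---------------------------------------------------------------------------

def stationary_fractions(spec: LocomotionSimSpec) -> dict[str, float]:
    """Analytic long-run time fraction per state of the semi-Markov chain.

    The embedded jump chain's stationary law pi is weighted by mean dwell
    times: fraction_s = pi_s d_s / sum_k pi_k d_k.  A state with an empty
    transition row is absorbing and gets fraction 1.
    """
    states = list(spec.states)
    n = len(states)
    for s in states:
        if not spec.transition.get(s):
            return {k: float(k == s) for k in states}
    P = np.zeros((n, n))
    for i, s in enumerate(states):
        for t, p in spec.transition[s].items():
            P[i, states.index(t)] = p
    # stationary law of the jump chain: pi P = pi
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi = np.linalg.lstsq(A, b, rcond=None)[0]
    w = pi * np.array([spec.dwell_mean_s[s] for s in states])
    w = w / w.sum()
    return dict(zip(states, (float(x) for x in w)))


def _sample_states(
    spec: LocomotionSimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame labels and state-change frame indices.

    The initial state is drawn from the stationary time-fraction law; with
    exponential dwells the residual dwell is again exponential, so the
    emitted process is stationary from frame 0.
    """
    states = list(spec.states)
    fracs = stationary_fractions(spec)
    state = rng.choice(states, p=[fracs[s] for s in states])
    t, boundaries, seq = 0.0, [], []
    while t < spec.duration_s:
        # gamma dwells with the stated mean; shape 1 recovers exponential
        dwell = rng.gamma(
            spec.dwell_shape, spec.dwell_mean_s[state] / spec.dwell_shape
        )
        seq.append(state)
        t += dwell
        boundaries.append(t)
        row = spec.transition.get(state) or {}
        if not row:
            boundaries[-1] = spec.duration_s + 1.0
            break
        nxt = list(row)
        state = rng.choice(nxt, p=[row[s] for s in nxt])
    n_frames = int(round(spec.duration_s * spec.fps))
    times = np.arange(n_frames) / spec.fps
    idx = np.searchsorted(np.asarray(boundaries), times, side="right")
    idx = np.minimum(idx, len(seq) - 1)
    labels = np.array([seq[i] for i in idx], dtype="<U1")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return labels, change


def simulate_trajectory(
    spec: LocomotionSimSpec,
) -> tuple[Trajectory, SimTruth]:
    """Render the semi-Markov locomotion process as tracked coordinates.

    The centroid advances by the per-frame signed speed along the current
    tail->head body axis (positive forward, negative during reversals,
    near-zero during pauses); head and tail sit half a body length from the
    centroid along that axis.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels, change = _sample_states(spec, rng)
    n = len(labels)
    dt = 1.0 / spec.fps

    heading = np.empty(n)
    heading[0] = rng.uniform(0.0, 360.0)
    steps = rng.normal(
        0.0, spec.heading_diffusion_deg * np.sqrt(dt), size=n - 1
    )
    heading[1:] = heading[0] + np.cumsum(steps)

    sign = np.select(
        [labels == "F", labels == "R"], [1.0, -1.0], default=0.0
    )
    mean_speed = np.array([spec.speed_mean_um_s[s] for s in labels])
    # worms accelerate into and decelerate out of a bout: speed waxes and
    # wanes as a half-sine over each bout, peaking mid-bout
    if spec.speed_modulation > 0:
        env = np.ones(n)
        i = 0
        while i < n:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            frac = (np.arange(i, j) - i + 0.5) / (j - i)
            env[i:j] = 1.0 + spec.speed_modulation * np.sin(np.pi * frac)
            i = j
        mean_speed = mean_speed * env
    v = sign * mean_speed + rng.normal(0.0, spec.speed_noise_sd, size=n)

    u = np.column_stack(
        [np.cos(np.radians(heading)), np.sin(np.radians(heading))]
    )
    centroid = np.zeros((n, 2))
    centroid[1:] = np.cumsum(v[:-1, None] * dt * u[:-1], axis=0)

    half = 0.5 * spec.body_length_um
    head = centroid + half * u
    tail = centroid - half * u
    if spec.position_noise_sd_um > 0:
        head = head + rng.normal(0, spec.position_noise_sd_um, head.shape)
        tail = tail + rng.normal(0, spec.position_noise_sd_um, tail.shape)
        centroid = centroid + rng.normal(
            0, spec.position_noise_sd_um, centroid.shape
        )

    traj = Trajectory(fps=spec.fps, head=head, tail=tail, centroid=centroid)
    truth = SimTruth(
        fps=spec.fps,
        labels=labels,
        transition_frames=change,
        transition_times_s=change / spec.fps,
        headings_deg=heading,
        speeds_um_s=v,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Calcium
# ---------------------------------------------------------------------------

def simulate_calcium_session(
    truth: SimTruth, spec: CalciumSimSpec
) -> CalciumTrace:
    """Emit a two-channel fluorescence recording coupled to forward movement.

    The drive is either the forward-state indicator (mode ``"indicator"``)
    or, by default, the rectified forward velocity normalised to its typical
    peak (mode ``"graded"`` — neural activity scales with crawling vigour,
    so faster accelerations produce steeper calcium rises).  The drive is
    delayed by the onset lag and passed through an exact first-order
    low-pass (per-frame factor ``1 - exp(-dt/tau)``), so a unit step crosses
    63% of its plateau one time constant after the lag.  Both channels share
    the multiplicative artifact m(t); the latent activity is stored back
    into ``truth.activity``.
    """
    if truth.labels is None or truth.fps is None:
        raise ValueError("truth must carry per-frame labels and fps")
    rng = np.random.default_rng(spec.seed)
    fps = truth.fps
    n = len(truth.labels)
    dt = 1.0 / fps

    if spec.drive == "graded" and truth.speeds_um_s is not None:
        fwd = np.clip(truth.speeds_um_s, 0.0, None)
        ref = np.percentile(fwd[fwd > 0], 90) if (fwd > 0).any() else 1.0
        x = fwd / max(ref, 1e-12)
    else:
        x = (truth.labels == "F").astype(float)
    lag = int(round(spec.lag_s * fps))
    x_lag = np.concatenate([np.full(lag, x[0]), x[: n - lag]]) if lag else x

    a = np.empty(n)
    a[0] = x_lag[0]
    k = 1.0 - np.exp(-dt / spec.tau_s)
    for i in range(1, n):
        a[i] = a[i - 1] + k * (x_lag[i] - a[i - 1])
    truth.activity = a

    t = np.arange(n) * dt
    m = 1.0 + spec.artifact_amplitude * np.sin(
        2.0 * np.pi * spec.artifact_freq_hz * t
    )
    gcamp = spec.f0 * (1.0 + spec.alpha * a) * m
    rfp = spec.r0 * m
    if spec.noise_sd > 0:
        gcamp = gcamp + rng.normal(0.0, spec.noise_sd, n)
        rfp = rfp + rng.normal(0.0, spec.noise_sd, n)
    return CalciumTrace(gcamp=gcamp, rfp=rfp, fps=fps)


# ---------------------------------------------------------------------------
# Optogenetics
# ---------------------------------------------------------------------------

def simulate_opto_session(
    spec: LocomotionSimSpec,
    on_off_period_s: float = 180.0,
    on_effect: tuple[float, float] = (1.0, 1.0),
    seed: int | None = None,
    mean_run_s: float | None = None,
    turn_duration_s: float = 0.5,
    start_on: bool = False,
) -> tuple[Trajectory, np.ndarray, SimTruth]:
    """Run/turn crawling session with laser-ON run and speed modulation.

    Runs have exponential durations (mean ``mean_run_s``, default the
    forward dwell mean) scaled by the ON run-duration multiplier at the
    epoch of the run's start; between runs the heading pivots by 90-180
    degrees over ``turn_duration_s`` seconds (well above the 60-degrees-
    per-second turn criterion).  Crawling speed is the forward state speed
    multiplied per-frame by the ON speed multiplier, so velocity steps
    exactly at epoch switches.  Returns the trajectory, the per-frame
    laser-ON flags and the ground truth.
    """
    if on_off_period_s <= 0:
        raise ValueError("on/off period must be positive")
    dur_mult, speed_mult = on_effect
    if dur_mult <= 0 or speed_mult <= 0:
        raise ValueError("ON-effect multipliers must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fps = spec.fps
    dt = 1.0 / fps
    n = int(round(spec.duration_s * fps))
    t = np.arange(n) * dt

    cycle = (t // on_off_period_s).astype(int)
    laser_on = (cycle % 2 == 0) if start_on else (cycle % 2 == 1)

    base = mean_run_s if mean_run_s is not None else spec.dwell_mean_s["F"]
    turn_frames = max(1, int(round(turn_duration_s * fps)))

    heading = np.empty(n)
    heading[0] = rng.uniform(0.0, 360.0)
    is_turn = np.zeros(n, dtype=bool)
    run_starts: list[int] = []
    run_durs: list[float] = []
    run_on: list[bool] = []
    run_mult: list[float] = []
    turn_ivals: list[tuple[int, int]] = []

    i = 0
    while i < n:
        mult = dur_mult if laser_on[i] else 1.0
        dur = rng.exponential(base * mult)
        n_run = max(1, int(round(dur * fps)))
        j = min(n, i + n_run)
        steps = rng.normal(
            0.0, spec.heading_diffusion_deg * np.sqrt(dt), size=j - i
        )
        heading[i:j] = heading[max(i - 1, 0)] + np.cumsum(steps)
        run_starts.append(i)
        run_durs.append(dur)
        run_on.append(bool(laser_on[i]))
        run_mult.append(mult)
        i = j
        if i >= n:
            break
        # pivot turn
        jt = min(n, i + turn_frames)
        total = rng.uniform(90.0, 180.0) * rng.choice([-1.0, 1.0])
        inc = np.full(jt - i, total / turn_frames)
        heading[i:jt] = heading[i - 1] + np.cumsum(inc)
        is_turn[i:jt] = True
        turn_ivals.append((i, jt))
        i = jt

    speed = spec.speed_mean_um_s["F"] + rng.normal(
        0.0, spec.speed_noise_sd, size=n
    )
    speed = np.clip(speed, 0.0, None)
    speed = speed * np.where(laser_on, speed_mult, 1.0)
    speed[is_turn] *= 0.5  # worms slow while pivoting

    u = np.column_stack(
        [np.cos(np.radians(heading)), np.sin(np.radians(heading))]
    )
    centroid = np.zeros((n, 2))
    centroid[1:] = np.cumsum(speed[:-1, None] * dt * u[:-1], axis=0)
    half = 0.5 * spec.body_length_um
    head = centroid + half * u
    tail = centroid - half * u

    traj = Trajectory(fps=fps, head=head, tail=tail, centroid=centroid)
    truth = SimTruth(
        fps=fps,
        headings_deg=heading,
        speeds_um_s=speed,
        run_starts=np.array(run_starts),
        run_durations_s=np.array(run_durs),
        run_laser_on=np.array(run_on),
        run_multipliers=np.array(run_mult),
        turn_intervals=turn_ivals,
    )
    return traj, laser_on, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _mixture_weights(
    n_types: int, members: np.ndarray, target: int, target_weight: float
) -> np.ndarray:
    """Weights over all types: target fixed, the rest uniform over members."""
    w = np.zeros(n_types)
    others = members[members != target]
    w[target] = target_weight
    w[others] = (1.0 - target_weight) / len(others)
    return w


def simulate_counts(
    spec: CountSimSpec,
) -> tuple[CountMatrix, SimTruth]:
    """Generate the two-genotype, two-fraction NB count design.

    Planted target-type-specific genes have elevated GFP+ means only in the
    wild-type design; in the mutant both mixtures lack the target type, so
    their true GFP+/AllCells ratio collapses to ~1.  Identical seeds give
    identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    G, T = spec.n_genes, spec.n_cell_types
    genes = [f"g{i:05d}" for i in range(G)]

    base = rng.gamma(spec.baseline_shape, spec.baseline_scale, size=G)
    base = np.maximum(base, 0.5)
    profiles = np.tile(base[:, None], (1, T))
    if spec.type_heterogeneity_sd > 0:
        profiles = profiles * rng.lognormal(
            0.0, spec.type_heterogeneity_sd, size=(G, T)
        )

    target = 0
    planted_idx = rng.choice(G, size=spec.n_planted, replace=False)
    planted_idx.sort()
    # cell-specific marker transcripts are abundantly expressed in their
    # cell, so planted genes get their own (higher-mean) baseline draw
    planted_base = rng.gamma(
        spec.planted_base_shape, spec.planted_base_scale, size=spec.n_planted
    )
    base[planted_idx] = planted_base
    profiles[planted_idx, :] = spec.off_target_level * planted_base[:, None]
    profiles[planted_idx, target] = spec.effect_size * planted_base

    gfp_members = np.arange(spec.n_gfp_types)
    all_members = np.arange(T)
    w_gfp_wt = _mixture_weights(
        T, gfp_members, target, spec.gfp_target_weight
    )
    w_all_wt = _mixture_weights(
        T, all_members, target, spec.all_target_weight
    )
    # mutant: target type absent from both mixtures
    w_gfp_mut = np.zeros(T)
    w_gfp_mut[gfp_members[gfp_members != target]] = 1.0 / (
        spec.n_gfp_types - 1
    )
    w_all_mut = np.zeros(T)
    w_all_mut[all_members != target] = 1.0 / (T - 1)

    means = {
        ("wt", "GFP+"): profiles @ w_gfp_wt,
        ("wt", "AllCells"): profiles @ w_all_wt,
        ("mut", "GFP+"): profiles @ w_gfp_mut,
        ("mut", "AllCells"): profiles @ w_all_mut,
    }

    cols, data, meta_rows = [], [], []
    for genotype, n_rep in (("wt", spec.replicates_wt), ("mut", spec.replicates_mut)):
        for fraction in ("GFP+", "AllCells"):
            mu = means[(genotype, fraction)]
            for r in range(n_rep):
                sf = float(rng.lognormal(0.0, spec.libsize_sd))
                m = np.maximum(mu * sf, 1e-8)
                n_nb = 1.0 / spec.dispersion
                p_nb = n_nb / (n_nb + m)
                data.append(rng.negative_binomial(n_nb, p_nb))
                name = f"{genotype}_{fraction}_{r + 1}"
                cols.append(name)
                meta_rows.append(
                    {"sample": name, "genotype": genotype,
                     "fraction": fraction, "replicate": r + 1}
                )

    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene"), columns=cols
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")

    eps = 1e-12
    truth = SimTruth(
        planted_genes=[genes[i] for i in planted_idx],
        true_ratio_wt=(means[("wt", "GFP+")] + eps)
        / (means[("wt", "AllCells")] + eps),
        true_ratio_mut=(means[("mut", "GFP+")] + eps)
        / (means[("mut", "AllCells")] + eps),
    )
    return CountMatrix(counts=counts, meta=meta), truth
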