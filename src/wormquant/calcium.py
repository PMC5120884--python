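"""Ratiometric calcium analysis around locomotor direction changes.

The GCaMP/RFP channel ratio cancels multiplicative motion artifacts common
to both channels; its baseline-normalised change (dF/F) is the activity
read-out.  Directional transitions (reversal->forward, forward->reversal)
are anchored at bout boundaries; each transition carries a velocity rate
(peak minus trough velocity over the frames between them) and a calcium
slope (least-squares dF/F slope over the same frames), whose Pearson
correlation quantifies the coupling between acceleration/deceleration and
calcium rise/decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .locomotion import StateSegmentation

__all__ = [
    "CalciumTrace",
    "TransitionEvent",
    "ratiometric_dff",
    "detect_transitions",
    "transition_rates",
    "event_aligned_average",
    "rate_correlation",
]


@dataclass
class CalciumTrace:
    """Two-channel fluorescence with derived ratio and dF/F.

    ``ratio`` and ``dff`` are filled by :func:`ratiometric_dff`; frames with
    non-positive RFP are masked (NaN).
    """

    gcamp: np.ndarray
    rfp: np.ndarray
    fps: float
    ratio: np.ndarray | None = None
    dff: np.ndarray | None = None
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        if len(self.gcamp) != len(self.rfp):
            raise ValueError("channels must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.gcamp)


@dataclass
class TransitionEvent:
    """A directional transition with its velocity-rate and Ca-slope read-out.

    ``kind`` is ``"RF"`` (reversal to forward) or ``"FR"``; ``anchor`` the
    boundary frame.  ``velocity_rate`` follows the convention
    (V_peak - V_trough)/n_frames for RF and (V_trough - V_peak)/n_frames for
    FR, so accelerations are positive and decelerations negative.
    ``ca_slope`` is the least-squares dF/F slope per frame over
    [trough, peak] (RF) or [peak, trough] (FR).
    """

    kind: str
    anchor: int
    prev_bout: int
    next_bout: int
    trough_frame: int | None = None
    peak_frame: int | None = None
    v_trough: float | None = None
    v_peak: float | None = None
    n_frames: int | None = None
    velocity_rate: float | None = None
    ca_slope: float | None = None
    window: tuple[int, int] | None = None


def ratiometric_dff(
    gcamp: np.ndarray,
    rfp: np.ndarray,
    fps: float,
    baseline_rule: str = "percentile",
    baseline_percentile: float = 10.0,
) -> CalciumTrace:
    """GCaMP/RFP ratio and its baseline-normalised change.

    The default baseline is the 10th percentile of the ratio over the
    recording (rule ``"percentile"``); rule ``"mean"`` uses the recording
    mean.  dF/F = (ratio - baseline)/baseline.  Frames with RFP <= 0 are
    masked.
    """
    trace = CalciumTrace(gcamp=gcamp, rfp=rfp, fps=fps)
    ratio = np.full(trace.n_frames, np.nan)
    ok = trace.rfp > 0
    ratio[ok] = trace.gcamp[ok] / trace.rfp[ok]
    if not ok.any():
        raise ValueError("no frame with positive RFP")
    if baseline_rule == "percentile":
        baseline = float(np.nanpercentile(ratio, baseline_percentile))
    elif baseline_rule == "mean":
        baseline = float(np.nanmean(ratio))
    else:
        raise ValueError(f"unknown baseline rule {baseline_rule!r}")
    if baseline == 0:
        raise ValueError("ratio baseline is zero; dF/F undefined")
    trace.ratio = ratio
    trace.baseline = baseline
    trace.dff = (ratio - baseline) / baseline
    return trace


def detect_transitions(
    seg: StateSegmentation,
    kinds: tuple[str, ...] = ("RF", "FR"),
    max_pause_gap_s: float | None = None,
) -> list[TransitionEvent]:
    """Anchor one event at each adjacent (R, F) or (F, R) bout pair.

    The anchor is the first frame of the later bout.  Pause bouts shorter
    than the minimum-bout rule — irreducible remnants the velocity leaves
    at a direction change as it crosses zero — do not break adjacency; the
    default gap tolerance is the minimum bout duration at the recording's
    frame rate, overridable via ``max_pause_gap_s``.  An empty list is a
    valid result.
    """
    from .locomotion import SegmentationConfig

    if max_pause_gap_s is None:
        max_pause_gap_s = (
            SegmentationConfig().min_frames(seg.fps) - 1
        ) / seg.fps
    events: list[TransitionEvent] = []
    bouts = seg.bouts
    for i, b in enumerate(bouts):
        if b.state not in ("F", "R"):
            continue
        j = i + 1
        while (
            j < len(bouts)
            and bouts[j].state == "P"
            and bouts[j].duration_s <= max_pause_gap_s
        ):
            j += 1
        if j >= len(bouts):
            continue
        nxt = bouts[j]
        kind = f"{b.state}{nxt.state}"
        if kind in kinds and kind in ("RF", "FR"):
            events.append(
                TransitionEvent(
                    kind=kind, anchor=nxt.start, prev_bout=i, next_bout=j
                )
            )
    return events


def transition_rates(
    event: TransitionEvent,
    seg: StateSegmentation,
    velocity: np.ndarray,
    dff: np.ndarray,
) -> TransitionEvent | None:
    """Complete an event with its velocity rate and calcium slope.

    For RF the trough is the minimum velocity in the preceding reversal bout
    and the peak the maximum in the following forward bout; the rate is
    (V_peak - V_trough)/n_frames.  FR is symmetric with the printed sign
    convention (V_trough - V_peak)/n_frames.  The Ca slope is fit over the
    same frame support.  Returns None (event dropped) when the support is
    degenerate or leaves the recording.
    """
    velocity = np.asarray(velocity, dtype=float)
    dff = np.asarray(dff, dtype=float)
    prev_b = seg.bouts[event.prev_bout]
    next_b = seg.bouts[event.next_bout]

    if event.kind == "RF":
        lo = prev_b.start + int(np.nanargmin(velocity[prev_b.start:prev_b.end]))
        hi = next_b.start + int(np.nanargmax(velocity[next_b.start:next_b.end]))
        event.trough_frame, event.peak_frame = lo, hi
        event.v_trough = float(velocity[lo])
        event.v_peak = float(velocity[hi])
        first, last = lo, hi
        n = hi - lo
        rate = (event.v_peak - event.v_trough) / n if n >= 1 else None
    elif event.kind == "FR":
        hi = prev_b.start + int(np.nanargmax(velocity[prev_b.start:prev_b.end]))
        lo = next_b.start + int(np.nanargmin(velocity[next_b.start:next_b.end]))
        event.peak_frame, event.trough_frame = hi, lo
        event.v_peak = float(velocity[hi])
        event.v_trough = float(velocity[lo])
        first, last = hi, lo
        n = lo - hi
        rate = (event.v_trough - event.v_peak) / n if n >= 1 else None
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")

    if rate is None or last >= len(dff):
        return None
    y = dff[first : last + 1]
    if np.isnan(y).any():
        return None
    x = np.arange(len(y), dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    event.n_frames = n
    event.velocity_rate = float(rate)
    event.ca_slope = slope
    event.window = (first, last + 1)
    return event


def event_aligned_average(
    events: list[TransitionEvent],
    signal: np.ndarray,
    fps: float,
    window_s: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean +/- SEM of a signal aligned on event anchors.

    Only events whose full +/- window lies inside the recording contribute.
    Returns (lag times in s, mean trace, SEM trace, number of events).
    """
    signal = np.asarray(signal, dtype=float)
    w = int(round(window_s * fps))
    segs = []
    for e in events:
        if e.anchor - w >= 0 and e.anchor + w + 1 <= len(signal):
            segs.append(signal[e.anchor - w : e.anchor + w + 1])
    if not segs:
        raise ValueError("no event with a complete alignment window")
    m = np.vstack(segs)
    mean = m.mean(axis=0)
    sem = (
        m.std(axis=0, ddof=1) / np.sqrt(len(segs))
        if len(segs) > 1
        else np.zeros_like(mean)
    )
    lags = (np.arange(-w, w + 1)) / fps
    return lags, mean, sem, len(segs)


def rate_correlation(
    events: list[TransitionEvent],
) -> tuple[float, float]:
    """Pearson correlation between velocity rate and calcium slope.

    Events must be completed (non-None rate and slope).  Raises on fewer
    than 3 events or on zero variance in either variable.
    """
    done = [
        e
        for e in events
        if e.velocity_rate is not None and e.ca_slope is not None
    ]
    if len(done) < 3:
        raise ValueError("need at least 3 completed events")
    x = np.array([e.velocity_rate for e in done])
    y = np.array([e.ca_slope for e in done])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
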