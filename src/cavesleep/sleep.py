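"""Sleep scoring from locomotor velocity traces.

Sleep in larval *Astyanax mexicanus* (and zebrafish) is scored behaviourally:
a fish is immobile when its instantaneous swimming velocity falls below a
mobility cut-off (6 mm/s by default, separating active swimming from passive
drift), and a sleep bout is a consolidated run of immobility lasting at least
60 s.  This module turns frame-by-frame velocity traces into sleep bouts,
windowed summary metrics (total sleep, bout number, mean bout length), binned
24-h sleep profiles on the Zeitgeber-time axis, and per-epoch sleep/wake
transition probabilities P(doze) and P(wake) — behavioural proxies for sleep
pressure and sleep depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VelocityTrace",
    "ScoringConfig",
    "SleepBout",
    "SleepMetrics",
    "SleepProfile",
    "TransitionProbabilities",
    "binarize_mobility",
    "detect_sleep_bouts",
    "score_sleep",
    "compute_sleep_metrics",
    "compute_sleep_profile",
    "transition_probabilities",
    "epoch_quiescence",
    "estimate_epoch_transition_rates",
    "estimate_transition_probabilities",
    "read_trace_csv",
    "write_trace_csv",
    "read_manifest",
    "write_bout_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VelocityTrace:
    """Uniformly sampled velocity time series for one subject.

    Parameters
    ----------
    subject_id
        Identifier of the tracked animal.
    velocity
        Per-frame velocity in mm/s; NaN marks missing frames.  Must be
        non-negative where present.
    frame_rate
        Sampling rate in Hz.
    t0
        Clock time (s) of the first frame.
    zt0_offset
        Clock time (s) at which lights came on (ZT0).
    light_schedule
        (light hours, dark hours); the husbandry default is a 14:10 cycle.
    labels
        Free-form metadata (population, treatment, ...).
    """

    subject_id: str
    velocity: np.ndarray
    frame_rate: float
    t0: float = 0.0
    zt0_offset: float = 0.0
    light_schedule: tuple[float, float] = (14.0, 10.0)
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 1:
            raise ValueError("velocity must be a 1-D array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        v = self.velocity
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("velocities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.velocity.size

    @property
    def duration(self) -> float:
        """Trace extent in seconds (n_frames frame periods)."""
        return self.n_frames / self.frame_rate

    @property
    def time(self) -> np.ndarray:
        """Uniform time grid in seconds (clock time of each frame)."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class ScoringConfig:
    """Parameters of the sleep-scoring rule.

    velocity_threshold is the mobility cut-off in mm/s (frames with velocity
    strictly below it are immobile); min_bout_s is the minimum consolidated
    immobility for a sleep bout ("60 s or more"); max_gap_s > 0 allows brief
    mobile interruptions inside a bout (off by default — "consolidated" is read
    as uninterrupted); nan_policy governs missing frames; epoch_s is the epoch
    length for transition-probability estimation.
    """

    velocity_threshold: float = 6.0
    min_bout_s: float = 60.0
    max_gap_s: float = 0.0
    nan_policy: str = "break"
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0:
            raise ValueError("velocity_threshold must be positive")
        if self.min_bout_s <= 0:
            raise ValueError("min_bout_s must be positive")
        if self.max_gap_s < 0:
            raise ValueError("max_gap_s must be non-negative")
        if self.nan_policy not in ("break", "fill_short"):
            raise ValueError("nan_policy must be 'break' or 'fill_short'")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")


@dataclass(frozen=True)
class SleepBout:
    """One maximal interval of consolidated immobility (>= min_bout_s)."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SleepMetrics:
    """Windowed sleep summary: total minutes, bout count, mean bout length.

    mean_bout_length_s is NaN when no bout onset falls inside the window.
    """

    window: tuple[float, float]
    total_sleep_min: float
    bout_number: int
    mean_bout_length_s: float


@dataclass
class SleepProfile:
    """Binned sleep minutes on the Zeitgeber-time axis.

    bin_edges_zt are in ZT hours (hours since lights-on, not wrapped at 24 so
    the axis stays monotone over multi-day traces).
    """

    bin_edges_zt: np.ndarray
    sleep_min_per_bin: np.ndarray


@dataclass
class TransitionProbabilities:
    """Per-epoch sleep/wake transition probabilities.

    p_doze is the probability that a wake epoch is followed by a sleep epoch
    (sleep pressure); p_wake the reverse (inverse sleep depth).  Either is NaN
    when the source state contributes no epoch with a successor.
    """

    p_doze: float
    p_wake: float
    n_wake_epochs: int
    n_sleep_epochs: int


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def binarize_mobility(trace: VelocityTrace, cfg: ScoringConfig | None = None) -> np.ndarray:
    """Per-frame immobility flags (True = immobile).

    A frame is immobile iff velocity < cfg.velocity_threshold.  Missing
    (NaN) frames are treated as mobile under the default ``break`` policy,
    so they interrupt bouts; under ``fill_short`` missing runs no longer than
    1 s inherit the previous frame's state (conservative against inflating
    sleep), longer runs still break.
    """
    cfg = cfg or ScoringConfig()
    v = trace.velocity
    if v.size == 0:
        raise ValueError("empty trace")
    immobile = v < cfg.velocity_threshold  # NaN compares False -> mobile
    missing = ~np.isfinite(v)
    if cfg.nan_policy == "fill_short" and missing.any():
        max_fill = int(round(trace.frame_rate))  # 1 s of frames
        runs = _runs(missing)
        for i0, i1 in runs:
            if i1 - i0 <= max_fill and i0 > 0:
                immobile[i0:i1] = immobile[i0 - 1]
    return immobile


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where flags is True."""
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        return []
    d = np.diff(f.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if f[0]:
        starts.insert(0, 0)
    if f[-1]:
        stops.append(f.size)
    return list(zip(starts, stops))


def detect_sleep_bouts(
    immobile: np.ndarray,
    frame_rate: float,
    cfg: ScoringConfig | None = None,
    t0: float = 0.0,
) -> list[SleepBout]:
    """Detect sleep bouts from per-frame immobility flags.

    Maximal immobile runs (optionally merged across mobile gaps of at most
    cfg.max_gap_s) with duration >= cfg.min_bout_s become bouts; a run of
    exactly min_bout_s qualifies.  Durations are whole frames times the frame
    period; bout times are offset by ``t0``.
    """
    cfg = cfg or ScoringConfig()
    runs = _runs(np.asarray(immobile, dtype=bool))
    if cfg.max_gap_s > 0 and len(runs) > 1:
        max_gap_frames = cfg.max_gap_s * frame_rate + 1e-9
        merged = [runs[0]]
        for i0, i1 in runs[1:]:
            if i0 - merged[-1][1] <= max_gap_frames:
                merged[-1] = (merged[-1][0], i1)
            else:
                merged.append((i0, i1))
        runs = merged
    period = 1.0 / frame_rate
    min_frames = cfg.min_bout_s * frame_rate - 1e-9
    return [
        SleepBout(start=t0 + i0 * period, end=t0 + i1 * period)
        for i0, i1 in runs
        if (i1 - i0) >= min_frames
    ]


def score_sleep(trace: VelocityTrace, cfg: ScoringConfig | None = None) -> list[SleepBout]:
    """Binarize mobility and detect sleep bouts in one step."""
    cfg = cfg or ScoringConfig()
    return detect_sleep_bouts(binarize_mobility(trace, cfg), trace.frame_rate, cfg, t0=trace.t0)


# ---------------------------------------------------------------------------
# Windowed metrics and profiles
# ---------------------------------------------------------------------------

def compute_sleep_metrics(bouts: Sequence[SleepBout], window: tuple[float, float]) -> SleepMetrics:
    """Windowed sleep summary.

    Total sleep counts only each bout's overlap with the window (conserves
    time); the bout count and the mean bout length use bouts whose *onset*
    lies in [window start, window end), with the full duration of each counted
    bout entering the mean.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window must have positive length")
    overlap = sum(max(0.0, min(b.end, w1) - max(b.start, w0)) for b in bouts)
    counted = [b for b in bouts if w0 <= b.start < w1]
    mean_len = float(np.mean([b.duration for b in counted])) if counted else float("nan")
    return SleepMetrics(
        window=(w0, w1),
        total_sleep_min=overlap / 60.0,
        bout_number=len(counted),
        mean_bout_length_s=mean_len,
    )


def compute_sleep_profile(
    bouts: Sequence[SleepBout],
    trace: VelocityTrace,
    bin_min: float = 10.0,
) -> SleepProfile:
    """Apportion sleep to time bins by overlap; bin axis in ZT hours.

    Bins tile the trace extent from its first frame; bin_min must divide 60
    so bins align with the hour grid.  The bins of any window sum to that
    window's total sleep (conservation).
    """
    if 60.0 % bin_min != 0:
        raise ValueError("bin_min must divide 60")
    bin_s = bin_min * 60.0
    if trace.duration < bin_s:
        raise ValueError("trace shorter than one bin")
    n_bins = int(np.ceil(trace.duration / bin_s - 1e-9))
    edges = trace.t0 + bin_s * np.arange(n_bins + 1)
    sleep_s = np.zeros(n_bins)
    for b in bouts:
        lo = max(0, int(np.floor((b.start - trace.t0) / bin_s)))
        hi = min(n_bins - 1, int(np.floor((b.end - trace.t0) / bin_s - 1e-12)))
        for k in range(lo, hi + 1):
            sleep_s[k] += max(0.0, min(b.end, edges[k + 1]) - max(b.start, edges[k]))
    return SleepProfile(
        bin_edges_zt=(edges - trace.zt0_offset) / 3600.0,
        sleep_min_per_bin=sleep_s / 60.0,
    )


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def transition_probabilities(
    bouts: Sequence[SleepBout],
    window: tuple[float, float],
    epoch_s: float = 1.0,
) -> TransitionProbabilities:
    """Per-epoch P(doze) and P(wake) over a window.

    The window is tiled with epochs of epoch_s; an epoch is sleep iff it lies
    entirely inside a scored bout.  P(doze) = (# wake epochs whose successor
    is sleep) / (# wake epochs with a successor); P(wake) symmetrically.  A
    state with no qualifying epochs yields NaN, not zero.
    """
    w0, w1 = window
    n_epochs = int(np.floor((w1 - w0) / epoch_s + 1e-9))
    if n_epochs < 2:
        raise ValueError("window must contain at least 2 epochs")
    starts = w0 + epoch_s * np.arange(n_epochs)
    asleep = np.zeros(n_epochs, dtype=bool)
    for b in bouts:
        # epoch [s, s+epoch_s) inside bout iff b.start <= s and s+epoch_s <= b.end
        lo = int(np.ceil((b.start - w0) / epoch_s - 1e-9))
        hi = int(np.floor((b.end - w0 - epoch_s) / epoch_s + 1e-9))
        if hi >= 0 and lo < n_epochs:
            asleep[max(lo, 0): min(hi, n_epochs - 1) + 1] = True
    cur, nxt = asleep[:-1], asleep[1:]
    n_wake_src = int(np.sum(~cur))
    n_sleep_src = int(np.sum(cur))
    p_doze = float(np.sum(~cur & nxt) / n_wake_src) if n_wake_src else float("nan")
    p_wake = float(np.sum(cur & ~nxt) / n_sleep_src) if n_sleep_src else float("nan")
    return TransitionProbabilities(
        p_doze=p_doze,
        p_wake=p_wake,
        n_wake_epochs=int(np.sum(~asleep)),
        n_sleep_epochs=int(np.sum(asleep)),
    )


def epoch_quiescence(
    immobile: np.ndarray, frame_rate: float, epoch_s: float = 1.0
) -> np.ndarray:
    """Collapse frame-level immobility to epoch-level quiescence.

    An epoch is quiescent iff every frame it contains is immobile; trailing
    frames that do not fill an epoch are dropped.
    """
    frames_per_epoch = int(round(frame_rate * epoch_s))
    if frames_per_epoch < 1:
        raise ValueError("epoch shorter than one frame period")
    flags = np.asarray(immobile, dtype=bool)
    n_epochs = flags.size // frames_per_epoch
    if n_epochs < 1:
        raise ValueError("trace shorter than one epoch")
    return flags[: n_epochs * frames_per_epoch].reshape(n_epochs, frames_per_epoch).all(axis=1)


def estimate_epoch_transition_rates(
    immobile: np.ndarray, frame_rate: float, epoch_s: float = 1.0
) -> TransitionProbabilities:
    """Per-epoch transition probabilities of raw quiescence (not scored sleep).

    Labels epochs directly by immobility and counts epoch-to-epoch
    transitions.  Unlike :func:`transition_probabilities`, which operates on
    scored sleep bouts (and therefore conditions quiescent runs on the 60-s
    sleep rule), this estimator is unbiased for the generative per-epoch
    transition probabilities of a two-state model whose dwell times may be
    shorter than a sleep bout.
    """
    q = epoch_quiescence(immobile, frame_rate, epoch_s)
    if q.size < 2:
        raise ValueError("need at least 2 epochs")
    cur, nxt = q[:-1], q[1:]
    n_active_src = int(np.sum(~cur))
    n_quiescent_src = int(np.sum(cur))
    p_doze = float(np.sum(~cur & nxt) / n_active_src) if n_active_src else float("nan")
    p_wake = float(np.sum(cur & ~nxt) / n_quiescent_src) if n_quiescent_src else float("nan")
    return TransitionProbabilities(
        p_doze=p_doze,
        p_wake=p_wake,
        n_wake_epochs=int(np.sum(~q)),
        n_sleep_epochs=int(np.sum(q)),
    )


def estimate_transition_probabilities(
    trace: VelocityTrace,
    cfg: ScoringConfig | None = None,
    window: tuple[float, float] | None = None,
) -> TransitionProbabilities:
    """Score a trace and estimate its P(doze)/P(wake) in one step."""
    cfg = cfg or ScoringConfig()
    bouts = score_sleep(trace, cfg)
    if window is None:
        window = (trace.t0, trace.t0 + trace.duration)
    return transition_probabilities(bouts, window, epoch_s=cfg.epoch_s)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trace_csv(trace: VelocityTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "velocity_mm_s": trace.velocity}).to_csv(
        path, index=False
    )


def read_trace_csv(
    path: str | Path,
    subject_id: str | None = None,
    zt0_offset: float = 0.0,
    labels: dict | None = None,
) -> VelocityTrace:
    """Read a per-subject trace CSV (columns time_s, velocity_mm_s)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace must contain at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
        raise ValueError("time grid must be strictly increasing and uniform")
    return VelocityTrace(
        subject_id=subject_id or Path(path).stem,
        velocity=df["velocity_mm_s"].to_numpy(dtype=float),
        frame_rate=1.0 / float(np.mean(dt)),
        t0=float(t[0]),
        zt0_offset=zt0_offset,
        labels=labels or {},
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV: subject_id, group, population, treatment, file."""
    m = pd.read_csv(path, sep="\t")
    if m["subject_id"].duplicated().any():
        raise ValueError("duplicate subject identifiers in manifest")
    return m


def write_bout_table(subject_id: str, bouts: Sequence[SleepBout], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject": subject_id,
            "start_s": [b.start for b in bouts],
            "end_s": [b.end for b in bouts],
            "duration_s": [b.duration for b in bouts],
        }
    ).to_csv(path, sep="\t", index=False)
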