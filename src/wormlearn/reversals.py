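"""Reversal detection from centroid tracks and light-evoked reversal statistics.

A reversal is operationally the onset of a heading change greater than
``angle_threshold`` (default 150 deg) relative to the smoothed pre-onset run
heading, sustained for at least ``min_duration`` (default 1 s); onsets less
than 2 s apart are not distinct.  The original tracking scripts are
unpublished, so this detector is a defined stand-in with all thresholds
exposed.

The headline statistic per light pulse is the number of reversal onsets
initiated during the 20-s stimulation window minus the number in the 20 s
immediately after light-off, summed over animals; by default pulses six
through ten of the ten-pulse schedule are analyzed and the per-pulse mean is
the trial-level value compared between groups with a Welch t-test (the trial
is the replication unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import TestResult, welch_t
from .types import StimulusProtocol, ValidationError, WormTrack

__all__ = [
    "detect_reversals",
    "detect_reversal_bouts",
    "reversal_fraction_timecourse",
    "during_minus_after",
    "analyze_pulses",
    "TrialSummary",
    "compare_groups",
]

_STALL_SPEED = 0.01  # mm/s; below this the heading is meaningless


def _headings(track: WormTrack, smooth_s: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-step headings and speeds from lightly smoothed coordinates."""
    dt = float(np.median(np.diff(track.t)))
    w = max(1, int(round(smooth_s / dt)))
    x = ndimage.uniform_filter1d(track.x, w, mode="nearest")
    y = ndimage.uniform_filter1d(track.y, w, mode="nearest")
    dx, dy = np.diff(x), np.diff(y)
    speed = np.hypot(dx, dy) / dt
    heading = np.arctan2(dy, dx)
    return heading, speed, dt


def _angdiff(a, b):
    """Smallest signed angular difference a-b in (-pi, pi]."""
    return (a - b + np.pi) % (2 * np.pi) - np.pi


def detect_reversal_bouts(
    track: WormTrack,
    angle_threshold: float = 150.0,
    min_duration: float = 1.0,
    refractory: float = 2.0,
    smooth_s: float = 0.75,
) -> list[tuple[float, float]]:
    """Detect reversal bouts as (onset, end) intervals.

    State machine over per-step headings: while running forward, a reference
    run heading is tracked by an exponential circular average; when the
    instantaneous heading departs from the reference by more than
    ``angle_threshold`` and stays departed for ``min_duration``, a bout
    begins at the departure; the bout ends once the heading returns within
    90 deg of the reference (the post-reversal course change is small
    relative to the flip).  Stationary tracks yield no events.
    """
    if len(track.t) < 3:
        raise ValidationError("need at least three samples to detect reversals")
    if not (np.all(np.isfinite(track.x)) and np.all(np.isfinite(track.y))):
        raise ValidationError("non-finite coordinates")
    heading, speed, dt = _headings(track, smooth_s)
    if float(np.median(speed)) < _STALL_SPEED:
        return []
    thr = np.deg2rad(angle_threshold)
    exit_thr = np.pi / 2
    need = max(1, int(round(min_duration / dt)))
    alpha = min(1.0, dt / max(smooth_s, dt))

    bouts: list[tuple[float, float]] = []
    ref = heading[0]
    state = "forward"
    cand_start_idx = 0
    run = 0
    last_onset = -np.inf
    stale = 0          # samples since the reference heading last updated
    stale_limit = max(1, int(round(3.0 / dt)))
    max_bout = max(1, int(round(8.0 / dt)))  # force exit of implausibly long bouts
    bout_len = 0
    for k in range(1, len(heading)):
        if speed[k] < _STALL_SPEED:
            continue
        d = abs(_angdiff(heading[k], ref))
        stale += 1
        if state == "forward" and stale > stale_limit:
            # the reference went stale (e.g. after a missed flip): re-anchor
            ref = heading[k]
            stale = 0
            continue
        if state == "forward":
            if d > thr:
                state = "candidate"
                cand_start_idx = k
                run = 1
            elif d < exit_thr:
                # update the run heading only from forward-coherent samples;
                # ambiguous headings (e.g. mid-flip) must not drag the reference
                ref = ref + alpha * _angdiff(heading[k], ref)
                stale = 0
        elif state == "candidate":
            if d > thr:
                run += 1
                if run >= need:
                    onset_t = track.t[cand_start_idx]
                    if onset_t - last_onset >= refractory:
                        bouts.append([onset_t, track.t[k]])
                        last_onset = onset_t
                        state = "reversed"
                    else:
                        state = "reversed"  # continuation of the previous event
                    bout_len = run
            else:
                state = "forward"
                if d < exit_thr:
                    ref = ref + alpha * _angdiff(heading[k], ref)
                    stale = 0
                run = 0
        else:  # reversed
            bout_len += 1
            if d < exit_thr or bout_len > max_bout:
                state = "forward"
                if bouts:
                    bouts[-1][1] = track.t[k]
                ref = heading[k]
                stale = 0
            elif bouts:
                bouts[-1][1] = track.t[k]
    return [(float(a), float(b)) for a, b in bouts]


def detect_reversals(
    track: WormTrack,
    angle_threshold: float = 150.0,
    min_duration: float = 1.0,
    refractory: float = 2.0,
    smooth_s: float = 0.75,
) -> np.ndarray:
    """Reversal-onset times for one track (see :func:`detect_reversal_bouts`)."""
    bouts = detect_reversal_bouts(track, angle_threshold, min_duration, refractory, smooth_s)
    return np.array([a for a, _ in bouts])


def reversal_fraction_timecourse(
    tracks: list[WormTrack],
    schedule: StimulusProtocol,
    bin_s: float = 1.0,
    assumed_duration_s: float = 2.5,
    pre_s: float = 20.0,
    post_s: float = 60.0,
    analyzed: list[int] | None = None,
    bouts_per_track: list[list[tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Pulse-aligned fraction of animals with an ongoing reversal.

    Time bins run from ``-pre_s`` before light-on to ``post_s`` after;
    the curve is averaged across the analyzed pulses (all by default).  A
    reversal occupies ``[onset, onset + duration)``; detected bout intervals
    may be passed in, otherwise each event in ``track.events`` is assumed to
    last ``assumed_duration_s``.
    """
    if not tracks:
        raise ValidationError("no tracks given")
    if bin_s <= 0:
        raise ValidationError("bin_s must be positive")
    onsets = schedule.onsets()
    idx = (
        [i - 1 for i in analyzed] if analyzed is not None else list(range(len(onsets)))
    )
    edges = np.arange(-pre_s, post_s + bin_s, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(len(centers))
    for p in idx:
        on = onsets[p]
        frac = np.zeros(len(centers))
        for j, tr in enumerate(tracks):
            if bouts_per_track is not None:
                ivs = bouts_per_track[j]
            else:
                ivs = [(e, e + assumed_duration_s) for e in tr.events]
            busy = np.zeros(len(centers), dtype=bool)
            for a, b in ivs:
                busy |= (on + centers >= a) & (on + centers < b)
            frac += busy
        acc += frac / len(tracks)
    return pd.DataFrame({"t_rel": centers, "fraction_reversing": acc / len(idx)})


def during_minus_after(
    events_per_animal: list[np.ndarray],
    schedule: StimulusProtocol,
    window_s: float = 20.0,
) -> pd.DataFrame:
    """Per-pulse (during count, after count, difference), summed over animals.

    During = onsets in [light_on, light_on + window); after = onsets in
    [light_off, light_off + window); the after window abuts the stimulation
    window (closed-open).  Consecutive pulse windows must not overlap.
    """
    if schedule.kind != "light":
        raise ValidationError("during_minus_after requires a light schedule")
    ons, offs = schedule.onsets(), schedule.offsets()
    for i in range(len(ons) - 1):
        if offs[i] + window_s > ons[i + 1]:
            raise ValidationError(
                f"after-window of pulse {i + 1} overlaps pulse {i + 2}"
            )
    rows = []
    for p, (on, off) in enumerate(zip(ons, offs), start=1):
        during = after = 0
        for ev in events_per_animal:
            ev = np.asarray(ev, float)
            during += int(np.sum((ev >= on) & (ev < on + window_s)))
            after += int(np.sum((ev >= off) & (ev < off + window_s)))
        rows.append(
            {"pulse": p, "during": during, "after": after, "difference": during - after}
        )
    return pd.DataFrame(rows)


@dataclass
class TrialSummary:
    """Trial-level reversal statistics over the analyzed pulse subset."""

    trial_id: str
    n_animals: int
    analyzed_pulses: list[int]
    per_pulse: pd.DataFrame = field(repr=False)
    during_minus_after: float = 0.0  # mean per-pulse difference

    def __post_init__(self) -> None:
        if (self.per_pulse["during"] < 0).any() or (self.per_pulse["after"] < 0).any():
            raise ValidationError("negative event counts")


def analyze_pulses(
    events_per_animal: list[np.ndarray],
    schedule: StimulusProtocol,
    analyzed: list[int] | None = None,
    window_s: float = 20.0,
    trial_id: str = "trial0",
) -> TrialSummary:
    """TrialSummary over the analyzed pulses (1-based indices; default 6-10)."""
    n_pulses = len(schedule.intervals)
    if analyzed is None:
        analyzed = [i for i in range(6, 11) if i <= n_pulses] or list(range(1, n_pulses + 1))
    if max(analyzed) > n_pulses:
        raise ValidationError(
            f"requested pulse {max(analyzed)} but schedule has only {n_pulses}"
        )
    table = during_minus_after(events_per_animal, schedule, window_s)
    sub = table[table["pulse"].isin(analyzed)].reset_index(drop=True)
    return TrialSummary(
        trial_id=trial_id,
        n_animals=len(events_per_animal),
        analyzed_pulses=list(analyzed),
        per_pulse=sub,
        during_minus_after=float(sub["difference"].mean()),
    )


def compare_groups(a: list[TrialSummary], b: list[TrialSummary]) -> TestResult:
    """Welch t-test on trial-level mean during-minus-after values."""
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two trials per group")
    return welch_t(
        [s.during_minus_after for s in a], [s.during_minus_after for s in b]
    )
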