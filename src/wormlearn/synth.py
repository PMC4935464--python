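"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* AWC calcium traces — odor suppresses fluorescence with Hill-type
  concentration dependence; odor removal gives an exponential return to
  baseline with an optional overshoot and optional damped oscillations;
  conditioning shifts the effective EC50 by ``shift_fold`` (default 10),
  speeds recovery, and reduces the overshoot.
* Cell-plane images — a disk-shaped cytoplasm with a concentric nuclear disk
  whose mean-intensity ratio is programmed exactly (before noise).
* Worm tracks — persistent runs at constant speed; reversal initiations are
  an inhomogeneous Poisson process whose rate is elevated inside light
  pulses; a reversal flips the heading ~180 deg for a bout of duration
  floor + exponential.  Initiations are suppressed while a bout is ongoing
  (a reversing animal cannot initiate another reversal), a small dead-time
  that the closed-form rate expectation must account for.
* Chemotaxis plates — a multinomial draw over the four end-point zones.

Everything is bit-reproducible given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (
    CellPlaneImage,
    FluorTrace,
    PlateCount,
    StimulusProtocol,
    ValidationError,
    WormTrack,
)

__all__ = [
    "AwcModelParams",
    "ReversalModelParams",
    "make_odor_protocol",
    "make_light_schedule",
    "simulate_awc_trace",
    "simulate_awc_cohort",
    "simulate_cell_image",
    "simulate_tracks",
    "simulate_plate",
    "BUTANONE_CONCENTRATIONS",
]

#: The six-step, 10-fold butanone dilution series (M): 11 nM up to 1.1 mM.
BUTANONE_CONCENTRATIONS: tuple[float, ...] = tuple(11e-9 * 10 ** k for k in range(6))


# ---------------------------------------------------------------------------
# stimulus protocols

def make_odor_protocol(
    concentrations=BUTANONE_CONCENTRATIONS,
    pulse_s: float = 30.0,
    n_pulses_per_conc: int = 3,
    inter_block_s: float = 60.0,
) -> StimulusProtocol:
    """Pulsed odor dose-series protocol.

    Each concentration block alternates ``pulse_s`` of buffer with ``pulse_s``
    of odor, ``n_pulses_per_conc`` times, then ``inter_block_s`` of buffer;
    blocks run in ascending concentration order (within-block odor onsets are
    therefore ``2*pulse_s`` apart).
    """
    concs = [float(c) for c in concentrations]
    if not concs:
        raise ValidationError("need at least one concentration")
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValidationError("concentrations must be strictly increasing")
    intervals = []
    t = 0.0
    for c in concs:
        for _ in range(n_pulses_per_conc):
            t += pulse_s  # leading buffer pulse
            intervals.append((t, t + pulse_s, c))
            t += pulse_s
        t += inter_block_s
    return StimulusProtocol(intervals=intervals, kind="odor")


def make_light_schedule(
    pulse_s: float = 20.0, period_s: float = 120.0, n_pulses: int = 10
) -> StimulusProtocol:
    """Blue-light pulse train: ``n_pulses`` pulses of ``pulse_s``, onsets ``period_s`` apart."""
    if period_s <= pulse_s:
        raise ValidationError("period_s must exceed pulse_s")
    if n_pulses < 1:
        raise ValidationError("need at least one pulse")
    intervals = [(k * period_s, k * period_s + pulse_s, 1.0) for k in range(n_pulses)]
    return StimulusProtocol(intervals=intervals, kind="light")


# ---------------------------------------------------------------------------
# AWC calcium model

@dataclass
class AwcModelParams:
    """Parameters of the phenomenological AWC calcium-fluorescence model.

    Suppression depth at concentration c follows a Hill curve
    ``d(c) = d_max * c^hill / (c^hill + ec50_eff^hill)`` with
    ``ec50_eff = ec50 * shift_fold`` for conditioned animals.  Conditioning
    additionally scales the recovery time constant and the overshoot
    (``tau_rec_conditioned_scale``, ``overshoot_conditioned_scale``), the
    three channels through which conditioned and naive traces may differ.
    ``tau_rec`` and ``overshoot_amp`` may be scalars or callables of
    concentration.
    """

    f0: float = 1.0
    ec50: float = 2e-7           # M; half-maximal suppression, naive
    hill: float = 1.0
    d_max: float = 0.9           # maximal fractional suppression
    tau_on: float = 2.0          # s; first-order approach to suppression
    tau_rec: float | object = 25.0       # s; recovery after odor removal
    overshoot_amp: float | object = 0.08  # fraction of f0, scaled by d(c)/d_max
    overshoot_tau: float = 6.0   # s; alpha-function overshoot time-to-peak
    osc_amp: float = 0.0         # post-removal oscillation amplitude (off by default)
    osc_freq: float = 0.1        # Hz
    osc_tau: float = 30.0        # s; oscillation damping
    shift_fold: float = 10.0     # conditioning-induced EC50 multiplier
    tau_rec_conditioned_scale: float = 0.4
    overshoot_conditioned_scale: float = 0.5
    noise_sd: float = 0.02       # additive Gaussian noise, units of f0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValidationError("ec50 and hill must be positive")
        if not (0 < self.d_max <= 1):
            raise ValidationError("d_max must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.shift_fold < 1:
            raise ValidationError("shift_fold must be >= 1")
        if _eval_cparam(self.tau_rec, self.ec50) <= 0:
            raise ValidationError("tau_rec must be positive")

    def depth(self, c: float, conditioned: bool = False) -> float:
        """Steady-state fractional suppression at concentration c."""
        if c <= 0:
            return 0.0
        ec = self.ec50 * (self.shift_fold if conditioned else 1.0)
        ch = c ** self.hill
        return self.d_max * ch / (ch + ec ** self.hill)


def _eval_cparam(p, c: float) -> float:
    return float(p(c)) if callable(p) else float(p)


def simulate_awc_trace(
    params: AwcModelParams,
    protocol: StimulusProtocol,
    conditioned: bool = False,
    fs: float = 10.0,
    post_s: float = 360.0,
    animal_id: str = "",
    rng: np.random.Generator | None = None,
) -> FluorTrace:
    """Simulate one AWC fluorescence trace under a pulsed odor protocol.

    Piecewise first-order kinetics: during odor at concentration c the trace
    relaxes toward ``f0*(1-d(c))`` with time constant ``tau_on``; in buffer it
    relaxes back toward ``f0`` with ``tau_rec(c)`` of the preceding odor, plus
    an alpha-function overshoot and optional damped oscillation added at each
    odor removal.  ``post_s`` of buffer recording is appended after the last
    pulse.  The trace is continuous across segment boundaries.
    """
    if protocol.kind != "odor":
        raise ValidationError("simulate_awc_trace requires an odor protocol")
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    total = protocol.span + post_s
    t = np.arange(0.0, total, 1.0 / fs)
    f = np.full_like(t, params.f0)

    tau_scale = params.tau_rec_conditioned_scale if conditioned else 1.0
    ov_scale = params.overshoot_conditioned_scale if conditioned else 1.0

    # build the alternating segment list: (t0, t1, conc, conc_of_previous_pulse)
    segments = []
    cursor, prev_c = 0.0, 0.0
    for a, b, c in protocol.intervals:
        if a > cursor:
            segments.append((cursor, a, 0.0, prev_c))
        segments.append((a, b, c, prev_c))
        cursor, prev_c = b, c
    if total > cursor:
        segments.append((cursor, total, 0.0, prev_c))

    f_cur = params.f0
    for t0, t1, c, prev in segments:
        m = (t >= t0) & (t < t1)
        if c > 0:
            target = params.f0 * (1.0 - params.depth(c, conditioned))
            tau = params.tau_on
        else:
            target = params.f0
            tau = _eval_cparam(params.tau_rec, prev if prev > 0 else params.ec50) * tau_scale
        dt = t[m] - t0
        f[m] = target + (f_cur - target) * np.exp(-dt / tau)
        if c == 0 and prev > 0:
            # odor was just removed: overshoot bump + optional oscillation
            rel_depth = params.depth(prev, conditioned) / params.d_max
            amp = _eval_cparam(params.overshoot_amp, prev) * ov_scale * rel_depth
            if amp > 0:
                x = dt / params.overshoot_tau
                f[m] += amp * x * np.exp(1.0 - x)
            if params.osc_amp > 0:
                f[m] += (
                    params.osc_amp
                    * rel_depth
                    * np.exp(-dt / params.osc_tau)
                    * np.sin(2 * np.pi * params.osc_freq * dt)
                )
        # carry the exact boundary value into the next segment
        f_cur = target + (f_cur - target) * math.exp(-(t1 - t0) / tau)
        if c == 0 and prev > 0:
            rel_depth = params.depth(prev, conditioned) / params.d_max
            amp = _eval_cparam(params.overshoot_amp, prev) * ov_scale * rel_depth
            x = (t1 - t0) / params.overshoot_tau
            if amp > 0:
                f_cur += amp * x * math.exp(1.0 - x)
            if params.osc_amp > 0:
                f_cur += (
                    params.osc_amp
                    * rel_depth
                    * math.exp(-(t1 - t0) / params.osc_tau)
                    * math.sin(2 * np.pi * params.osc_freq * (t1 - t0))
                )

    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=f.shape)
    return FluorTrace(t=t, f=f, animal_id=animal_id or "sim", norm_state="raw")


def simulate_awc_cohort(
    params: AwcModelParams,
    protocol: StimulusProtocol,
    conditioned: bool,
    n_animals: int,
    fs: float = 10.0,
    post_s: float = 360.0,
) -> list[FluorTrace]:
    """Simulate ``n_animals`` independent traces (per-animal noise streams)."""
    children = np.random.SeedSequence(params.seed).spawn(n_animals)
    label = "cond" if conditioned else "naive"
    return [
        simulate_awc_trace(
            params,
            protocol,
            conditioned,
            fs=fs,
            post_s=post_s,
            animal_id=f"{label}{i:03d}",
            rng=np.random.default_rng(ss),
        )
        for i, ss in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# cell images

def simulate_cell_image(
    nuclear_index_target: float,
    size: int = 64,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_radius_frac: float = 0.35,
    nucleus_radius_frac: float = 0.12,
    cyto_intensity: float = 100.0,
    background: float = 5.0,
) -> CellPlaneImage:
    """Disk cell with concentric nuclear disk; ROIs returned as ground truth.

    Before noise, mean(nucleus)/mean(cytoplasm) equals ``nuclear_index_target``
    exactly.
    """
    if nuclear_index_target <= 0:
        raise ValidationError("nuclear_index_target must be positive")
    if nucleus_radius_frac >= cell_radius_frac:
        raise ValidationError("nucleus would exceed the cell")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cell = r2 <= (cell_radius_frac * size) ** 2
    nucleus = r2 <= (nucleus_radius_frac * size) ** 2
    cytoplasm = cell & ~nucleus
    img = np.full((size, size), background, dtype=float)
    img[cytoplasm] = cyto_intensity
    img[nucleus] = cyto_intensity * nuclear_index_target
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    return CellPlaneImage(
        pixels=img,
        nucleus_roi=np.flatnonzero(nucleus.ravel()),
        cytoplasm_roi=np.flatnonzero(cytoplasm.ravel()),
    )


# ---------------------------------------------------------------------------
# worm tracks

@dataclass
class ReversalModelParams:
    """Two-state run/reversal locomotion model parameters.

    Rates are reversal initiations per minute; a light pulse switches the
    initiation rate from ``r_base`` to ``r_stim``.  Bout durations are
    ``rev_duration_min + Exp(rev_duration_mean - rev_duration_min)`` so every
    bout is long enough to be detectable.
    """

    r_base: float = 2.0          # events/min outside light
    r_stim: float = 10.0         # events/min during light
    rev_duration_mean: float = 2.5  # s
    rev_duration_min: float = 1.5   # s
    speed: float = 0.15          # mm/s crawling speed
    heading_noise_deg: float = 10.0  # per-sqrt(second) heading diffusion
    position_noise_mm: float = 0.005
    end_turn_deg: float = 25.0   # course change after a reversal ends
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_base < 0 or self.r_stim < 0:
            raise ValidationError("rates must be non-negative")
        if self.rev_duration_mean <= 0 or self.rev_duration_min < 0:
            raise ValidationError("reversal durations must be positive")
        if self.rev_duration_mean <= self.rev_duration_min:
            raise ValidationError("rev_duration_mean must exceed rev_duration_min")


def _rate_segments(
    schedule: StimulusProtocol, duration_s: float, r_base: float, r_stim: float
):
    """Piecewise-constant rate (per second) over [0, duration_s)."""
    segs = []
    cursor = 0.0
    for a, b, lv in schedule.intervals:
        a, b = min(a, duration_s), min(b, duration_s)
        if a > cursor:
            segs.append((cursor, a, r_base / 60.0))
        if b > a:
            segs.append((a, b, (r_stim if lv > 0 else r_base) / 60.0))
        cursor = max(cursor, b)
    if duration_s > cursor:
        segs.append((cursor, duration_s, r_base / 60.0))
    return segs


def _draw_reversal_events(
    params: ReversalModelParams,
    schedule: StimulusProtocol,
    duration_s: float,
    rng: np.random.Generator,
):
    """Ground-truth reversal bouts: (onsets, durations), dead-time thinned."""
    candidates = []
    for a, b, rate in _rate_segments(schedule, duration_s, params.r_base, params.r_stim):
        if rate <= 0:
            continue
        n = rng.poisson(rate * (b - a))
        candidates.append(a + (b - a) * rng.random(n))
    times = np.sort(np.concatenate(candidates)) if candidates else np.array([])
    onsets, durations = [], []
    busy_until = -np.inf
    for ev in times:
        if ev < busy_until:
            continue  # already reversing: initiation suppressed
        dur = params.rev_duration_min + rng.exponential(
            params.rev_duration_mean - params.rev_duration_min
        )
        onsets.append(ev)
        durations.append(dur)
        busy_until = ev + dur
    return np.array(onsets), np.array(durations)


def simulate_tracks(
    params: ReversalModelParams,
    schedule: StimulusProtocol,
    n_animals: int,
    duration_s: float,
    fs: float = 4.0,
    trial_id: str = "trial0",
) -> list[WormTrack]:
    """Simulate centroid tracks of ``n_animals`` with ground-truth reversal onsets.

    Each animal runs at constant speed with slowly diffusing heading; at each
    ground-truth onset the heading flips 180 deg for the bout duration, then
    the animal resumes forward travel with a small random course change.
    """
    if schedule.kind != "light":
        raise ValidationError("simulate_tracks requires a light schedule")
    children = np.random.SeedSequence(params.seed).spawn(n_animals)
    dt = 1.0 / fs
    t = np.arange(0.0, duration_s, dt)
    tracks = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        onsets, durations = _draw_reversal_events(params, schedule, duration_s, rng)
        # drop bouts that would not complete within the recording
        keep = onsets + durations < duration_s - dt
        onsets, durations = onsets[keep], durations[keep]

        sigma = np.deg2rad(params.heading_noise_deg) * np.sqrt(dt)
        theta_base = rng.uniform(0, 2 * np.pi) + np.cumsum(sigma * rng.normal(size=len(t)))
        # piecewise-constant heading offset: +pi at each onset; at each bout
        # end the animal resumes the pre-bout run heading plus a small turn
        offset = np.zeros_like(t)
        cur = 0.0
        for on, dur in zip(onsets, durations):
            i_on = int(np.searchsorted(t, on, side="right"))
            i_end = min(int(np.searchsorted(t, on + dur, side="right")), len(t) - 1)
            pre = theta_base[max(i_on - 1, 0)] + cur
            offset[i_on:i_end] = cur + np.pi
            turn = np.deg2rad(params.end_turn_deg) * rng.normal()
            cur = pre + turn - theta_base[i_end]
            offset[i_end:] = cur
        theta = theta_base + offset
        step = params.speed * dt
        x = np.concatenate([[0.0], np.cumsum(step * np.cos(theta[1:]))])
        y = np.concatenate([[0.0], np.cumsum(step * np.sin(theta[1:]))])
        if params.position_noise_mm > 0:
            x = x + rng.normal(0, params.position_noise_mm, x.shape)
            y = y + rng.normal(0, params.position_noise_mm, y.shape)
        # snap ground-truth event times into the sampled span
        events = onsets[(onsets >= t[0]) & (onsets <= t[-1])]
        tracks.append(
            WormTrack(t=t, x=x, y=y, events=events, trial_id=trial_id, animal_id=f"worm{i:03d}")
        )
    return tracks


# ---------------------------------------------------------------------------
# chemotaxis plates

def simulate_plate(
    p_odor: float,
    p_control: float,
    p_other: float,
    p_origin: float,
    n_animals: int,
    seed: int = 0,
    condition: str = "naive",
    group: str = "WT",
    histamine: bool = False,
    plate_id: str = "",
) -> PlateCount:
    """Multinomial end-point draw over the four plate zones."""
    p = np.array([p_odor, p_control, p_other, p_origin], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValidationError("zone probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_animals), p / p.sum())
    return PlateCount(
        n_odor=int(counts[0]),
        n_control=int(counts[1]),
        n_other=int(counts[2]),
        n_origin=int(counts[3]),
        condition=condition,
        group=group,
        histamine=histamine,
        plate_id=plate_id,
    )
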