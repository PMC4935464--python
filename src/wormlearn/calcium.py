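"""Dose-response metrics for pulsed-odor AWC calcium recordings.

A recording covers an ascending concentration series of odor pulse blocks.
Per animal and concentration the analysis computes:

* **response magnitude** — decrease in normalized fluorescence at the first
  odor pulse of a block: mean over the 2 s preceding odor onset minus mean
  over the last 10 s of the pulse (positive = suppression);
* **recovery half-time** — time after the last odor removal of the block for
  fluorescence to regain 50% of the evoked suppression; computed only when
  the suppression reaches the responder threshold (default 0.075), and
  reported as a lower bound when recovery is not reached within the
  available window.

Cohort summaries average half-times only when at least half of the animals
responded; lower bounds propagate as flags, never silently as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .stats import TestResult, welch_t
from .types import FluorTrace, StimulusProtocol, ValidationError

__all__ = [
    "HalfTime",
    "PulseMetrics",
    "normalize_dff0",
    "normalize_dffmax",
    "response_magnitude",
    "recovery_half_time",
    "pulse_metrics",
    "aggregate_block",
    "dose_response_table",
    "per_concentration_welch",
    "fit_hill",
    "dynamic_range_shift",
    "DoseResponseShift",
]


# ---------------------------------------------------------------------------
# normalization

def normalize_dff0(trace: FluorTrace, baseline_t: float = 1700.0) -> FluorTrace:
    """Divide the trace by its value at the baseline time (nearest sample)."""
    if trace.norm_state != "raw":
        raise ValidationError(f"trace already normalized ({trace.norm_state})")
    if not (trace.t[0] <= baseline_t <= trace.t[-1]):
        raise ValidationError(
            f"baseline_t={baseline_t} outside trace span [{trace.t[0]}, {trace.t[-1]}]"
        )
    f0 = float(trace.f[np.argmin(np.abs(trace.t - baseline_t))])
    if f0 <= 0:
        raise ValidationError("baseline fluorescence sample is non-positive")
    return FluorTrace(
        t=trace.t.copy(), f=trace.f / f0, animal_id=trace.animal_id, norm_state="dff0",
        covers_protocol=trace.covers_protocol,
    )


def normalize_dffmax(trace: FluorTrace, tail_frac: float = 0.05) -> FluorTrace:
    """Affine 0-1 rescale: the means of the lowest and highest ``tail_frac``
    of sample values map to 0 and 1."""
    if trace.norm_state != "raw":
        raise ValidationError(f"trace already normalized ({trace.norm_state})")
    n = len(trace.f)
    k = int(np.floor(n * tail_frac))
    if k < 1:
        raise ValidationError(
            f"trace too short for tail_frac={tail_frac}: need >= {int(np.ceil(1 / tail_frac))} samples"
        )
    srt = np.sort(trace.f)
    lo = float(srt[:k].mean())
    hi = float(srt[-k:].mean())
    if hi == lo:
        raise ValidationError("degenerate (constant) trace: cannot rescale")
    return FluorTrace(
        t=trace.t.copy(),
        f=(trace.f - lo) / (hi - lo),
        animal_id=trace.animal_id,
        norm_state="dffmax",
        covers_protocol=trace.covers_protocol,
    )


def _require_normalized(trace: FluorTrace) -> None:
    if trace.norm_state == "raw":
        raise ValidationError("trace must be normalized (dff0 or dffmax) first")


def _block_intervals(protocol: StimulusProtocol, conc: float) -> list[tuple[float, float]]:
    ivs = protocol.intervals_at(conc)
    if not ivs:
        raise ValidationError(f"protocol has no odor block at concentration {conc:g} M")
    return ivs


# ---------------------------------------------------------------------------
# per-pulse metrics

def response_magnitude(
    trace: FluorTrace,
    protocol: StimulusProtocol,
    block_concentration: float,
    pre_window_s: float = 2.0,
    late_window_s: float = 10.0,
) -> float:
    """Suppression at the first odor pulse of the block (positive = decrease).

    Mean normalized fluorescence over [onset - pre_window, onset) minus the
    mean over [offset - late_window, offset).
    """
    _require_normalized(trace)
    onset, offset = _block_intervals(protocol, block_concentration)[0]
    if onset - pre_window_s < trace.t[0] or offset > trace.t[-1] + 1.0 / trace.fs:
        raise ValidationError("measurement windows extend outside the trace")
    pre = trace.window_mean(onset - pre_window_s, onset)
    late = trace.window_mean(offset - late_window_s, offset)
    return pre - late


@dataclass
class HalfTime:
    """Recovery half-time: a value, a lower bound, or not computed.

    ``kind`` is ``"value"`` when the half-recovery point was reached,
    ``"lower_bound"`` when fluorescence had not recovered by the end of the
    available window (``value`` is then the window length), and
    ``"not_computed"`` when the evoked suppression was below the responder
    threshold.
    """

    value: float | None
    kind: str  # "value" | "lower_bound" | "not_computed"

    def __post_init__(self) -> None:
        if self.kind not in ("value", "lower_bound", "not_computed"):
            raise ValidationError(f"unknown half-time kind {self.kind!r}")


def recovery_half_time(
    trace: FluorTrace,
    protocol: StimulusProtocol,
    block_concentration: float,
    threshold: float = 0.075,
    window_end: float | None = None,
    pre_window_s: float = 2.0,
) -> HalfTime:
    """Half-time of recovery after the last odor removal of the block.

    Peak magnitude is the pre-pulse baseline minus the minimum fluorescence
    during the pulse (the deepest suppression, not the post-removal
    overshoot).  The half-time is the first time after odor removal at which
    fluorescence reaches baseline - magnitude/2.  ``window_end`` defaults to
    the next odor onset (or the end of the trace).
    """
    _require_normalized(trace)
    onset, offset = _block_intervals(protocol, block_concentration)[-1]
    baseline = trace.window_mean(onset - pre_window_s, onset)
    in_pulse = (trace.t >= onset) & (trace.t < offset)
    if not in_pulse.any():
        raise ValidationError("odor pulse contains no samples")
    magnitude = baseline - float(trace.f[in_pulse].min())
    if magnitude < threshold:
        return HalfTime(value=None, kind="not_computed")
    if window_end is None:
        nxt = protocol.next_onset_after(offset)
        window_end = nxt if nxt is not None else trace.t[-1] + 1.0 / trace.fs
    post = (trace.t >= offset) & (trace.t < window_end)
    if not post.any():
        raise ValidationError("recovery window after odor removal is empty")
    level = baseline - magnitude / 2.0
    recovered = np.flatnonzero(post & (trace.f >= level) & (trace.t >= offset))
    if recovered.size:
        return HalfTime(value=float(trace.t[recovered[0]] - offset), kind="value")
    return HalfTime(value=float(window_end - offset), kind="lower_bound")


@dataclass
class PulseMetrics:
    """Per-animal metrics for one concentration block."""

    concentration: float
    response_magnitude: float
    responded: bool
    half_time: HalfTime | None
    animal_id: str

    def __post_init__(self) -> None:
        if self.half_time is not None and not self.responded:
            raise ValidationError("half_time may only be present for responders")


def pulse_metrics(
    trace: FluorTrace,
    protocol: StimulusProtocol,
    block_concentration: float,
    responder_threshold: float = 0.075,
    pre_window_s: float = 2.0,
    late_window_s: float = 10.0,
) -> PulseMetrics:
    """Response magnitude (first pulse) + recovery half-time (last pulse) for one block."""
    mag = response_magnitude(
        trace, protocol, block_concentration, pre_window_s, late_window_s
    )
    responded = mag >= responder_threshold
    half: HalfTime | None = None
    if responded:
        ht = recovery_half_time(
            trace, protocol, block_concentration, threshold=responder_threshold,
            pre_window_s=pre_window_s,
        )
        half = None if ht.kind == "not_computed" else ht
    return PulseMetrics(
        concentration=block_concentration,
        response_magnitude=mag,
        responded=responded,
        half_time=half,
        animal_id=trace.animal_id,
    )


# ---------------------------------------------------------------------------
# aggregation

def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else np.nan


def aggregate_block(metrics: list[PulseMetrics], min_responder_frac: float = 0.5) -> dict:
    """Cohort summary for one concentration.

    The half-time average is present only when the responder fraction
    reaches ``min_responder_frac``; if any contributing half-time is a lower
    bound the mean carries a lower-bound flag.
    """
    if not metrics:
        raise ValidationError("no metrics to aggregate")
    concs = {m.concentration for m in metrics}
    if len(concs) != 1:
        raise ValidationError("metrics span multiple concentrations")
    mags = np.array([m.response_magnitude for m in metrics])
    frac = float(np.mean([m.responded for m in metrics]))
    row = {
        "concentration": metrics[0].concentration,
        "n": len(metrics),
        "mean_magnitude": float(mags.mean()),
        "sem_magnitude": _sem(mags),
        "responder_frac": frac,
        "suppressed": frac < min_responder_frac,
        "mean_half_time": np.nan,
        "sem_half_time": np.nan,
        "n_half_time": 0,
        "half_time_lower_bound": False,
    }
    hts = [m.half_time for m in metrics if m.half_time is not None]
    if frac >= min_responder_frac and hts:
        vals = np.array([h.value for h in hts])
        row.update(
            mean_half_time=float(vals.mean()),
            sem_half_time=_sem(vals),
            n_half_time=len(vals),
            half_time_lower_bound=any(h.kind == "lower_bound" for h in hts),
        )
    return row


def dose_response_table(
    traces: list[FluorTrace],
    protocol: StimulusProtocol,
    responder_threshold: float = 0.075,
    tail_frac: float = 0.05,
    min_responder_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-cohort dose-response analysis.

    Raw traces are 0-1 normalized (5% tails); per animal and concentration
    the pulse metrics are computed and then aggregated per concentration.
    Returns ``(summary, per_animal)`` tidy tables.
    """
    if not traces:
        raise ValidationError("empty cohort")
    normed = [
        normalize_dffmax(tr, tail_frac) if tr.norm_state == "raw" else tr for tr in traces
    ]
    per_rows = []
    all_metrics: dict[float, list[PulseMetrics]] = {}
    for conc in protocol.concentrations:
        for tr in normed:
            m = pulse_metrics(tr, protocol, conc, responder_threshold)
            all_metrics.setdefault(conc, []).append(m)
            per_rows.append(
                {
                    "animal_id": m.animal_id,
                    "concentration": conc,
                    "response_magnitude": m.response_magnitude,
                    "responded": m.responded,
                    "half_time": np.nan if m.half_time is None else m.half_time.value,
                    "half_time_kind": "absent" if m.half_time is None else m.half_time.kind,
                }
            )
    summary = pd.DataFrame(
        [aggregate_block(ms, min_responder_frac) for _, ms in sorted(all_metrics.items())]
    )
    return summary, pd.DataFrame(per_rows)


def per_concentration_welch(
    naive: pd.DataFrame, conditioned: pd.DataFrame, field: str = "response_magnitude"
) -> pd.DataFrame:
    """Welch t-test of a per-animal metric at each shared concentration.

    Inputs are per-animal tables from :func:`dose_response_table`.  Entries
    with fewer than two finite values per group are omitted with a reason.
    """
    rows = []
    concs = sorted(set(naive["concentration"]) & set(conditioned["concentration"]))
    for c in concs:
        a = naive.loc[naive["concentration"] == c, field].dropna().to_numpy()
        b = conditioned.loc[conditioned["concentration"] == c, field].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"concentration": c, "t": np.nan, "df": np.nan, "p": np.nan,
                 "omitted_reason": f"insufficient n ({len(a)} vs {len(b)})"}
            )
            continue
        r: TestResult = welch_t(a, b)
        rows.append(
            {"concentration": c, "t": r.statistic, "df": r.df, "p": r.p, "omitted_reason": ""}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamic-range shift

def _hill(logc: np.ndarray, amp: float, log_ec50: float, hill: float) -> np.ndarray:
    return amp / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_hill(concentrations, magnitudes) -> dict:
    """Least-squares Hill fit of mean response magnitude vs concentration.

    Returns {'amp', 'ec50', 'hill', 'rss'}; fitting runs in log10
    concentration for conditioning.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(magnitudes, float)
    ok = np.isfinite(c) & np.isfinite(y) & (c > 0)
    c, y = c[ok], y[ok]
    if len(c) < 4:
        raise ValidationError("Hill fit needs at least four concentrations")
    logc = np.log10(c)
    half = max(y.max(), 1e-9) / 2.0
    above = np.flatnonzero(y >= half)
    guess_log_ec50 = logc[above[0]] if above.size else logc.mean()
    p0 = [max(y.max(), 1e-3), guess_log_ec50, 1.0]
    bounds = ([1e-6, logc.min() - 3.0, 0.2], [5.0, logc.max() + 3.0, 5.0])
    popt, _ = scipy.optimize.curve_fit(
        _hill, logc, y, p0=p0, bounds=bounds, maxfev=20000
    )
    rss = float(np.sum((y - _hill(logc, *popt)) ** 2))
    return {"amp": float(popt[0]), "ec50": float(10.0 ** popt[1]), "hill": float(popt[2]), "rss": rss}


@dataclass
class DoseResponseShift:
    """Conditioned/naive fold shifts of the concentration-response curve."""

    detection_threshold_fold: float
    saturation_fold: float
    ec50_fold: float
    naive_fit: dict
    conditioned_fit: dict
    diagnostics: str = ""

    def as_dict(self) -> dict:
        return {
            "detection_threshold_fold": self.detection_threshold_fold,
            "saturation_fold": self.saturation_fold,
            "ec50_fold": self.ec50_fold,
            "naive_ec50": self.naive_fit.get("ec50", np.nan),
            "conditioned_ec50": self.conditioned_fit.get("ec50", np.nan),
            "diagnostics": self.diagnostics,
        }


def _detection_threshold(summary: pd.DataFrame, threshold: float) -> float:
    hit = summary[summary["mean_magnitude"] > threshold]
    if hit.empty:
        return np.nan
    return float(hit["concentration"].min())


def _saturation(summary: pd.DataFrame, plateau: float, frac: float) -> float:
    hit = summary[summary["mean_magnitude"] >= frac * plateau]
    if hit.empty:
        return np.nan
    return float(hit["concentration"].min())


def dynamic_range_shift(
    naive_summary: pd.DataFrame,
    conditioned_summary: pd.DataFrame,
    responder_threshold: float = 0.075,
    plateau_frac: float = 0.9,
) -> DoseResponseShift:
    """Quantify the conditioning-induced displacement of the dose-response curve.

    Detection threshold = lowest concentration whose mean magnitude exceeds
    the responder threshold; saturation = lowest concentration reaching
    ``plateau_frac`` of the fitted Hill plateau; EC50s from the Hill fits.
    All three are reported as conditioned/naive fold ratios.
    """
    for name, tbl in (("naive", naive_summary), ("conditioned", conditioned_summary)):
        if tbl["concentration"].nunique() < 4:
            raise ValidationError(f"{name} table spans fewer than four concentrations")
    diag = []
    fits = {}
    for name, tbl in (("naive", naive_summary), ("conditioned", conditioned_summary)):
        try:
            fits[name] = fit_hill(tbl["concentration"], tbl["mean_magnitude"])
        except (ValidationError, RuntimeError) as e:
            fits[name] = {}
            diag.append(f"{name} Hill fit failed: {e}")
    det_n = _detection_threshold(naive_summary, responder_threshold)
    det_c = _detection_threshold(conditioned_summary, responder_threshold)
    sat_n = (
        _saturation(naive_summary, fits["naive"]["amp"], plateau_frac)
        if fits.get("naive") else np.nan
    )
    sat_c = (
        _saturation(conditioned_summary, fits["conditioned"]["amp"], plateau_frac)
        if fits.get("conditioned") else np.nan
    )
    ec50_fold = (
        fits["conditioned"]["ec50"] / fits["naive"]["ec50"]
        if fits.get("naive") and fits.get("conditioned")
        else np.nan
    )
    return DoseResponseShift(
        detection_threshold_fold=det_c / det_n if det_n and np.isfinite(det_n) else np.nan,
        saturation_fold=sat_c / sat_n if sat_n and np.isfinite(sat_n) else np.nan,
        ec50_fold=float(ec50_fold),
        naive_fit=fits.get("naive", {}),
        conditioned_fit=fits.get("conditioned", {}),
        diagnostics="; ".join(diag),
    )
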