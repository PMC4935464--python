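"""Domain types shared by all pipeline stages.

Conventions used throughout the package:

* all time windows and stimulus intervals are half-open ``[t_start, t_end)``;
  a sample falling exactly on a boundary belongs to the later interval;
* pixel coordinates are 0-based, row-major; ROIs are flat pixel-index arrays;
* concentrations are molar, times are seconds, distances millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "PlateCount",
    "StimulusProtocol",
    "FluorTrace",
    "CellPlaneImage",
    "WormTrack",
]


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class PlateCount:
    """End-point animal counts for one chemotaxis plate.

    ``n_odor``/``n_control`` are animals that reached the odor or the
    solvent-control spot, ``n_other`` left the origin but reached neither,
    ``n_origin`` never left the origin.
    """

    n_odor: int
    n_control: int
    n_other: int
    n_origin: int = 0
    condition: str = "naive"
    group: str = "WT"
    histamine: bool = False
    plate_id: str = ""

    def __post_init__(self) -> None:
        for name in ("n_odor", "n_control", "n_other", "n_origin"):
            v = getattr(self, name)
            if isinstance(v, bool) or (not isinstance(v, (int, np.integer)) and (not float(v).is_integer())):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            v = int(v)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
            setattr(self, name, v)
        self.histamine = bool(self.histamine)

    @property
    def n_total(self) -> int:
        return self.n_odor + self.n_control + self.n_other + self.n_origin

    @property
    def n_outside(self) -> int:
        """Animals that left the origin (the QC denominator)."""
        return self.n_odor + self.n_control + self.n_other


@dataclass
class StimulusProtocol:
    """Ordered stimulus-on intervals: odor pulses or light pulses.

    ``intervals`` holds only the stimulus-on epochs as ``(t_start, t_end,
    level)`` with half-open ``[t_start, t_end)``; the gaps between them are
    buffer / darkness.  For odor protocols ``level`` is the molar
    concentration; for light schedules it is 1.0 (on).
    """

    intervals: list[tuple[float, float, float]]
    kind: str = "odor"  # "odor" | "light"

    def __post_init__(self) -> None:
        if self.kind not in ("odor", "light"):
            raise ValidationError(f"kind must be 'odor' or 'light', got {self.kind!r}")
        ivs = [(float(a), float(b), float(lv)) for a, b, lv in self.intervals]
        prev_end = -np.inf
        for a, b, lv in ivs:
            if b <= a:
                raise ValidationError(f"empty or inverted interval [{a}, {b})")
            if a < prev_end:
                raise ValidationError("intervals must be sorted and non-overlapping")
            if lv < 0:
                raise ValidationError(f"negative stimulus level {lv}")
            prev_end = b
        self.intervals = ivs

    @property
    def span(self) -> float:
        """End time of the last stimulus interval (s)."""
        return self.intervals[-1][1] if self.intervals else 0.0

    @property
    def concentrations(self) -> list[float]:
        """Sorted unique positive stimulus levels."""
        return sorted({lv for _, _, lv in self.intervals if lv > 0})

    def intervals_at(self, level: float, rtol: float = 1e-9) -> list[tuple[float, float]]:
        return [
            (a, b)
            for a, b, lv in self.intervals
            if np.isclose(lv, level, rtol=rtol, atol=0.0)
        ]

    def level_at(self, t: float) -> float:
        """Stimulus level at time t (0 in buffer/darkness); half-open intervals."""
        for a, b, lv in self.intervals:
            if a <= t < b:
                return lv
        return 0.0

    def next_onset_after(self, t: float) -> float | None:
        for a, _, _ in self.intervals:
            if a >= t:
                return a
        return None

    def onsets(self) -> np.ndarray:
        return np.array([a for a, _, _ in self.intervals])

    def offsets(self) -> np.ndarray:
        return np.array([b for _, b, _ in self.intervals])


@dataclass
class FluorTrace:
    """One animal's fluorescence time series.

    ``norm_state`` tracks normalization: ``raw`` → ``dff0`` (divide by a
    baseline sample) or ``raw`` → ``dffmax`` (affine 0–1 rescale by the
    5 %-tail means); re-normalizing an already-normalized trace is refused.
    """

    t: np.ndarray
    f: np.ndarray
    animal_id: str = ""
    norm_state: str = "raw"
    covers_protocol: bool = True

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.f = _as_float_array(self.f, "f")
        if len(self.t) != len(self.f):
            raise ValidationError("t and f must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"time vector not strictly increasing (animal {self.animal_id!r})")
        if self.norm_state not in ("raw", "dff0", "dffmax"):
            raise ValidationError(f"unknown norm_state {self.norm_state!r}")

    @property
    def fs(self) -> float:
        """Sampling rate (Hz), from the median sample interval."""
        if len(self.t) < 2:
            raise ValidationError("trace too short to infer sampling rate")
        return 1.0 / float(np.median(np.diff(self.t)))

    def window_mean(self, t0: float, t1: float) -> float:
        """Mean of f over the half-open time window [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        if not m.any():
            raise ValidationError(f"window [{t0}, {t1}) contains no samples")
        return float(self.f[m].mean())


@dataclass
class CellPlaneImage:
    """Single central-plane image of one neuron with optional ROIs.

    ROIs are flat (row-major, 0-based) pixel indices into ``pixels``; the
    nucleus and cytoplasm ROIs must be disjoint.
    """

    pixels: np.ndarray
    nucleus_roi: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))
    cytoplasm_roi: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"pixels must be a 2-D single plane, got {self.pixels.ndim}-D; "
                "select the central plane upstream"
            )
        if np.any(self.pixels < 0):
            raise ValidationError("pixel intensities must be non-negative")
        n = self.pixels.size
        self.nucleus_roi = np.asarray(self.nucleus_roi, dtype=np.intp).ravel()
        self.cytoplasm_roi = np.asarray(self.cytoplasm_roi, dtype=np.intp).ravel()
        for name, roi in (("nucleus_roi", self.nucleus_roi), ("cytoplasm_roi", self.cytoplasm_roi)):
            if roi.size and (roi.min() < 0 or roi.max() >= n):
                raise ValidationError(f"{name} indices outside the pixel grid")
        if self.nucleus_roi.size and self.cytoplasm_roi.size:
            if np.intersect1d(self.nucleus_roi, self.cytoplasm_roi).size:
                raise ValidationError("nucleus and cytoplasm ROIs overlap")

    @property
    def has_rois(self) -> bool:
        return bool(self.nucleus_roi.size and self.cytoplasm_roi.size)


@dataclass
class WormTrack:
    """One animal's centroid trajectory plus derived reversal-onset times."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.events = _as_float_array(self.events, "events")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValidationError("time vector not strictly increasing")
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValidationError("event times must be strictly increasing")
            if self.events[0] < self.t[0] or self.events[-1] > self.t[-1]:
                raise ValidationError("event times outside the track span")
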