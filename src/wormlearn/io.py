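"""File readers/writers, analysis configuration, and run provenance.

CSV dialect everywhere: comma-separated, UTF-8, '.' decimal, header required.
Images are single-plane TIFF or a numeric CSV matrix; ROI sidecars are JSON
files holding explicit flat pixel-index lists (row-major, 0-based).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    CellPlaneImage,
    FluorTrace,
    PlateCount,
    StimulusProtocol,
    ValidationError,
    WormTrack,
)

logger = logging.getLogger("wormlearn")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class FormatError(ValueError):
    """A file did not match the expected layout."""


# ---------------------------------------------------------------------------
# configuration

#: Analysis constants with their defaults.  Windows are in seconds; the
#: responder threshold is on the 0–1 normalized-fluorescence scale.
DEFAULT_CONFIG: dict = {
    "responder_threshold": 0.075,  # minimum suppression to count as a response
    "tail_frac": 0.05,             # tail fraction for the 0-1 normalization
    "min_responder_frac": 0.5,     # cohort fraction needed to average half-times
    "baseline_t": 1700.0,          # absolute time (s) of the dF/F0 baseline sample
    "pre_window_s": 2.0,           # pre-odor baseline window
    "late_window_s": 10.0,         # end-of-pulse window for response magnitude
    "fs": 10.0,                    # imaging sampling rate (Hz); not stated, exposed here
    "min_outside": 50,             # plate QC: minimum animals outside the origin
    "angle_threshold_deg": 150.0,  # heading change that defines a reversal
    "min_rev_duration_s": 1.0,     # reversal persistence requirement
    "refractory_s": 2.0,           # minimum separation of distinct reversal events
    "stim_window_s": 20.0,         # during/after counting window
    "analyzed_pulses": [6, 7, 8, 9, 10],  # 1-based pulse indices analyzed
    "nuclear_index_form": "ratio",  # "ratio" | "contrast"
    "background_subtract": False,   # subtract off-cell median before ROI means
    "seed": 0,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default analysis constants with a YAML config file.

    Returns the merged dict plus a ``"_provenance"`` entry mapping every key
    to ``"default"`` or ``"user"``.  Unknown keys are an error.
    """
    merged = dict(DEFAULT_CONFIG)
    prov = {k: "default" for k in DEFAULT_CONFIG}
    user: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        user.update(loaded or {})
    if overrides:
        user.update(overrides)
    unknown = sorted(set(user) - set(DEFAULT_CONFIG))
    if unknown:
        raise FormatError(
            f"unknown config key(s) {unknown}; valid keys: {sorted(DEFAULT_CONFIG)}"
        )
    for k, v in user.items():
        merged[k] = v
        prov[k] = "user"
    for k in sorted(merged):
        logger.debug("config %s = %r (%s)", k, merged[k], prov[k])
    merged["_provenance"] = prov
    return merged


def config_hash(config: dict) -> str:
    """Stable short hash of a config (provenance entry excluded)."""
    clean = {k: v for k, v in config.items() if not k.startswith("_")}
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(path: str | Path, config: dict, seed: int, outputs: list[str]) -> None:
    """JSON run manifest: config hash, seed, package versions, output files."""
    import wormlearn

    manifest = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "config": {k: v for k, v in config.items() if not k.startswith("_")},
        "outputs": sorted(outputs),
        "versions": {
            "wormlearn": wormlearn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# plate counts

_PLATE_COLUMNS = ["n_odor", "n_control", "n_other", "n_origin", "condition", "group", "histamine"]


def read_plate_counts(path: str | Path) -> list[PlateCount]:
    """Read one PlateCount per CSV row; counts validated as non-negative ints."""
    df = pd.read_csv(path)
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate-count file {path} missing column(s) {missing}")
    plates = []
    for i, row in df.iterrows():
        try:
            plates.append(
                PlateCount(
                    n_odor=row["n_odor"],
                    n_control=row["n_control"],
                    n_other=row["n_other"],
                    n_origin=row["n_origin"],
                    condition=str(row["condition"]),
                    group=str(row["group"]),
                    histamine=_parse_bool(row["histamine"]),
                    plate_id=str(row["plate_id"]) if "plate_id" in df.columns else f"plate{i}",
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {i} of {path}: {e}") from e
    return plates


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise ValidationError(f"cannot parse boolean {v!r}")
    return bool(v)


def write_plate_counts(path: str | Path, plates: list[PlateCount]) -> None:
    pd.DataFrame(
        [
            {
                "n_odor": p.n_odor,
                "n_control": p.n_control,
                "n_other": p.n_other,
                "n_origin": p.n_origin,
                "condition": p.condition,
                "group": p.group,
                "histamine": p.histamine,
                "plate_id": p.plate_id,
            }
            for p in plates
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fluorescence traces

def read_traces(path: str | Path, protocol: StimulusProtocol | None = None) -> list[FluorTrace]:
    """Read long-format (animal_id, t, f) CSV into one raw FluorTrace per animal.

    A trace ending before the protocol span is retained with
    ``covers_protocol=False`` and a logged warning; non-monotone or duplicated
    timestamps within an animal are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("animal_id", "t", "f") if c not in df.columns]
    if missing:
        raise FormatError(f"trace file {path} missing column(s) {missing}")
    traces = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("t")
        t = g["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"animal {animal_id!r}: duplicated or non-monotone timestamps")
        tr = FluorTrace(t=t, f=g["f"].to_numpy(float), animal_id=str(animal_id))
        if protocol is not None and len(t) and t[-1] < protocol.span:
            tr.covers_protocol = False
            msg = f"animal {animal_id!r}: trace ends at {t[-1]:g} s, before protocol span {protocol.span:g} s"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        traces.append(tr)
    return traces


def write_traces(path: str | Path, traces: list[FluorTrace]) -> None:
    frames = [
        pd.DataFrame({"animal_id": tr.animal_id, "t": tr.t, "f": tr.f}) for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cell images

def read_cell_image(path: str | Path, roi_sidecar: str | Path | None = None) -> CellPlaneImage:
    """Read a single-plane TIFF or numeric CSV matrix; ROIs from a JSON sidecar.

    If ``roi_sidecar`` is None, ``<path>.roi.json`` is used when present.
    Multi-plane TIFF stacks are refused.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        try:
            arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
        except ValueError as e:
            raise FormatError(f"{path}: non-numeric pixel data ({e})") from e
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single plane, got shape {arr.shape}; "
            "select the central plane upstream"
        )
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric pixels")
    nucleus = np.array([], dtype=np.intp)
    cytoplasm = np.array([], dtype=np.intp)
    sidecar = Path(roi_sidecar) if roi_sidecar is not None else path.with_suffix(path.suffix + ".roi.json")
    if sidecar.exists():
        rois = json.loads(sidecar.read_text())
        nucleus = np.asarray(rois.get("nucleus", []), dtype=np.intp)
        cytoplasm = np.asarray(rois.get("cytoplasm", []), dtype=np.intp)
    return CellPlaneImage(pixels=arr.astype(float), nucleus_roi=nucleus, cytoplasm_roi=cytoplasm)


def write_cell_image(path: str | Path, image: CellPlaneImage) -> None:
    """Write pixels as TIFF or CSV matrix plus a ROI sidecar when ROIs are set."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        pd.DataFrame(image.pixels).to_csv(path, index=False, header=False)
    if image.has_rois:
        sidecar = path.with_suffix(path.suffix + ".roi.json")
        sidecar.write_text(
            json.dumps(
                {
                    "nucleus": image.nucleus_roi.tolist(),
                    "cytoplasm": image.cytoplasm_roi.tolist(),
                }
            )
        )


# ---------------------------------------------------------------------------
# worm tracks

def read_tracks(path: str | Path) -> list[WormTrack]:
    """Read long-format (trial_id, animal_id, t, x, y) centroid tracks."""
    df = pd.read_csv(path)
    missing = [c for c in ("animal_id", "t", "x", "y") if c not in df.columns]
    if missing:
        raise FormatError(f"track file {path} missing column(s) {missing}")
    if "trial_id" not in df.columns:
        df = df.assign(trial_id="trial0")
    tracks = []
    for (trial_id, animal_id), g in df.groupby(["trial_id", "animal_id"], sort=True):
        g = g.sort_values("t")
        tracks.append(
            WormTrack(
                t=g["t"].to_numpy(float),
                x=g["x"].to_numpy(float),
                y=g["y"].to_numpy(float),
                trial_id=str(trial_id),
                animal_id=str(animal_id),
            )
        )
    return tracks


def write_tracks(path: str | Path, tracks: list[WormTrack]) -> None:
    frames = [
        pd.DataFrame(
            {"trial_id": tr.trial_id, "animal_id": tr.animal_id, "t": tr.t, "x": tr.x, "y": tr.y}
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# protocols

def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    return {
        "kind": protocol.kind,
        "intervals": [list(iv) for iv in protocol.intervals],
    }


def read_protocol(path: str | Path) -> StimulusProtocol:
    """Read a stimulus protocol from a YAML/JSON description."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if "intervals" not in d:
        raise FormatError(f"protocol file {path} lacks an 'intervals' entry")
    return StimulusProtocol(
        intervals=[tuple(iv) for iv in d["intervals"]], kind=d.get("kind", "odor")
    )


def write_protocol(path: str | Path, protocol: StimulusProtocol) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol)))
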