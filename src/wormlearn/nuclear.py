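"""EGL-4 nuclear-enrichment quantification and distribution comparison.

The nuclear index of a cell is mean nuclear over mean cytoplasmic
fluorescence of the same neuron (a ratio > 1 indicates nuclear enrichment);
condition distributions are compared as ECDFs with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stats import ks_asymptotic_p
from .types import CellPlaneImage, ValidationError

__all__ = [
    "roi_mean_fluorescence",
    "auto_rois",
    "nuclear_index",
    "nuclear_index_of_image",
    "Ecdf",
    "ecdf",
    "ks_two_sample",
]


def roi_mean_fluorescence(image: CellPlaneImage, roi: str) -> float:
    """Arithmetic mean pixel intensity over the named ROI ('nucleus' | 'cytoplasm')."""
    if roi not in ("nucleus", "cytoplasm"):
        raise ValidationError(f"unknown ROI {roi!r}")
    idx = image.nucleus_roi if roi == "nucleus" else image.cytoplasm_roi
    if idx.size == 0:
        raise ValidationError(f"{roi} ROI is empty")
    return float(image.pixels.ravel()[idx].mean())


def auto_rois(image: CellPlaneImage) -> CellPlaneImage:
    """Segment cell and nucleus by two rounds of Otsu thresholding.

    The cell is the largest connected component above a global Otsu
    threshold (holes filled); the nucleus is the brightest concentric
    subregion found by a second Otsu threshold restricted to cell pixels;
    the cytoplasm is the cell minus the nucleus.  Deterministic.  Images
    whose ROIs are already set are returned unchanged.
    """
    if image.has_rois:
        return image
    px = image.pixels
    if np.ptp(px) == 0:
        raise ValidationError("blank image: no foreground found")
    thr = threshold_otsu(px)
    fg = px > thr
    if not fg.any():
        raise ValidationError("no foreground found above the Otsu threshold")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(px), labels, index=np.arange(1, n + 1))
    cell = ndimage.binary_fill_holes(labels == (1 + int(np.argmax(sizes))))
    inside = px[cell]
    if np.ptp(inside) == 0:
        # flat cell: no distinguishable nucleus
        raise ValidationError("cell has uniform intensity; cannot separate a nucleus")
    thr2 = threshold_otsu(inside)
    nucleus = cell & (px > thr2)
    nucleus = ndimage.binary_fill_holes(nucleus)
    if not nucleus.any() or nucleus.sum() == cell.sum():
        raise ValidationError("could not separate a nuclear subregion")
    cytoplasm = cell & ~nucleus
    return CellPlaneImage(
        pixels=px,
        nucleus_roi=np.flatnonzero(nucleus.ravel()),
        cytoplasm_roi=np.flatnonzero(cytoplasm.ravel()),
    )


def nuclear_index(f_nucleus: float, f_cytoplasm: float, form: str = "ratio") -> float:
    """Degree of nuclear localization from the two ROI means.

    ``ratio``: F_nucleus / F_cytoplasm (default); ``contrast``:
    (F_n - F_c) / (F_n + F_c).  Both increase with nuclear enrichment and
    are invariant to rescaling the whole image.
    """
    if f_cytoplasm <= 0:
        raise ValidationError("cytoplasmic fluorescence must be positive; record flagged")
    if form == "ratio":
        return f_nucleus / f_cytoplasm
    if form == "contrast":
        return (f_nucleus - f_cytoplasm) / (f_nucleus + f_cytoplasm)
    raise ValidationError(f"unknown nuclear-index form {form!r}")


def nuclear_index_of_image(
    image: CellPlaneImage,
    form: str = "ratio",
    background_subtract: bool = False,
) -> float:
    """ROI means -> nuclear index; optionally subtract the off-cell median first."""
    img = image if image.has_rois else auto_rois(image)
    fn = roi_mean_fluorescence(img, "nucleus")
    fc = roi_mean_fluorescence(img, "cytoplasm")
    if background_subtract:
        mask = np.ones(img.pixels.size, dtype=bool)
        mask[img.nucleus_roi] = False
        mask[img.cytoplasm_roi] = False
        bg = float(np.median(img.pixels.ravel()[mask])) if mask.any() else 0.0
        fn, fc = fn - bg, fc - bg
    return nuclear_index(fn, fc, form=form)


@dataclass
class Ecdf:
    """Right-continuous empirical CDF with sorted support and cumulative fractions."""

    support: np.ndarray
    fractions: np.ndarray

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.support, np.asarray(x, float), side="right")
        out = np.concatenate([[0.0], self.fractions])[idx]
        return out if out.ndim else float(out)


def ecdf(values) -> Ecdf:
    """ECDF of a sample; ties collapse to a single jump of height k/n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(v, return_counts=True)
    return Ecdf(support=support, fractions=np.cumsum(counts) / v.size)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a - ECDF_b|, asymptotic p.

    Warns when either sample has fewer than 5 observations (the asymptotic
    p-value is unreliable there).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if min(a.size, b.size) < 5:
        warnings.warn("KS asymptotic p-value unreliable for n < 5", stacklevel=2)
    fa, fb = ecdf(a), ecdf(b)
    pooled = np.union1d(fa.support, fb.support)
    D = float(np.max(np.abs(fa(pooled) - fb(pooled))))
    return D, ks_asymptotic_p(D, a.size, b.size)
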