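"""Lung parenchyma isolation from a normalized chest volume.

The stage follows a fixed order: 256-bin histogram, minimum-error
(Kittler-Illingworth) threshold, per-slice removal of dark components
touching the in-plane border (background air, scanner bed), retention of
the one or two largest 3D components (the lungs), then per-slice pleural
closing and hole filling so bright structures — vessels, and in particular
nodules attached to the pleura — end up inside the lung mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .volume_io import CTVolume

__all__ = [
    "LungMask",
    "LungExtractionError",
    "histogram256",
    "minimum_error_threshold",
    "fill_holes",
    "extract_lungs",
]

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)
# variance floor for single-bin classes: variance of a uniform spread within one bin
_VAR_FLOOR = 1.0 / 12.0


class LungExtractionError(RuntimeError):
    pass


@dataclass
class LungMask:
    """Binary lung mask aligned to its source volume."""

    mask: np.ndarray
    threshold_used: float
    components_kept: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components_kept not in (1, 2):
            raise ValueError(f"components_kept must be 1 or 2, got {self.components_kept}")


def histogram256(volume: CTVolume) -> np.ndarray:
    """256-bin intensity histogram over [0, 255]; counts sum to voxel count.

    Intensities are rounded to the nearest integer level and clipped into
    [0, 255], so the histogram is exact for 8-bit-like data.
    """
    levels = np.clip(np.rint(volume.intensities), 0, 255).astype(np.int64)
    return np.bincount(levels.ravel(), minlength=256)


def minimum_error_criterion(hist: np.ndarray, t: int) -> float:
    """Kittler-Illingworth criterion J(t) for the split {bins < t | bins >= t}.

    J(t) = 1 + 2[P1 ln s1 + P2 ln s2] - 2[P1 ln P1 + P2 ln P2],
    with class priors P, standard deviations s estimated from the histogram.
    Zero-variance (single-spike) classes use a quarter-bin variance floor.
    """
    hist = np.asarray(hist, dtype=np.float64)
    g = np.arange(hist.size, dtype=np.float64)
    w1, w2 = hist[:t], hist[t:]
    n1, n2 = w1.sum(), w2.sum()
    if n1 == 0 or n2 == 0:
        return np.inf
    total = n1 + n2
    p1, p2 = n1 / total, n2 / total
    mu1 = (w1 * g[:t]).sum() / n1
    mu2 = (w2 * g[t:]).sum() / n2
    var1 = max((w1 * (g[:t] - mu1) ** 2).sum() / n1, _VAR_FLOOR)
    var2 = max((w2 * (g[t:] - mu2) ** 2).sum() / n2, _VAR_FLOOR)
    return float(
        1.0
        + p1 * np.log(var1) + p2 * np.log(var2)
        - 2.0 * (p1 * np.log(p1) + p2 * np.log(p2))
    )


def minimum_error_threshold(hist: np.ndarray) -> int:
    """Exhaustive minimum-error threshold search over a 256-bin histogram.

    Returns the threshold t* minimizing J(t); voxels with level < t* belong
    to the dark (air/lung) class. Ties break toward the smaller t. Requires
    at least two nonzero bins (a unimodal histogram has no valid split).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if (hist > 0).sum() < 2:
        raise LungExtractionError(
            "histogram has fewer than 2 nonzero bins; no bimodal split exists")
    best_t, best_j = None, np.inf
    for t in range(1, hist.size):
        j = minimum_error_criterion(hist, t)
        if j < best_j:
            best_t, best_j = t, j
    return int(best_t)


def fill_holes(slice_mask: np.ndarray) -> np.ndarray:
    """Fill 2D holes: background regions not 4-connected to the slice border.

    Monotone (output is a superset of the input) and idempotent.
    """
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if slice_mask.ndim != 2:
        raise ValueError(f"expected 2D mask, got ndim={slice_mask.ndim}")
    return ndimage.binary_fill_holes(slice_mask)


def _clear_border_slices(dark: np.ndarray) -> np.ndarray:
    """Remove, per slice, dark components touching the in-plane border."""
    out = np.empty_like(dark)
    for k in range(dark.shape[0]):
        out[k] = segmentation.clear_border(dark[k])
    return out


def extract_lungs(volume: CTVolume, closing_radius_mm: float = 7.0,
                  second_lung_min_fraction: float = 0.10) -> LungMask:
    """Isolate the lung region of a normalized chest volume.

    Steps: (1) binarize at the minimum-error threshold, dark side = air;
    (2) per slice, drop dark components touching the in-plane border;
    (3) keep the largest 3D component plus the second-largest if it holds at
    least ``second_lung_min_fraction`` of the largest's volume (two separate
    lungs vs. one fused region); (4) close the pleural surface with a disk of
    ``closing_radius_mm`` per slice (the radius should be at least half the
    widest expected pleural notch, i.e. about the largest nodule radius of
    interest), then fill holes slice-wise, so vessels
    and pleura-attached nodules are folded back into the mask.
    """
    if volume.intensity_scale != "normalized8bit":
        raise ValueError("extract_lungs expects a normalized volume "
                         "(use volume_io.normalize_volume first)")
    hist = histogram256(volume)
    t_star = minimum_error_threshold(hist)
    dark = volume.intensities < t_star

    interior = _clear_border_slices(dark)
    labels, n_labels = ndimage.label(interior, structure=_CONN26)
    if n_labels == 0:
        raise LungExtractionError("no lungs detected")
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    keep = [order[0] + 1]
    if n_labels > 1 and sizes[order[1]] >= second_lung_min_fraction * sizes[order[0]]:
        keep.append(order[1] + 1)
    mask = np.isin(labels, keep)
    logger.info("lung extraction: t*=%d, %d component(s) kept of %d (sizes %s)",
                t_star, len(keep), n_labels, sizes[order[:3]].tolist())

    dy = volume.spacing_mm[1]
    radius_px = int(np.ceil(closing_radius_mm / dy))
    footprint = morphology.disk(radius_px) if radius_px >= 1 else None
    filled = np.empty_like(mask)
    for k in range(mask.shape[0]):
        sl = mask[k]
        if footprint is not None and sl.any():
            sl = morphology.closing(sl, footprint)
        filled[k] = fill_holes(sl)
    return LungMask(filled, float(t_star), len(keep))
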