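"""Candidate generation: per-slice structure filtering, 3D grouping, blob
shape discrimination.

The 2D stage thresholds bright structures inside the lung mask slice by
slice (8-connectivity in-plane), keeping only structures that pass BOTH an
area floor — the equatorial cross-section of the smallest nodule of
interest, 4 mm diameter by default — and a mean-intensity floor. The
surviving pixels are regrouped in 3D with 26-connectivity, and each
component is scored for sphericity and width to discriminate compact
nodule-like blobs from residual tubular vessel fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .volume_io import CTVolume

__all__ = [
    "SliceStructure",
    "Candidate",
    "label_slice_structures",
    "filter_slice_structures",
    "area_floor_from_spacing",
    "structure_threshold",
    "segment_structures",
    "label_components_26",
    "blob_scores",
    "discriminate_candidates",
]

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SliceStructure:
    """One 2D connected bright structure on a single slice."""

    slice_index: int
    pixel_set: np.ndarray  # (N, 2) array of (y, x)
    area_px: int
    mean_intensity: float

    def __post_init__(self) -> None:
        self.pixel_set = np.asarray(self.pixel_set, dtype=np.int64).reshape(-1, 2)
        if self.area_px != len(self.pixel_set) or self.area_px < 1:
            raise ValueError("area_px must equal |pixel_set| and be >= 1")


@dataclass
class Candidate:
    """One 26-connected 3D structure with blob shape scores.

    ``bbox_mm`` holds the (z, y, x) bounding-box edge lengths
    (LBB, WBB, HBB), each computed as (index extent + 1) x spacing.
    """

    id: int
    voxel_set: np.ndarray  # (N, 3) array of (z, y, x)
    bbox_mm: tuple[float, float, float]
    centroid_mm: tuple[float, float, float]
    sphericity: float
    width_mm: float
    volume_mm3: float

    def __post_init__(self) -> None:
        self.voxel_set = np.asarray(self.voxel_set, dtype=np.int64).reshape(-1, 3)
        if len(self.voxel_set) == 0:
            raise ValueError("candidate voxel_set is empty")

    @property
    def voxel_count(self) -> int:
        return len(self.voxel_set)

    @property
    def elongation(self) -> float:
        return max(self.bbox_mm) / min(self.bbox_mm)


def area_floor_from_spacing(spacing_mm, min_diameter_mm: float = 4.0) -> int:
    """Pixel-count floor: the equatorial cross-section of the smallest
    nodule of interest, ceil(pi (d/2)^2 / (dy dx))."""
    _, dy, dx = spacing_mm
    if min_diameter_mm <= 0:
        return 0
    return int(math.ceil(math.pi * (min_diameter_mm / 2.0) ** 2 / (dy * dx)))


def structure_threshold(volume: CTVolume, lung_mask: np.ndarray) -> float:
    """Scan-level bright-structure threshold: Otsu over lung-interior voxels."""
    values = volume.intensities[lung_mask]
    if values.size == 0:
        raise ValueError("empty lung mask")
    if np.ptp(values) == 0:
        return float(values.flat[0]) + 1.0  # constant interior: no structures
    return float(filters.threshold_otsu(values))


def label_slice_structures(slice_image: np.ndarray, lung_mask_slice: np.ndarray,
                           threshold: float) -> list[SliceStructure]:
    """Label bright structures (>= threshold) inside the lung mask of one
    slice, 8-connectivity, with per-structure area and mean intensity."""
    slice_image = np.asarray(slice_image)
    lung_mask_slice = np.asarray(lung_mask_slice, dtype=bool)
    if slice_image.shape != lung_mask_slice.shape:
        raise ValueError(
            f"slice shape {slice_image.shape} != mask shape {lung_mask_slice.shape}")
    bright = (slice_image >= threshold) & lung_mask_slice
    labels = measure.label(bright, connectivity=2)
    structures = []
    for region in measure.regionprops(labels, intensity_image=slice_image):
        structures.append(SliceStructure(
            slice_index=-1,
            pixel_set=region.coords,
            area_px=int(region.area),
            mean_intensity=float(region.intensity_mean),
        ))
    return structures


def filter_slice_structures(structures: list[SliceStructure], area_min_px: int,
                            intensity_min: float) -> list[SliceStructure]:
    """Keep structures where BOTH indicators agree: area >= area_min_px AND
    mean intensity >= intensity_min. Rejections are logged with the failing
    indicator."""
    kept = []
    for s in structures:
        if s.area_px < area_min_px:
            logger.debug("slice %d: structure rejected on area (%d < %d px)",
                         s.slice_index, s.area_px, area_min_px)
        elif s.mean_intensity < intensity_min:
            logger.debug("slice %d: structure rejected on intensity (%.1f < %.1f)",
                         s.slice_index, s.mean_intensity, intensity_min)
        else:
            kept.append(s)
    return kept


def segment_structures(volume: CTVolume, lung_mask: np.ndarray,
                       min_diameter_mm: float = 4.0,
                       intensity_min: float | None = None,
                       threshold: float | None = None):
    """Run the 2D stage over every slice; returns the surviving binary
    volume and a per-stage count log.

    ``threshold`` defaults to the scan-level Otsu value over lung-interior
    intensities; ``intensity_min`` defaults to that same threshold (the
    mean of a true bright structure sits above it).
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != volume.shape:
        raise ValueError("lung mask shape mismatch")
    if threshold is None:
        threshold = structure_threshold(volume, lung_mask)
    if intensity_min is None:
        intensity_min = threshold
    area_min = area_floor_from_spacing(volume.spacing_mm, min_diameter_mm)

    surviving = np.zeros(volume.shape, dtype=bool)
    n_before = n_after = 0
    for k in range(volume.shape[0]):
        structs = label_slice_structures(volume.intensities[k], lung_mask[k], threshold)
        for s in structs:
            s.slice_index = k
        n_before += len(structs)
        kept = filter_slice_structures(structs, area_min, intensity_min)
        n_after += len(kept)
        for s in kept:
            surviving[k, s.pixel_set[:, 0], s.pixel_set[:, 1]] = True
    log = {"threshold": float(threshold), "area_min_px": int(area_min),
           "intensity_min": float(intensity_min),
           "structures_before": int(n_before), "structures_after": int(n_after)}
    logger.info("2D stage: %(structures_before)d structures -> %(structures_after)d "
                "(threshold %(threshold).1f, area >= %(area_min_px)d px)", log)
    return surviving, log


def blob_scores(voxel_set: np.ndarray, spacing_mm) -> tuple[float, float]:
    """Sphericity and width of a voxel set.

    Sphericity is the component volume divided by the volume of the sphere
    whose radius is the maximum centroid-to-voxel-center distance, clipped
    to (0, 1]; width is the smallest bounding-box edge in mm. A single voxel
    scores sphericity 1 (its radius degenerates to half the largest spacing).
    """
    if hasattr(voxel_set, "voxel_set"):  # accept a Candidate directly
        voxel_set = voxel_set.voxel_set
    voxels = np.asarray(voxel_set, dtype=np.float64).reshape(-1, 3)
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    mm = voxels * spacing
    extent = voxels.max(axis=0) - voxels.min(axis=0)
    edges = (extent + 1) * spacing
    width = float(edges.min())
    volume = len(voxels) * float(spacing.prod())
    if len(voxels) == 1:
        return 1.0, width
    centroid = mm.mean(axis=0)
    r_max = float(np.sqrt(((mm - centroid) ** 2).sum(axis=1)).max())
    if r_max == 0.0:
        return 1.0, width
    sphericity = volume / (4.0 / 3.0 * math.pi * r_max ** 3)
    return float(np.clip(sphericity, np.finfo(float).tiny, 1.0)), width


def label_components_26(binary_volume: np.ndarray, spacing_mm=(1.0, 1.0, 1.0),
                        origin_mm=(0.0, 0.0, 0.0)) -> list["Candidate"]:
    """Partition the foreground into maximal 26-connected components.

    Candidate ids follow the ascending (z, y, x) lexicographic order of each
    component's first voxel, so the output is deterministic.
    """
    binary_volume = np.asarray(binary_volume, dtype=bool)
    labels, n_labels = ndimage.label(binary_volume, structure=_CONN26)
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    origin = np.asarray(origin_mm, dtype=np.float64)
    objects = ndimage.find_objects(labels)
    raw = []
    for lab in range(1, n_labels + 1):
        sl = objects[lab - 1]
        local = np.argwhere(labels[sl] == lab)
        voxels = local + np.array([s.start for s in sl])
        raw.append(voxels)
    # scipy assigns labels in raster order already; sort defensively anyway
    raw.sort(key=lambda v: tuple(v[0]))
    candidates = []
    for cid, voxels in enumerate(raw):
        sphericity, width = blob_scores(voxels, spacing)
        extent = voxels.max(axis=0) - voxels.min(axis=0)
        edges = tuple(float(e) for e in (extent + 1) * spacing)
        centroid = tuple(float(c) for c in origin + voxels.mean(axis=0) * spacing)
        candidates.append(Candidate(
            id=cid, voxel_set=voxels, bbox_mm=edges, centroid_mm=centroid,
            sphericity=sphericity, width_mm=width,
            volume_mm3=len(voxels) * float(spacing.prod()),
        ))
    return candidates


def discriminate_candidates(candidates: list[Candidate],
                            sphericity_min: float = 0.15,
                            width_min_mm: float = 2.5,
                            width_max_mm: float | None = None,
                            elongation_max: float = 4.0) -> list[Candidate]:
    """Blob discrimination: keep candidates that are compact (sphericity),
    wide enough to be a nodule of interest, and not tube-like (elongation).
    Each rejection is logged with the failing test.

    The default width floor equals a typical slice thickness: a bounding
    box is quantized to whole slices, so any stricter floor would reject
    every single-slice candidate regardless of its in-plane size."""
    kept = []
    for c in candidates:
        if c.sphericity < sphericity_min:
            logger.debug("candidate %d rejected on sphericity (%.3f < %.3f)",
                         c.id, c.sphericity, sphericity_min)
        elif c.width_mm < width_min_mm:
            logger.debug("candidate %d rejected on width (%.2f < %.2f mm)",
                         c.id, c.width_mm, width_min_mm)
        elif width_max_mm is not None and c.width_mm > width_max_mm:
            logger.debug("candidate %d rejected on width (%.2f > %.2f mm)",
                         c.id, c.width_mm, width_max_mm)
        elif c.elongation > elongation_max:
            logger.debug("candidate %d rejected on elongation (%.2f > %.2f)",
                         c.id, c.elongation, elongation_max)
        else:
            kept.append(c)
    return kept
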