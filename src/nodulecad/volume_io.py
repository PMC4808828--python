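"""Volume input/output and the common in-memory CT representation.

Arrays are indexed ``(z, y, x)`` with z the slice axis. Physical coordinates
follow the voxel-center convention: ``mm = origin_mm + index * spacing_mm``
per axis. DICOM series are read as single-frame CT slices and converted to
Hounsfield units via each file's linear rescale; NIfTI volumes are read and
written with an affine built from the voxel spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "read_dicom_series",
    "read_nifti",
    "write_volume_nifti",
    "write_mask_nifti",
    "normalize_volume",
]


@dataclass
class CTVolume:
    """A 3D intensity grid ``I(z, y, x)`` with per-axis spacing in mm.

    Parameters
    ----------
    intensities
        3D array indexed ``(z, y, x)``.
    spacing_mm
        ``(dz, dy, dx)`` voxel spacing, all positive.
    origin_mm
        Physical position of voxel ``(0, 0, 0)``, in ``(z, y, x)`` order.
    intensity_scale
        ``"HU"`` for calibrated Hounsfield units, ``"normalized8bit"`` after
        min-max normalization to ``[0, 255]``.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_scale: str = "HU"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x), got ndim={self.intensities.ndim}"
            )
        if self.intensities.size == 0:
            raise ValueError("intensities grid is empty")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if self.intensity_scale not in ("HU", "normalized8bit"):
            raise ValueError(f"unknown intensity_scale {self.intensity_scale!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx

    def index_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (z, y, x) to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)


def _slice_position(ds: pydicom.Dataset) -> float:
    if "ImagePositionPatient" in ds:
        return float(ds.ImagePositionPatient[2])
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    if "InstanceNumber" in ds:
        return float(ds.InstanceNumber)
    raise ValueError(
        "cannot order slices: ImagePositionPatient, SliceLocation and "
        "InstanceNumber are all missing"
    )


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read a single-frame CT DICOM series from ``directory`` into HU.

    Slices are sorted by position along the slice axis; raw stored values are
    converted to Hounsfield units with each file's RescaleSlope/Intercept.

    Raises
    ------
    ValueError
        If the directory holds mixed series, or a required spacing tag
        (PixelSpacing, or any way to derive the slice increment) is missing.
    """
    directory = os.fspath(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    datasets = []
    for p in paths:
        if os.path.isdir(p):
            continue
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue  # non-DICOM clutter in the directory
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory!r}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series: {sorted(uids)}")

    datasets.sort(key=_slice_position)

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError("missing spacing tag PixelSpacing (0028,0030)")
    dy, dx = (float(v) for v in first.PixelSpacing)

    if len(datasets) > 1:
        positions = [_slice_position(ds) for ds in datasets]
        dz = float(np.median(np.abs(np.diff(positions))))
        if dz <= 0:
            dz = None
    else:
        dz = None
    if dz is None:
        for tag in ("SpacingBetweenSlices", "SliceThickness"):
            if tag in first:
                dz = float(getattr(first, tag))
                break
    if dz is None or dz <= 0:
        raise ValueError(
            "missing spacing tag: cannot derive slice increment from positions, "
            "SpacingBetweenSlices (0018,0088) or SliceThickness (0018,0050)"
        )

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    volume = np.stack(slices, axis=0)

    if "ImagePositionPatient" in first:
        ipp = first.ImagePositionPatient
        origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    else:
        origin = (0.0, 0.0, 0.0)
    return CTVolume(volume, (dz, dy, dx), origin, intensity_scale="HU")


def read_nifti(path: str | os.PathLike) -> CTVolume:
    """Read a 3D NIfTI volume into the (z, y, x) convention."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path!r}")
    # NIfTI stores (x, y, z); transpose to (z, y, x).
    data = np.ascontiguousarray(np.transpose(data, (2, 1, 0)).astype(np.float64))
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]  # (x, y, z) translation
    origin = (float(t[2]), float(t[1]), float(t[0]))
    return CTVolume(data, spacing, origin, intensity_scale="HU")


def _affine_from(volume: CTVolume) -> np.ndarray:
    dz, dy, dx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    return affine


def write_volume_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume as NIfTI-1; round-trips grid and spacing exactly."""
    data = np.transpose(volume.intensities, (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine_from(volume)), os.fspath(path))


def write_mask_nifti(mask: np.ndarray, like: CTVolume, path: str | os.PathLike) -> None:
    """Write a binary mask aligned to ``like`` as uint8 NIfTI."""
    mask = np.asarray(mask)
    if mask.shape != like.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {like.shape}")
    data = np.transpose(mask.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine_from(like)), os.fspath(path))


def normalize_volume(volume: CTVolume) -> CTVolume:
    """Linear min-max rescale of the intensities to [0, 255].

    Constant volumes map to all zeros. The result is tagged
    ``normalized8bit``; thresholding operates on this scale.
    """
    data = volume.intensities.astype(np.float64)
    lo = float(data.min())
    hi = float(data.max())
    if hi > lo:
        data = (data - lo) * (255.0 / (hi - lo))
    else:
        data = np.zeros_like(data)
    return replace(volume, intensities=data, intensity_scale="normalized8bit")
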