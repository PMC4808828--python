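"""Synthetic thoracic CT phantoms with voxel-exact ground truth.

A phantom emulates the gross structure an axial chest scan presents to a
nodule-detection pipeline: a bright soft-tissue body cross-section enclosing
two dark air-filled lung regions (a two-peak intensity histogram), tubular
vessels with Y-bifurcations inside the lungs, and bright spherical or
irregular nodules, including juxtapleural ones attached to the chest wall.
It does not simulate CT physics; intensities are piecewise-constant
materials plus additive Gaussian noise on an 8-bit-like scale.

Ground truth is analytic: every nodule is returned as a ``NoduleTruth``
(center and radius in mm), and ``reference_lung_mask`` /
``nodule_voxel_mask`` digitize the generating geometry by brute force so
tests can compare pipeline output against the construction itself.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .volume_io import CTVolume, write_volume_nifti

__all__ = [
    "NoduleTruth",
    "VesselSegment",
    "PhantomSpec",
    "PhantomSpecError",
    "generate_phantom",
    "phantom_suite",
    "reference_lung_mask",
    "nodule_voxel_mask",
    "write_phantom_suite",
]

NODULE_KINDS = ("isolated", "juxtapleural", "vascular")


class PhantomSpecError(ValueError):
    """A phantom specification violates an invariant; names the field."""


@dataclass
class NoduleTruth:
    """Ground truth for one planted nodule.

    ``center_mm`` is (cz, cy, cx); ``radius_mm`` the nominal sphere radius;
    ``irregularity`` in [0, 1] scales a low-order radial surface
    perturbation (0 = exact sphere).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    kind: str = "isolated"
    irregularity: float = 0.0

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(c) for c in self.center_mm)
        self.radius_mm = float(self.radius_mm)
        if self.radius_mm <= 0:
            raise PhantomSpecError(f"nodules: radius_mm must be > 0, got {self.radius_mm}")
        if self.kind not in NODULE_KINDS:
            raise PhantomSpecError(f"nodules: kind must be one of {NODULE_KINDS}, got {self.kind!r}")
        if not 0.0 <= self.irregularity <= 1.0:
            raise PhantomSpecError(f"nodules: irregularity must be in [0,1], got {self.irregularity}")


@dataclass
class VesselSegment:
    """A capsule (line segment + radius) with optional bifurcation children."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    children: list["VesselSegment"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start_mm = tuple(float(c) for c in self.start_mm)
        self.end_mm = tuple(float(c) for c in self.end_mm)
        self.radius_mm = float(self.radius_mm)
        if self.radius_mm <= 0:
            raise PhantomSpecError(f"vessels: radius_mm must be > 0, got {self.radius_mm}")

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom deterministically.

    Intensities are on an 8-bit-like scale; ``lung_intensity`` must be the
    darkest material so the volume histogram keeps its two dominant modes.
    """

    shape_voxels: tuple[int, int, int] = (48, 128, 128)  # (nz, ny, nx)
    spacing_mm: tuple[float, float, float] = (2.5, 0.7, 0.7)  # (dz, dy, dx)
    body_intensity: float = 200.0
    lung_intensity: float = 60.0
    structure_intensity: float = 220.0
    noise_sigma: float = 0.0
    nodules: list[NoduleTruth] = field(default_factory=list)
    vessels: list[VesselSegment] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        shape = tuple(int(n) for n in self.shape_voxels)
        if len(shape) != 3 or any(n < 8 for n in shape):
            raise PhantomSpecError(f"shape_voxels: each axis must be >= 8, got {self.shape_voxels}")
        self.shape_voxels = shape
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise PhantomSpecError(f"spacing_mm: all spacings must be > 0, got {self.spacing_mm}")
        self.spacing_mm = spacing
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma: must be >= 0, got {self.noise_sigma}")
        if not (self.lung_intensity < self.body_intensity
                and self.lung_intensity < self.structure_intensity):
            raise PhantomSpecError(
                "lung_intensity: must be darker than body_intensity and "
                f"structure_intensity (got lung={self.lung_intensity}, "
                f"body={self.body_intensity}, structure={self.structure_intensity})"
            )


# ---------------------------------------------------------------------------
# geometry helpers (all in physical mm, voxel-center convention)

def _grids_mm(spec: PhantomSpec):
    nz, ny, nx = spec.shape_voxels
    dz, dy, dx = spec.spacing_mm
    z = (np.arange(nz) * dz)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    x = (np.arange(nx) * dx)[None, None, :]
    return z, y, x


def _body_params(spec: PhantomSpec):
    nz, ny, nx = spec.shape_voxels
    dz, dy, dx = spec.spacing_mm
    ly, lx = ny * dy, nx * dx
    center = (0.5 * ly, 0.5 * lx)  # (cy, cx)
    semi = (0.33 * ly, 0.42 * lx)
    return center, semi


def _lung_params(spec: PhantomSpec):
    """Centers and semi-axes (mm) of the two lung ellipsoids."""
    nz, ny, nx = spec.shape_voxels
    dz, dy, dx = spec.spacing_mm
    lz, ly, lx = nz * dz, ny * dy, nx * dx
    cz, cy = 0.5 * lz, 0.5 * ly
    semi = (0.45 * lz, 0.22 * ly, 0.13 * lx)
    lungs = []
    for side in (-1.0, +1.0):
        cx = 0.5 * lx + side * 0.22 * lx
        lungs.append(((cz, cy, cx), semi))
    return lungs


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    z, y, x = _grids_mm(spec)
    (cy, cx), (ay, ax) = _body_params(spec)
    in_plane = ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    return np.broadcast_to(in_plane, spec.shape_voxels).copy()


def reference_lung_mask(spec: PhantomSpec) -> np.ndarray:
    """Brute-force digitization of the two lung ellipsoids (ground truth)."""
    z, y, x = _grids_mm(spec)
    mask = np.zeros(spec.shape_voxels, dtype=bool)
    for (cz, cy, cx), (az, ay, ax) in _lung_params(spec):
        mask |= ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    return mask


def _nodule_rng(spec_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, 7919, index]))


def nodule_voxel_mask(spec: PhantomSpec, nodule: NoduleTruth,
                      index: int = 0) -> np.ndarray:
    """Digitize one nodule: voxel centers within its (perturbed) radius.

    For ``irregularity == 0`` this is exactly the set of voxel centers
    within ``radius_mm`` of ``center_mm``. Otherwise the radius is modulated
    by a fixed low-order quadratic form on the unit sphere, seeded from the
    phantom seed and the nodule's index so the digitization is reproducible.
    """
    z, y, x = _grids_mm(spec)
    cz, cy, cx = nodule.center_mm
    dzv, dyv, dxv = z - cz, y - cy, x - cx
    dist = np.sqrt(dzv ** 2 + dyv ** 2 + dxv ** 2)
    if nodule.irregularity == 0.0:
        return dist <= nodule.radius_mm
    rng = _nodule_rng(spec.seed, index)
    a = rng.normal(size=(3, 3))
    a = a + a.T
    a -= np.eye(3) * np.trace(a) / 3.0
    a /= max(np.abs(a).max(), 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        uz, uy, ux = dzv / dist, dyv / dist, dxv / dist
    uz, uy, ux = (np.nan_to_num(u) for u in (uz, uy, ux))
    quad = (a[0, 0] * uz * uz + a[1, 1] * uy * uy + a[2, 2] * ux * ux
            + 2 * (a[0, 1] * uz * uy + a[0, 2] * uz * ux + a[1, 2] * uy * ux))
    radius = nodule.radius_mm * (1.0 + 0.35 * nodule.irregularity * quad)
    return dist <= radius


def _capsule_mask(spec: PhantomSpec, seg: VesselSegment) -> np.ndarray:
    z, y, x = _grids_mm(spec)
    p0 = np.asarray(seg.start_mm)
    p1 = np.asarray(seg.end_mm)
    d = p1 - p0
    L2 = float(d @ d)
    rz, ry, rx = z - p0[0], y - p0[1], x - p0[2]
    if L2 == 0.0:
        t = 0.0
        dist2 = rz ** 2 + ry ** 2 + rx ** 2
    else:
        t = np.clip((rz * d[0] + ry * d[1] + rx * d[2]) / L2, 0.0, 1.0)
        dist2 = (rz - t * d[0]) ** 2 + (ry - t * d[1]) ** 2 + (rx - t * d[2]) ** 2
    return dist2 <= seg.radius_mm ** 2


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, list[NoduleTruth]]:
    """Render a phantom volume from its spec.

    Returns the volume (intensity scale ``HU`` meaning "raw" here — the
    pipeline normalizes before thresholding) and the nodule ground truth
    verbatim. Identical specs (including seed) give bit-identical volumes.
    """
    spec.validate()
    vol = np.full(spec.shape_voxels, spec.lung_intensity, dtype=np.float64)

    body = _body_mask(spec)
    vol[body] = spec.body_intensity

    lung = reference_lung_mask(spec)
    vol[lung] = spec.lung_intensity

    for tree in spec.vessels:
        for seg in tree.walk():
            vol[_capsule_mask(spec, seg) & lung] = spec.structure_intensity

    for i, nodule in enumerate(spec.nodules):
        sphere = nodule_voxel_mask(spec, nodule, index=i)
        if nodule.kind == "juxtapleural":
            # attached to the chest wall: paint wherever the sphere meets tissue
            vol[sphere & (lung | body)] = spec.structure_intensity
        else:
            vol[sphere & lung] = spec.structure_intensity

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
        np.clip(vol, 0.0, 255.0, out=vol)

    volume = CTVolume(vol, spec.spacing_mm, intensity_scale="HU")
    return volume, list(spec.nodules)


# ---------------------------------------------------------------------------
# randomized suites

def _sample_point_in_ellipsoid(rng, center, semi, shrink: float):
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if float(u @ u) <= 1.0:
            return tuple(center[i] + shrink * semi[i] * u[i] for i in range(3))


def _sample_interior_center(rng, center, semi, radius_mm, margin_mm=1.0):
    """Center such that the whole sphere sits inside the lung ellipsoid."""
    eff = [max(s - radius_mm - margin_mm, 0.3 * s) for s in semi]
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if float(u @ u) <= 1.0:
            return tuple(center[i] + eff[i] * u[i] for i in range(3))


def _sample_boundary_center(rng, center, semi, radius_mm):
    """Juxtapleural center: about one radius inside the lung boundary.

    The wall is convex, so a center exactly one radius from the boundary
    along the inward direction still leaves the sphere shouldering into the
    wall sideways; depths around 0.95-1.15 radii keep the nodule attached
    to the pleura without burying half of it in the chest wall.
    """
    probes = rng.normal(size=(128, 3))
    probes /= np.linalg.norm(probes, axis=1, keepdims=True)
    probes *= rng.uniform(0, 1, size=(128, 1)) ** (1 / 3)  # uniform in ball
    best, best_frac = None, -1.0
    for _ in range(40):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        surface = np.asarray(center) + np.asarray(semi) * v
        depth = rng.uniform(0.98, 1.15) * radius_mm
        # inward surface normal of the ellipsoid (NOT the direction to the
        # center, which runs almost parallel to the wall near the poles)
        normal = (surface - np.asarray(center)) / np.asarray(semi) ** 2
        normal /= np.linalg.norm(normal)
        c = surface - depth * normal
        # on a strongly curved wall patch the sphere shoulders into the
        # chest wall; demand that most of it stays inside the lung
        pts = (c + radius_mm * probes - np.asarray(center)) / np.asarray(semi)
        frac = float(((pts ** 2).sum(axis=1) <= 1.0).mean())
        if frac > best_frac:
            best, best_frac = c, frac
        if frac >= 0.55:
            break
    return tuple(best)


def _inside_margin(point, center, semi, margin_mm) -> bool:
    """Whole sphere of radius ``margin_mm`` at ``point`` inside the ellipsoid
    (conservative: shrinks each semi-axis by the margin)."""
    eff = np.asarray(semi) - margin_mm
    if (eff <= 0).any():
        return False
    d = (np.asarray(point) - np.asarray(center)) / eff
    return float(d @ d) <= 1.0


def _random_direction(rng, min_z: float = 0.5) -> np.ndarray:
    """Random unit vector with a floor on |z|: pulmonary vessels run
    predominantly cranio-caudally from the hilum, and at coarse slice
    spacing a purely in-plane tube would be an atypical worst case."""
    while True:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if abs(d[0]) >= min_z:
            return d


def _random_vessel_tree(rng, center, semi, vertical: bool = False) -> VesselSegment:
    """One vessel tree: a sub-4mm trunk with 1-2 Y-bifurcations, each
    junction carrying a bulb (a short fat degenerate capsule) — the compact
    bright blob a branch point presents at coarse resolution, and the
    pipeline's deliberate false-positive source."""
    start = _sample_point_in_ellipsoid(rng, center, semi, shrink=0.35)
    direction = _random_direction(rng, min_z=0.75 if vertical else 0.5)
    length = rng.uniform(25.0, 40.0)
    radius = rng.uniform(1.0, 1.5)
    end = np.asarray(start) + length * direction

    # keep the trunk inside a slightly shrunken lung so it never notches the pleura
    end = np.asarray(center) + np.clip(
        (end - np.asarray(center)) / np.asarray(semi), -0.85, 0.85
    ) * np.asarray(semi)
    trunk = VesselSegment(tuple(start), tuple(end), radius)

    n_bif = rng.integers(1, 3)  # 1 or 2 Y-bifurcations along the tree
    parent = trunk
    for _ in range(int(n_bif)):
        base = np.asarray(parent.end_mm)
        axis = base - np.asarray(parent.start_mm)
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        children = []
        for _ in range(2):
            tilt = rng.normal(size=3)
            tilt -= (tilt @ axis) * axis
            tn = np.linalg.norm(tilt)
            tilt = tilt / tn if tn > 0 else np.array([0.0, 1.0, 0.0])
            angle = np.deg2rad(rng.uniform(25.0, 50.0))
            child_dir = np.cos(angle) * axis + np.sin(angle) * tilt
            child_len = rng.uniform(10.0, 20.0)
            child_end = base + child_len * child_dir
            child_end = np.asarray(center) + np.clip(
                (child_end - np.asarray(center)) / np.asarray(semi), -0.9, 0.9
            ) * np.asarray(semi)
            children.append(
                VesselSegment(tuple(base), tuple(child_end), 0.75 * parent.radius_mm)
            )
        # junction bulb: a modest widening at the branch point; the visible
        # junction is the lobed union of bulb and tube stubs, not a sphere
        bulb_radius = min(max(1.6 * parent.radius_mm, 2.0), 2.6)
        children.append(VesselSegment(tuple(base), tuple(base), bulb_radius))
        parent.children.extend(children)
        parent = children[0]
    return trunk


def random_phantom_spec(seed: int,
                        noise_sigma: float = 5.0,
                        n_nodules: int | None = None) -> PhantomSpec:
    """Draw one randomized phantom spec: 40-80 slices, 0-2 nodules of mixed
    kinds with diameters 5-14 mm, and 2-4 vessel trees with bifurcations."""
    rng = np.random.default_rng(seed)
    nz = int(rng.integers(40, 81))
    spec = PhantomSpec(shape_voxels=(nz, 128, 128), noise_sigma=noise_sigma,
                       seed=int(rng.integers(0, 2 ** 31)))
    lungs = _lung_params(spec)

    vessels = []
    n_trees = int(rng.integers(3, 6))
    for i in range(n_trees):
        center, semi = lungs[int(rng.integers(0, 2))]
        # tree 0 runs near-vertically; vascular nodules attach to it
        vessels.append(_random_vessel_tree(rng, center, semi, vertical=(i == 0)))

    if n_nodules is None:
        n_nodules = int(rng.integers(0, 3))
    nodules = []
    vascular_slots = iter(((0.2, 0.45), (0.55, 0.8)))
    for _ in range(n_nodules):
        center, semi = lungs[int(rng.integers(0, 2))]
        radius = float(rng.uniform(2.5, 7.0))
        kind = NODULE_KINDS[int(rng.integers(0, 3))]
        irregularity = float(rng.uniform(0.0, 0.5)) if rng.random() < 0.4 else 0.0
        if kind == "juxtapleural":
            c = _sample_boundary_center(rng, center, semi, radius)
            for _ in range(20):
                if all(np.linalg.norm(np.asarray(c) - np.asarray(n.center_mm))
                       >= radius + n.radius_mm + 4.0 for n in nodules):
                    break
                c = _sample_boundary_center(rng, center, semi, radius)
        elif kind == "vascular":
            # the near-vertical trunk passes through the nodule interior
            seg = vessels[0]
            axis = np.asarray(seg.end_mm) - np.asarray(seg.start_mm)
            axis /= max(np.linalg.norm(axis), 1e-9)
            # recover which lung holds the trunk
            tree_center, tree_semi = min(
                lungs, key=lambda cs: np.linalg.norm(
                    np.asarray(seg.start_mm) - np.asarray(cs[0])))
            t_lo, t_hi = next(vascular_slots, (0.2, 0.8))
            best, best_score = None, -np.inf
            for _ in range(50):
                t = rng.uniform(t_lo, t_hi)
                on_axis = (np.asarray(seg.start_mm) * (1 - t)
                           + np.asarray(seg.end_mm) * t)
                perp = rng.normal(size=3)
                perp -= (perp @ axis) * axis
                perp /= max(np.linalg.norm(perp), 1e-9)
                cand = on_axis + rng.uniform(0.0, 0.3) * radius * perp
                clear = all(
                    np.linalg.norm(cand - np.asarray(n.center_mm))
                    >= radius + n.radius_mm + 4.0 for n in nodules)
                d = ((cand - np.asarray(tree_center))
                     / np.maximum(np.asarray(tree_semi) - radius - 1.0, 1e-3))
                score = -float(d @ d) - (0.0 if clear else 100.0)
                if score > best_score:
                    best, best_score = cand, score
                if clear and _inside_margin(cand, tree_center, tree_semi,
                                            radius + 1.0):
                    best = cand
                    break
            c = tuple(best)
        else:
            c = _sample_interior_center(rng, center, semi, radius)
            # distinct lesions: keep isolated nodules clear of earlier ones
            for _ in range(30):
                if all(np.linalg.norm(np.asarray(c) - np.asarray(n.center_mm))
                       >= radius + n.radius_mm + 4.0 for n in nodules):
                    break
                c = _sample_interior_center(rng, center, semi, radius)
        nodules.append(NoduleTruth(c, radius, kind, irregularity))

    spec.nodules = nodules
    spec.vessels = vessels
    return spec


def phantom_suite(n_scans: int, seed: int,
                  noise_sigma: float = 5.0) -> list[tuple[CTVolume, list[NoduleTruth]]]:
    """Generate ``n_scans`` randomized phantoms, reproducible from ``seed``."""
    if n_scans < 1:
        raise ValueError(f"n_scans must be >= 1, got {n_scans}")
    rng = np.random.default_rng(seed)
    suite = []
    for _ in range(n_scans):
        child_seed = int(rng.integers(0, 2 ** 31))
        spec = random_phantom_spec(child_seed, noise_sigma=noise_sigma)
        suite.append(generate_phantom(spec))
    return suite


def write_phantom_suite(suite, out_dir: str | os.PathLike) -> None:
    """Write a suite as NIfTI volumes plus CSV and JSON ground truth."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (volume, truths) in enumerate(suite):
        scan_id = f"phantom_{i:03d}"
        write_volume_nifti(volume, os.path.join(out_dir, scan_id + ".nii.gz"))
        for t in truths:
            cz, cy, cx = t.center_mm
            rows.append({"scan_id": scan_id, "cx_mm": cx, "cy_mm": cy,
                         "cz_mm": cz, "radius_mm": t.radius_mm, "kind": t.kind})
    with open(os.path.join(out_dir, "truth.csv"), "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["scan_id", "cx_mm", "cy_mm", "cz_mm", "radius_mm", "kind"])
        writer.writeheader()
        writer.writerows(rows)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(rows, fh, indent=2)
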