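"""The eight minimal candidate descriptors and correlation-based selection.

Each possible nodule (PN) is summarised by eight descriptors d1-d8 mixing
2D shape, 3D extent and intensity-histogram statistics:

=====  ======================  =============================================
name   quantity                definition
=====  ======================  =============================================
d1     area                    pixel count of the largest axial cross-section
d2     circularity             d1 / (4 pi (D/2)^2), D the cross-section
                               diameter (max pairwise pixel distance + 1 px)
d3     mean intensity          mean of f over all PN voxels
d4     intensity variance      population variance over PN voxels
d5     skewness                m3 / m2^(3/2), biased 1/n moments
d6     kurtosis                m4 / m2^2, raw (a normal sample gives 3)
d7     bounding-box volume     LBB x WBB x HBB in mm^3
d8     intensity sum           sum of f over PN voxels
=====  ======================  =============================================

d1/d2 are 2D by design (the slice-wise stage reasons in pixels); d7/d8 are
volumetric. A correlation analysis (`select_features_by_correlation`)
greedily drops one member of every feature pair correlated beyond ``r_max``
so only the least redundant descriptors enter classification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .candidate_segmentation import Candidate
from .volume_io import CTVolume

__all__ = [
    "FEATURE_NAMES",
    "MINIMAL8",
    "FeatureError",
    "area_d1",
    "circularity_d2",
    "intensity_stats",
    "skewness_d5",
    "kurtosis_d6",
    "volume_box_d7",
    "feature_matrix",
    "select_features_by_correlation",
    "scatter_matrix_plot",
]

FEATURE_NAMES = [
    "d1_area",
    "d2_circularity",
    "d3_mean_intensity",
    "d4_variance_intensity",
    "d5_skewness",
    "d6_kurtosis",
    "d7_volume_box",
    "d8_sum_intensity",
]

#: the fixed eight-descriptor preset; using it skips correlation selection
MINIMAL8 = tuple(FEATURE_NAMES)


class FeatureError(ValueError):
    pass


def _largest_cross_section(candidate: Candidate) -> np.ndarray:
    """(y, x) pixels of the candidate's largest-area axial slice (ties: lowest z)."""
    voxels = candidate.voxel_set
    zs, counts = np.unique(voxels[:, 0], return_counts=True)
    z_best = zs[np.argmax(counts)]  # argmax takes first maximum -> lowest z
    return voxels[voxels[:, 0] == z_best, 1:]


def area_d1(candidate: Candidate) -> int:
    """d1: pixel count of the largest axial cross-section."""
    return int(len(_largest_cross_section(candidate)))


def _diameter_px(pixels: np.ndarray) -> float:
    """Cross-section diameter: max pairwise pixel-center distance + 1 px.

    The +1 makes the measure total (a single pixel has diameter 1) and
    accounts for pixels having unit extent rather than being points.
    """
    pts = np.asarray(pixels, dtype=np.float64)
    if len(pts) == 1:
        return 1.0
    if len(pts) > 400:
        # the diametral pair lies on the convex hull; keep only extreme points
        from scipy.spatial import ConvexHull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) sets: fall through to full pdist
    return float(pdist(pts).max()) + 1.0


def circularity_d2(candidate: Candidate) -> float:
    """d2: d1 / (4 pi (D/2)^2) on the largest cross-section.

    A perfect digital disk tends to 1/4 as its radius grows; elongated
    shapes score much lower.
    """
    pixels = _largest_cross_section(candidate)
    d1 = float(len(pixels))
    diameter = _diameter_px(pixels)
    return d1 / (4.0 * np.pi * (diameter / 2.0) ** 2)


def intensity_stats(candidate: Candidate, volume: CTVolume) -> tuple[float, float, float]:
    """(d3, d4, d8): mean, population variance, and sum of intensity over PN."""
    voxels = candidate.voxel_set
    shape = volume.shape
    if (voxels < 0).any() or (voxels >= np.asarray(shape)).any():
        raise FeatureError(f"candidate {candidate.id}: voxel outside volume bounds")
    f = volume.intensities[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(np.float64)
    mean = float(f.mean())
    var = float(f.var())  # population (1/n) variance
    return mean, var, float(f.sum())


def _moments(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise FeatureError("moment ratios need at least 2 values")
    d = values - values.mean()
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        raise FeatureError("undefined moment ratio: zero variance")
    return m2, float(np.mean(d ** 3)), float(np.mean(d ** 4))


def skewness_d5(values) -> float:
    """d5 = m3 / m2^(3/2) with biased (1/n) central moments."""
    m2, m3, _ = _moments(values)
    return m3 / m2 ** 1.5


def kurtosis_d6(values) -> float:
    """d6 = m4 / m2^2, raw kurtosis (not excess): a normal sample gives 3."""
    m2, _, m4 = _moments(values)
    return m4 / m2 ** 2


def volume_box_d7(candidate: Candidate, spacing_mm=None) -> float:
    """d7 = LBB x WBB x HBB, the axis-aligned bounding-box volume in mm^3."""
    if spacing_mm is None:
        return float(np.prod(candidate.bbox_mm))
    voxels = candidate.voxel_set
    extent = voxels.max(axis=0) - voxels.min(axis=0)
    edges = (extent + 1) * np.asarray(spacing_mm, dtype=np.float64)
    return float(np.prod(edges))


def feature_vector(candidate: Candidate, volume: CTVolume) -> dict[str, float]:
    d3, d4, d8 = intensity_stats(candidate, volume)
    f = volume.intensities[candidate.voxel_set[:, 0],
                           candidate.voxel_set[:, 1],
                           candidate.voxel_set[:, 2]]
    return {
        "d1_area": float(area_d1(candidate)),
        "d2_circularity": circularity_d2(candidate),
        "d3_mean_intensity": d3,
        "d4_variance_intensity": d4,
        "d5_skewness": skewness_d5(f),
        "d6_kurtosis": kurtosis_d6(f),
        "d7_volume_box": volume_box_d7(candidate),
        "d8_sum_intensity": d8,
    }


def feature_matrix(candidates: list[Candidate], volume: CTVolume) -> pd.DataFrame:
    """One row per candidate (indexed by id), columns d1..d8 in fixed order."""
    rows, index = [], []
    for c in candidates:
        try:
            rows.append(feature_vector(c, volume))
        except FeatureError as exc:
            raise FeatureError(f"candidate {c.id}: {exc}") from exc
        index.append(c.id)
    m = pd.DataFrame(rows, index=pd.Index(index, name="candidate_id"),
                     columns=FEATURE_NAMES)
    m.attrs["normalization"] = "raw"
    return m


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c != "label"]


def select_features_by_correlation(matrix: pd.DataFrame, r_max: float = 0.95) -> list[str]:
    """Greedy redundancy elimination by pairwise Pearson correlation.

    While any feature pair has |r| > r_max, drop the member of the worst
    (most correlated) pair with the larger mean absolute correlation to the
    remaining features; ties break by column order (the later column goes).
    Constant columns are dropped first with a warning, since their
    correlation is undefined.
    """
    if not 0.0 <= r_max <= 1.0:
        raise ValueError(f"r_max must be in [0, 1], got {r_max}")
    cols = _feature_columns(matrix)
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows for a correlation analysis")
    data = matrix[cols].to_numpy(dtype=np.float64)
    constant = [c for c, col in zip(cols, data.T) if np.ptp(col) == 0]
    for c in constant:
        warnings.warn(f"feature {c!r} is constant; dropped before correlation analysis")
    cols = [c for c in cols if c not in constant]

    while len(cols) > 1:
        sub = matrix[cols].to_numpy(dtype=np.float64)
        r = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(r, 0.0)
        if r.max() <= r_max:
            break
        i, j = np.unravel_index(np.argmax(r), r.shape)
        mean_i, mean_j = r[i].mean(), r[j].mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: drop the later column
        cols.pop(drop)
    return cols


def scatter_matrix_plot(matrix: pd.DataFrame, path: str) -> None:
    """Diagnostic pairwise scatter plot of the feature matrix (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = _feature_columns(matrix)
    labels = matrix["label"] if "label" in matrix.columns else None
    n = len(cols)
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n))
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i, j]
            if i == j:
                ax.hist(matrix[ci], bins=20)
            elif labels is not None:
                for lab, marker in ((1, "o"), (-1, "x")):
                    sel = labels == lab
                    ax.scatter(matrix.loc[sel, cj], matrix.loc[sel, ci],
                               s=8, marker=marker)
            else:
                ax.scatter(matrix[cj], matrix[ci], s=8)
            if i == n - 1:
                ax.set_xlabel(cj, fontsize=7)
            if j == 0:
                ax.set_ylabel(ci, fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
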