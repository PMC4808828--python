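import numpy as np
import pandas as pd
import pytest

from nodulecad.phantom import (NoduleTruth, PhantomSpec, VesselSegment,
                               generate_phantom, phantom_suite)
from nodulecad.phantom import _lung_params
from nodulecad.pipeline import PipelineConfig, detect, label_candidates


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sigma=0)


@pytest.fixture(scope="session")
def lung_geometry(noiseless_spec):
    """((center_left, semi), (center_right, semi)) of the default phantom."""
    return _lung_params(noiseless_spec)


def make_vessels(lungs):
    """Three plain, non-intersecting tubes (no bifurcations, no bulbs)."""
    (cA, _), (cB, _) = lungs
    return [
        VesselSegment((cA[0] - 25, cA[1] - 6, cA[2]), (cA[0] + 25, cA[1] - 2, cA[2] + 3), 1.3),
        VesselSegment((cB[0] - 20, cB[1] - 3, cB[2]), (cB[0] + 20, cB[1] + 5, cB[2] - 2), 1.1),
        VesselSegment((cA[0] - 15, cA[1] + 8, cA[2] - 4), (cA[0] + 20, cA[1] + 10, cA[2] + 2), 1.4),
    ]


@pytest.fixture(scope="session")
def noisy_nodule_phantom(lung_geometry):
    """One noisy phantom with a known isolated nodule, plus its truth."""
    (cA, _), _ = lung_geometry
    spec = PhantomSpec(noise_sigma=5.0, seed=17,
                       nodules=[NoduleTruth((cA[0] + 10, cA[1] - 4, cA[2] + 3), 4.5)],
                       vessels=make_vessels(lung_geometry))
    volume, truths = generate_phantom(spec)
    return spec, volume, truths


@pytest.fixture(scope="session")
def labeled_candidate_matrix():
    """Feature matrix of nodule vs non-nodule candidates pooled from a
    20-phantom suite (computed once per session; the slow shared fixture)."""
    config = PipelineConfig(seed=3)
    parts = []
    for volume, truths in phantom_suite(20, 3, noise_sigma=5.0):
        labeled = label_candidates(detect(volume, config), truths)
        if len(labeled):
            parts.append(labeled)
    matrix = pd.concat(parts, ignore_index=True)
    assert (matrix["label"] == 1).sum() >= 10
    assert (matrix["label"] == -1).sum() >= 10
    return matrix


def make_separable_matrix(n_per_class=12, seed=0):
    """Two well-separated Gaussian clouds in two features, labels +/-1."""
    rng = np.random.default_rng(seed)
    pos = rng.normal([0.8, 0.8], 0.04, size=(n_per_class, 2))
    neg = rng.normal([0.2, 0.2], 0.04, size=(n_per_class, 2))
    m = pd.DataFrame(np.vstack([pos, neg]), columns=["f1", "f2"])
    m["label"] = [1] * n_per_class + [-1] * n_per_class
    return m


def digitized_sphere(radius_vox, center=None):
    """Voxel coordinates of a lattice sphere in an odd cubic grid."""
    n = 2 * int(np.ceil(radius_vox)) + 3
    c = (n // 2,) * 3 if center is None else center
    zz, yy, xx = np.indices((n, n, n))
    mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius_vox ** 2
    return np.argwhere(mask), mask
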