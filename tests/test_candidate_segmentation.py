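import numpy as np
import pytest

from nodulecad import candidate_segmentation as cseg
from nodulecad.phantom import NoduleTruth, PhantomSpec, generate_phantom
from nodulecad.pipeline import PipelineConfig, detect

from conftest import digitized_sphere, make_vessels


class TestSliceStructures:
    def test_two_separated_squares(self):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 200    # 3x3
        img[10:14, 10:14] = 220  # 4x4
        mask = np.ones((20, 20), dtype=bool)
        structs = cseg.label_slice_structures(img, mask, threshold=100)
        assert sorted(s.area_px for s in structs) == [9, 16]

    def test_empty_lung_mask(self):
        img = np.full((10, 10), 200.0)
        structs = cseg.label_slice_structures(
            img, np.zeros((10, 10), dtype=bool), threshold=100)
        assert structs == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cseg.label_slice_structures(np.zeros((5, 5)),
                                        np.ones((6, 6), dtype=bool), 1)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 255, size=(30, 30))
        mask = np.ones((30, 30), dtype=bool)
        structs = cseg.label_slice_structures(img, mask, threshold=180)
        # oracle: 8-connected flood fill over the thresholded pixels
        bright = img >= 180
        seen = np.zeros_like(bright)
        components = []
        for i in range(30):
            for j in range(30):
                if bright[i, j] and not seen[i, j]:
                    comp, stack = [], [(i, j)]
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        comp.append((a, b))
                        for da in (-1, 0, 1):
                            for db in (-1, 0, 1):
                                na, nb = a + da, b + db
                                if 0 <= na < 30 and 0 <= nb < 30 \
                                        and bright[na, nb] and not seen[na, nb]:
                                    seen[na, nb] = True
                                    stack.append((na, nb))
                    components.append(frozenset(comp))
        got = {frozenset(map(tuple, s.pixel_set)) for s in structs}
        assert got == set(components)


class TestFilterSliceStructures:
    def make(self, area, mean):
        pixels = [(0, i) for i in range(area)]
        return cseg.SliceStructure(0, pixels, area, mean)

    def test_small_area_removed(self):
        assert cseg.filter_slice_structures([self.make(3, 250)], 5, 0) == []

    def test_and_rule_requires_both_indicators(self):
        s = self.make(10, 40.0)
        assert cseg.filter_slice_structures([s], 5, 50.0) == []
        assert cseg.filter_slice_structures([s], 5, 30.0) == [s]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_filter(self, seed):
        rng = np.random.default_rng(seed)
        structs = [self.make(int(rng.integers(1, 50)), rng.uniform(0, 255))
                   for _ in range(30)]
        a_min, i_min = 20, 120.0
        expected = [s for s in structs
                    if s.area_px >= a_min and s.mean_intensity >= i_min]
        assert cseg.filter_slice_structures(structs, a_min, i_min) == expected


class TestAreaFloor:
    def test_submillimeter_grid(self):
        assert cseg.area_floor_from_spacing((2.5, 0.7, 0.7)) == 26

    def test_coarse_grid(self):
        assert cseg.area_floor_from_spacing((2.5, 2.0, 2.0)) == 4

    def test_zero_diameter_disables(self):
        assert cseg.area_floor_from_spacing((2.5, 0.7, 0.7), 0.0) == 0


def bfs_components_26(volume):
    """Oracle: 26-connected components by breadth-first flood fill."""
    fg = {tuple(v) for v in np.argwhere(volume)}
    comps = []
    while fg:
        seed = fg.pop()
        comp, queue = {seed}, [seed]
        while queue:
            z, y, x = queue.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        n = (z + dz, y + dy, x + dx)
                        if n in fg:
                            fg.remove(n)
                            comp.add(n)
                            queue.append(n)
        comps.append(frozenset(comp))
    return set(comps)


class TestLabelComponents26:
    def test_corner_adjacency_joins(self):
        vol = np.zeros((3, 3, 3), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        assert len(cseg.label_components_26(vol)) == 1

    def test_gap_separates(self):
        vol = np.zeros((1, 1, 3), dtype=bool)
        vol[0, 0, 0] = vol[0, 0, 2] = True
        assert len(cseg.label_components_26(vol)) == 2

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(77)
        vol = rng.random((20, 20, 20)) < 0.2
        cands = cseg.label_components_26(vol)
        got = {frozenset(map(tuple, c.voxel_set)) for c in cands}
        assert got == bfs_components_26(vol)

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        vol = rng.random((15, 15, 15)) < 0.3
        cands = cseg.label_components_26(vol)
        all_voxels = [tuple(v) for c in cands for v in c.voxel_set]
        assert len(all_voxels) == len(set(all_voxels)) == vol.sum()

    def test_ids_follow_first_voxel_order(self):
        rng = np.random.default_rng(9)
        vol = rng.random((10, 10, 10)) < 0.15
        cands = cseg.label_components_26(vol)
        firsts = [tuple(c.voxel_set[0]) for c in cands]
        assert firsts == sorted(firsts)
        assert [c.id for c in cands] == list(range(len(cands)))

    def test_component_count_monotone_under_bridging(self):
        vol = np.zeros((1, 1, 5), dtype=bool)
        vol[0, 0, 0] = vol[0, 0, 2] = vol[0, 0, 4] = True
        n0 = len(cseg.label_components_26(vol))
        vol[0, 0, 1] = True  # bridge adjacent to existing foreground
        assert len(cseg.label_components_26(vol)) < n0


class TestBlobScores:
    def test_digitized_sphere_is_spherical(self):
        voxels, _ = digitized_sphere(5.0)
        sphericity, width = cseg.blob_scores(voxels, (1.0, 1.0, 1.0))
        assert sphericity >= 0.9
        assert width == 11.0

    def test_tube_is_not_spherical(self):
        zz, yy, xx = np.indices((30, 5, 5))
        tube = (yy - 2) ** 2 + (xx - 2) ** 2 <= 1
        sphericity, _ = cseg.blob_scores(np.argwhere(tube), (1.0, 1.0, 1.0))
        assert sphericity < 0.2

    def test_single_voxel_degenerate_rule(self):
        sphericity, width = cseg.blob_scores(np.array([[3, 4, 5]]),
                                             (2.5, 0.7, 0.7))
        assert sphericity == 1.0
        assert width == pytest.approx(0.7)


class TestDiscriminateCandidates:
    def test_sphere_kept_tube_rejected(self):
        sphere_vox, _ = digitized_sphere(4.0)
        zz, yy, xx = np.indices((40, 5, 5))
        tube_vox = np.argwhere((yy - 2) ** 2 + (xx - 2) ** 2 <= 1)
        vol = np.zeros((40, 30, 30), dtype=bool)
        vol[tuple(sphere_vox.T + np.array([[0], [12], [12]]))] = True
        vol[:, 25:, 25:][tuple((tube_vox
                                - tube_vox.min(axis=0)).T)] = True
        cands = cseg.label_components_26(vol, (1.0, 1.0, 1.0))
        kept = cseg.discriminate_candidates(cands)
        assert len(cands) == 2
        assert len(kept) == 1
        assert kept[0].sphericity >= 0.5

    def test_empty_input(self):
        assert cseg.discriminate_candidates([]) == []


class TestEndToEndSegmentation:
    def test_nodules_found_and_plain_vessels_suppressed(self, lung_geometry):
        (cA, _), (cB, _) = lung_geometry
        vessels = make_vessels(lung_geometry)
        nodules = [NoduleTruth((cA[0] + 10, cA[1] - 1, cA[2] + 4), 4.0),
                   NoduleTruth((cB[0] - 8, cB[1] + 4, cB[2] - 2), 5.0)]
        spec = PhantomSpec(noise_sigma=0, nodules=nodules, vessels=vessels)
        volume, truths = generate_phantom(spec)
        result = detect(volume, PipelineConfig(), compute_features=False)
        # every truth overlapped by exactly one surviving candidate
        for truth in truths:
            hits = [c for c in result.candidates
                    if np.linalg.norm(np.asarray(c.centroid_mm)
                                      - np.asarray(truth.center_mm))
                    <= truth.radius_mm]
            assert len(hits) == 1
        assert len(result.candidates) == len(truths)

    def test_vessels_without_bifurcations_leave_no_candidates(self, lung_geometry):
        spec = PhantomSpec(noise_sigma=0, vessels=make_vessels(lung_geometry))
        volume, _ = generate_phantom(spec)
        result = detect(volume, PipelineConfig(), compute_features=False)
        assert result.candidates == []
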