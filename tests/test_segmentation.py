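"""SUV_max seeding, percentage and PERCIST thresholding, region growing."""

import numpy as np
import pytest
from scipy import ndimage

from btvseg.imaging import ImageGeometry, StructureMask, SUVImage, VOISphere, rasterize_sphere
from btvseg.segmentation import (
    PERCENT_THRESHOLDS,
    LesionNotAboveBackgroundWarning,
    SearchRegion,
    ThresholdSpec,
    background_stats,
    exclude_structures,
    lesion_suv_max,
    percent_threshold_btv,
    percist_tlg_btv,
    run_all_algorithms,
)

from conftest import uniform_suv


def full_region(geometry) -> SearchRegion:
    return SearchRegion(StructureMask(geometry, np.ones(geometry.shape, dtype=bool)))


class TestLesionSuvMax:
    def test_constant_field(self, geom8):
        value, seed = lesion_suv_max(uniform_suv(geom8, 7.0), full_region(geom8))
        assert value == 7.0
        assert all(0 <= s < n for s, n in zip(seed, geom8.shape))

    def test_finds_maximum(self, geom8, rng):
        vals = rng.uniform(1.0, 8.9, geom8.shape)
        vals[2, 5, 1] = 9.2
        value, seed = lesion_suv_max(SUVImage(geom8, vals), full_region(geom8))
        assert value == 9.2 and seed == (2, 5, 1)

    def test_tie_break_is_lexicographic(self, geom8, rng):
        vals = rng.uniform(0.0, 1.0, geom8.shape)
        for idx in [(5, 1, 7), (2, 6, 0), (2, 3, 4)]:
            vals[idx] = 2.0
        _, seed = lesion_suv_max(SUVImage(geom8, vals), full_region(geom8))
        # brute-force lexicographic scan oracle
        expected = min(map(tuple, np.argwhere(vals == 2.0)))
        assert seed == expected

    def test_region_restricts_search(self, geom8):
        vals = np.ones(geom8.shape)
        vals[0, 0, 0] = 50.0
        vals[4, 4, 4] = 5.0
        region_vox = np.zeros(geom8.shape, dtype=bool)
        region_vox[3:6, 3:6, 3:6] = True
        region = SearchRegion(StructureMask(geom8, region_vox))
        value, seed = lesion_suv_max(SUVImage(geom8, vals), region)
        assert value == 5.0 and seed == (4, 4, 4)

    def test_empty_region_errors(self, geom8):
        with pytest.raises(ValueError):
            SearchRegion(StructureMask(geom8, np.zeros(geom8.shape, dtype=bool)))


class TestPercentThreshold:
    def test_noiseless_sphere_recovered_exactly_at_any_percent(self, rng):
        g = ImageGeometry(shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0), origin=(1.0, 1.0, 1.0))
        sphere = rasterize_sphere(VOISphere((24.0, 24.0, 24.0), 10.0), g)
        vals = np.where(sphere.voxels, 10.0, 0.0)
        pet = SUVImage(g, vals)
        for pct in (0.05, *PERCENT_THRESHOLDS, 1.0):
            btv = percent_threshold_btv(pet, full_region(g),
                                        ThresholdSpec("percent_of_max", percent=pct))
            np.testing.assert_array_equal(btv.voxels, sphere.voxels)

    def test_1d_profile_half_max(self):
        g = ImageGeometry(shape=(7, 1, 1), spacing=(4.0, 4.0, 4.0))
        pet = SUVImage(g, np.array([0, 2, 5, 10, 5, 2, 0], dtype=float).reshape(7, 1, 1))
        btv = percent_threshold_btv(pet, full_region(g),
                                    ThresholdSpec("percent_of_max", percent=0.50))
        np.testing.assert_array_equal(btv.voxels[:, 0, 0],
                                      [False, False, True, True, True, False, False])

    def test_two_lesions_only_seed_component_kept(self):
        g = ImageGeometry(shape=(20, 5, 5), spacing=(4.0, 4.0, 4.0))
        vals = np.zeros(g.shape)
        vals[2:5, 1:4, 1:4] = 10.0   # global-max lesion
        vals[12:15, 1:4, 1:4] = 8.0  # second lesion, above 0.38 * 10
        pet = SUVImage(g, vals)
        btv = percent_threshold_btv(pet, full_region(g),
                                    ThresholdSpec("percent_of_max", percent=0.38))
        # oracle: brute-force connected components of the candidate set
        candidates = vals >= 3.8
        labels, _ = ndimage.label(candidates, structure=np.ones((3, 3, 3)))
        expected = labels == labels[2, 1, 1]
        np.testing.assert_array_equal(btv.voxels, expected)
        assert not btv.voxels[12:15].any()

    def test_nestedness_with_noise(self, rng):
        g = ImageGeometry(shape=(16, 16, 16), spacing=(4.0, 4.0, 4.0), origin=(2.0, 2.0, 2.0))
        sphere = rasterize_sphere(VOISphere((32.0, 32.0, 32.0), 20.0), g)
        vals = np.clip(np.where(sphere.voxels, 9.0, 1.0) + rng.normal(0, 0.5, g.shape), 0, None)
        pet = SUVImage(g, vals)
        vols = [
            percent_threshold_btv(pet, full_region(g),
                                  ThresholdSpec("percent_of_max", percent=p)).volume_ml
            for p in PERCENT_THRESHOLDS
        ]
        assert vols == sorted(vols, reverse=True)

    def test_scale_invariance(self, rng):
        g = ImageGeometry(shape=(12, 12, 12), spacing=(4.0, 4.0, 4.0))
        vals = rng.uniform(0.5, 10.0, g.shape)
        pet_a, pet_b = SUVImage(g, vals), SUVImage(g, 3.7 * vals)
        spec = ThresholdSpec("percent_of_max", percent=0.42)
        a = percent_threshold_btv(pet_a, full_region(g), spec)
        b = percent_threshold_btv(pet_b, full_region(g), spec)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestBackgroundStats:
    def liver_grid(self):
        return ImageGeometry(shape=(30, 30, 30), spacing=(2.0, 2.0, 2.0), origin=(1.0, 1.0, 1.0))

    def test_constant_liver(self):
        g = self.liver_grid()
        stats = background_stats(uniform_suv(g, 2.5), VOISphere((30.0, 30.0, 30.0), 15.0))
        assert stats.mean_suv == pytest.approx(2.5)
        assert stats.sd_suv == 0.0
        assert stats.n_voxels > 2

    def test_three_voxel_hand_arithmetic(self):
        g = ImageGeometry(shape=(3, 1, 1), spacing=(4.0, 4.0, 4.0))
        pet = SUVImage(g, np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        # r ~ 5 mm sphere centred on the middle voxel covers exactly 3 centres
        stats = background_stats(pet, VOISphere((4.0, 0.0, 0.0), 0.52))
        assert stats.n_voxels == 3
        assert stats.mean_suv == pytest.approx(2.0)
        assert stats.sd_suv == pytest.approx(1.0)  # sample SD, n-1 denominator

    def test_gaussian_liver_monte_carlo(self, rng):
        g = self.liver_grid()
        pet = SUVImage(g, np.clip(rng.normal(2.0, 0.3, g.shape), 0, None))
        stats = background_stats(pet, VOISphere((30.0, 30.0, 30.0), 15.0))
        assert stats.mean_suv == pytest.approx(2.0, abs=0.05)
        assert stats.sd_suv == pytest.approx(0.3, abs=0.05)

    def test_too_few_voxels_errors(self):
        g = ImageGeometry(shape=(3, 3, 3), spacing=(4.0, 4.0, 4.0))
        with pytest.raises(ValueError):
            background_stats(uniform_suv(g, 1.0), VOISphere((4.0, 4.0, 4.0), 0.001))


class TestPercistTlg:
    def test_threshold_hand_arithmetic(self):
        from btvseg.segmentation import BackgroundStats

        assert BackgroundStats(2.0, 0.2, 100).threshold(3.0) == pytest.approx(2.6)

    def test_noiseless_sphere_with_constant_liver(self):
        g = ImageGeometry(shape=(40, 40, 20), spacing=(4.0, 4.0, 4.0), origin=(2.0, 2.0, 2.0))
        lesion = rasterize_sphere(VOISphere((40.0, 40.0, 40.0), 20.0), g)
        liver = rasterize_sphere(VOISphere((120.0, 120.0, 40.0), 15.0), g)
        vals = np.zeros(g.shape)
        vals[lesion.voxels] = 10.0
        vals[liver.voxels] = 2.0
        pet = SUVImage(g, vals)
        region = SearchRegion.from_box(g, (40.0, 40.0, 40.0), (30.0, 30.0, 30.0))
        spec = ThresholdSpec("percist_tlg", sd_multiplier=3.0,
                             background_voi=VOISphere((120.0, 120.0, 40.0), 15.0))
        btv = percist_tlg_btv(pet, region, spec)
        np.testing.assert_array_equal(btv.voxels, lesion.voxels)

    def test_sub_background_lesion_flags_and_returns_empty(self):
        g = ImageGeometry(shape=(40, 40, 20), spacing=(4.0, 4.0, 4.0), origin=(2.0, 2.0, 2.0))
        vals = np.full(g.shape, 0.5)
        liver = rasterize_sphere(VOISphere((120.0, 120.0, 40.0), 15.0), g)
        vals[liver.voxels] = 2.0
        lesion_region = SearchRegion.from_box(g, (40.0, 40.0, 40.0), (20.0, 20.0, 20.0))
        vals[20 // 4, 10, 10] = 0.0
        pet = SUVImage(g, vals)
        spec = ThresholdSpec("percist_tlg", sd_multiplier=3.0,
                             background_voi=VOISphere((120.0, 120.0, 40.0), 15.0))
        with pytest.warns(LesionNotAboveBackgroundWarning):
            btv = percist_tlg_btv(pet, lesion_region, spec)
        assert btv.is_empty


class TestExcludeStructures:
    def test_set_arithmetic(self, geom8, rng):
        btv_vox = np.zeros(geom8.shape, dtype=bool)
        btv_vox.flat[:100] = True
        avoid_vox = np.zeros(geom8.shape, dtype=bool)
        avoid_vox.flat[70:120] = True  # overlaps 30 of the 100
        out = exclude_structures(StructureMask(geom8, btv_vox), StructureMask(geom8, avoid_vox))
        assert int(out.voxels.sum()) == 70

    def test_empty_avoid_is_identity(self, geom8, rng):
        btv = StructureMask(geom8, rng.random(geom8.shape) < 0.3)
        empty = StructureMask(geom8, np.zeros(geom8.shape, dtype=bool))
        np.testing.assert_array_equal(exclude_structures(btv, empty).voxels, btv.voxels)

    def test_full_exclusion(self, geom8, rng):
        btv = StructureMask(geom8, rng.random(geom8.shape) < 0.3)
        assert exclude_structures(btv, StructureMask(geom8, np.ones(geom8.shape, bool))).is_empty

    def test_geometry_mismatch(self, geom8):
        other = ImageGeometry(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            exclude_structures(StructureMask(geom8, np.ones(geom8.shape, bool)),
                               StructureMask(other, np.ones(other.shape, bool)))


def test_run_all_algorithms_returns_five_connected_masks():
    g = ImageGeometry(shape=(40, 40, 20), spacing=(4.0, 4.0, 4.0), origin=(2.0, 2.0, 2.0))
    lesion = rasterize_sphere(VOISphere((40.0, 40.0, 40.0), 20.0), g)
    liver = rasterize_sphere(VOISphere((120.0, 120.0, 40.0), 15.0), g)
    vals = np.zeros(g.shape)
    vals[lesion.voxels] = 10.0
    vals[liver.voxels] = 2.0
    region = SearchRegion.from_box(g, (40.0, 40.0, 40.0), (30.0, 30.0, 30.0))
    btvs = run_all_algorithms(SUVImage(g, vals), region, VOISphere((120.0, 120.0, 40.0), 15.0))
    assert set(btvs) == {"SUV38", "SUV42", "SUV47", "SUV50", "PERCIST"}
    for mask in btvs.values():
        _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1
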