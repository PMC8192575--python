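"""Tests for the image core: refinement, thinning, EDT, regional measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.distance import cdist

from vesselmorph import (
    BinaryVolume,
    CenterlineSet,
    GridMismatchError,
    GridSpec,
    LabelVolume,
    PhantomSpec,
    ProbabilityVolume,
    artery_mean_radius,
    centerline_radii,
    distance_transform,
    extract_measurements,
    intracranial_volume,
    make_tube_phantom,
    refine_segmentation,
    skeletonize3d,
    standard_phantom_spec,
    territory_density,
    territory_mean_radius,
)

from conftest import random_tube_spec

ISO = GridSpec(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))
S26 = np.ones((3, 3, 3))


def bv(data, grid=None):
    data = np.asarray(data, dtype=np.uint8)
    return BinaryVolume(data=data, grid=grid or GridSpec(shape=data.shape, spacing=(1, 1, 1)))


def brute_force_edt(mask: np.ndarray, spacing) -> np.ndarray:
    """O(n^2) nearest-background search, the independent oracle."""
    sp = np.asarray(spacing)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    if len(fg) and len(bg):
        D = cdist(fg * sp, bg * sp)
        out[tuple(fg.T)] = D.min(axis=1)
    return out


class TestRefinement:
    def grid(self):
        return GridSpec(shape=(4, 4, 4), spacing=(1, 1, 1))

    def test_below_threshold_removed_at_kept(self):
        g = self.grid()
        mask = np.ones(g.shape, dtype=np.uint8)
        atlas = np.full(g.shape, 0.5)
        atlas[0, 0, 0] = 0.005   # below 1% -> removed
        atlas[0, 0, 1] = 0.01    # exactly 1% -> kept (strictly-below rule)
        out = refine_segmentation(bv(mask, g), ProbabilityVolume(data=atlas, grid=g))
        assert out.data[0, 0, 0] == 0
        assert out.data[0, 0, 1] == 1
        assert out.data.sum() == mask.sum() - 1

    def test_identity_atlas(self):
        g = self.grid()
        rng = np.random.default_rng(0)
        mask = (rng.random(g.shape) < 0.3).astype(np.uint8)
        atlas = ProbabilityVolume(data=np.ones(g.shape), grid=g)
        out = refine_segmentation(bv(mask, g), atlas)
        np.testing.assert_array_equal(out.data, mask)

    def test_idempotent_and_antiextensive(self):
        rng = np.random.default_rng(1)
        g = GridSpec(shape=(10, 10, 10), spacing=(0.7, 0.7, 0.7))
        mask = bv((rng.random(g.shape) < 0.4).astype(np.uint8), g)
        atlas = ProbabilityVolume(data=rng.random(g.shape), grid=g)
        once = refine_segmentation(mask, atlas, threshold=0.3)
        twice = refine_segmentation(once, atlas, threshold=0.3)
        assert (once.data <= mask.data).all()
        np.testing.assert_array_equal(once.data, twice.data)

    def test_grid_mismatch_rejected(self):
        g1, g2 = self.grid(), GridSpec(shape=(5, 4, 4), spacing=(1, 1, 1))
        with pytest.raises(GridMismatchError, match="different grids"):
            refine_segmentation(
                bv(np.zeros(g1.shape), g1),
                ProbabilityVolume(data=np.zeros(g2.shape), grid=g2),
            )


class TestSkeletonize:
    def test_thin_path_unchanged(self):
        g = GridSpec(shape=(20, 5, 5), spacing=(1, 1, 1))
        mask = np.zeros(g.shape, dtype=np.uint8)
        mask[2:18, 2, 2] = 1
        cl = skeletonize3d(bv(mask, g))
        assert len(cl) == 16
        got = np.zeros(g.shape, bool)
        got[tuple(cl.voxels.T)] = True
        np.testing.assert_array_equal(got, mask.astype(bool))

    def test_cylinder_skeleton_near_axis(self, cylinder_phantom):
        spec, ph = cylinder_phantom
        cl = skeletonize3d(ph.mask)
        sk = np.zeros(ph.mask.grid.shape, bool)
        sk[tuple(cl.voxels.T)] = True
        assert ndimage.label(sk, S26)[1] == 1
        # every skeleton voxel within 1 voxel of the true axis (x = y = 12)
        assert (np.abs(cl.voxels[:, :2] - 12).max(axis=1) <= 1).all()

    def test_two_cylinders_two_components(self, two_cylinder_phantom):
        _, ph = two_cylinder_phantom
        cl = skeletonize3d(ph.mask)
        sk = np.zeros(ph.mask.grid.shape, bool)
        sk[tuple(cl.voxels.T)] = True
        assert ndimage.label(sk, S26)[1] == 2

    def test_subset_components_idempotence(self):
        """Skeleton is inside the mask, keeps its component count, and is a
        fixed point of thinning — over random tube phantoms."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            ph = make_tube_phantom(random_tube_spec(rng, max_shape=22))
            cl = skeletonize3d(ph.mask)
            assert ph.mask.data[tuple(cl.voxels.T)].all()
            sk = np.zeros(ph.mask.grid.shape, np.uint8)
            sk[tuple(cl.voxels.T)] = 1
            assert ndimage.label(sk, S26)[1] == ndimage.label(ph.mask.data, S26)[1]
            again = skeletonize3d(bv(sk, ph.mask.grid))
            np.testing.assert_array_equal(
                np.sort(again.voxels, axis=0), np.sort(cl.voxels, axis=0)
            )

    def test_empty_mask(self):
        cl = skeletonize3d(bv(np.zeros(ISO.shape), ISO))
        assert len(cl) == 0


class TestDistanceTransform:
    def test_single_voxel(self):
        mask = np.zeros(ISO.shape, dtype=np.uint8)
        mask[4, 4, 4] = 1
        d = distance_transform(bv(mask))
        assert d[4, 4, 4] == pytest.approx(1.0)
        assert d.sum() == pytest.approx(1.0)

    def test_center_of_3cube(self):
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[3:6, 3:6, 3:6] = 1
        d = distance_transform(bv(mask))
        assert d[4, 4, 4] == pytest.approx(2.0)

    def test_all_foreground_rejected(self):
        with pytest.raises(ValueError, match="no background"):
            distance_transform(bv(np.ones(ISO.shape)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_random_masks(self, seed):
        """Exact agreement with the O(n^2) oracle on random anisotropic masks."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 11, 3))
        spacing = tuple(rng.choice([0.5, 0.7, 1.0, 1.3], 3))
        mask = rng.random(shape) < rng.uniform(0.2, 0.8)
        if mask.all():
            mask[0, 0, 0] = False
        g = GridSpec(shape=shape, spacing=spacing)
        d = distance_transform(bv(mask.astype(np.uint8), g))
        np.testing.assert_allclose(d, brute_force_edt(mask, spacing), atol=1e-9)


class TestCenterlineRadii:
    def _tube_mean_radius(self, radius, spacing, length=30.0):
        n_xy = int(np.ceil((2 * radius + 6) / spacing))
        n_z = int(np.ceil((length + 8) / spacing))
        g = GridSpec(shape=(n_xy, n_xy, n_z), spacing=(spacing,) * 3)
        c = (n_xy // 2) * spacing
        z0, z1 = 3 * spacing, (n_z - 4) * spacing
        ph = make_tube_phantom(PhantomSpec(
            segments=[((c, c, z0), (c, c, z1), radius)], grid=g, seed=0))
        cl = centerline_radii(skeletonize3d(ph.mask), distance_transform(ph.mask))
        z = cl.voxels[:, 2] * spacing
        keep = (z > z0 + radius + spacing) & (z < z1 - radius - spacing)
        return float(cl.radius_mm[keep].mean())

    def test_tube_radius_recovery_1mm(self):
        assert 2.5 <= self._tube_mean_radius(3.0, 1.0) <= 3.5

    def test_finer_grid_tightens_recovery(self):
        m = self._tube_mean_radius(3.0, 0.5)
        assert 2.75 <= m <= 3.25
        assert abs(m - 3.0) <= abs(self._tube_mean_radius(3.0, 1.0) - 3.0)

    def test_single_voxel_line(self):
        g = GridSpec(shape=(20, 7, 7), spacing=(0.7, 0.7, 0.7))
        mask = np.zeros(g.shape, dtype=np.uint8)
        mask[3:17, 3, 3] = 1
        m = bv(mask, g)
        cl = centerline_radii(skeletonize3d(m), distance_transform(m))
        np.testing.assert_allclose(cl.radius_mm, 0.7)

    def test_zero_distance_rejected(self):
        mask = np.zeros(ISO.shape, dtype=np.uint8)
        mask[4, 4, 4] = 1
        d = distance_transform(bv(mask))
        with pytest.raises(ValueError, match="zero distance"):
            centerline_radii(CenterlineSet(voxels=np.array([[0, 0, 0]])), d)


class TestRegionalStats:
    def _territory(self, grid, region_slice, label=1, name="ACA_L"):
        data = np.zeros(grid.shape, dtype=np.int32)
        data[region_slice] = label
        return LabelVolume(data=data, grid=grid, label_names={label: name})

    def test_density_direct_ratio(self):
        g = GridSpec(shape=(10, 10, 10), spacing=(1, 1, 1))
        terr = self._territory(g, np.s_[:, :, :])  # 1000 voxels
        mask = np.zeros(g.shape, dtype=np.uint8)
        mask.flat[:10] = 1
        assert territory_density(bv(mask, g), terr, "ACA_L") == pytest.approx(1.0)
        assert territory_density(bv(np.zeros(g.shape), g), terr, 1) == 0.0

    def test_density_phantom_exhaustive_count(self, cylinder_phantom):
        _, ph = cylinder_phantom
        terr = ph.territories
        for lab, name in terr.label_names.items():
            region = terr.data == lab
            expected = 100.0 * (ph.mask.data.astype(bool) & region).sum() / region.sum()
            assert territory_density(ph.mask, terr, name) == pytest.approx(expected)

    def test_density_translation_invariance(self, cylinder_phantom):
        _, ph = cylinder_phantom
        g = ph.mask.grid
        shifted_mask = bv(np.roll(ph.mask.data, 2, axis=0), g)
        shifted_terr = LabelVolume(data=np.roll(ph.territories.data, 2, axis=0),
                                   grid=g, label_names=ph.territories.label_names)
        for name in ph.territories.label_names.values():
            a = territory_density(ph.mask, ph.territories, name)
            b = territory_density(shifted_mask, shifted_terr, name)
            assert a == pytest.approx(b)

    def test_empty_territory_rejected(self):
        g = GridSpec(shape=(6, 6, 6), spacing=(1, 1, 1))
        terr = LabelVolume(data=np.zeros(g.shape, dtype=np.int32), grid=g,
                           label_names={})
        with pytest.raises((ValueError, KeyError)):
            territory_density(bv(np.zeros(g.shape), g), terr, 1)

    def test_mean_radius_single_and_equal_weight(self):
        g = GridSpec(shape=(10, 10, 10), spacing=(1, 1, 1))
        terr = self._territory(g, np.s_[:, :, :])
        one = CenterlineSet(voxels=np.array([[2, 2, 2]]), radius_mm=np.array([2.0]))
        assert territory_mean_radius(one, terr, "ACA_L") == pytest.approx(2.0)
        # two tubes, radii 2 and 4 mm, equal centerline voxel counts -> 3 mm
        vox = np.array([[1, 1, z] for z in range(4)] + [[5, 5, z] for z in range(4)])
        rad = np.array([2.0] * 4 + [4.0] * 4)
        both = CenterlineSet(voxels=vox, radius_mm=rad)
        assert territory_mean_radius(both, terr, 1) == pytest.approx(3.0)

    def test_mean_radius_missing_is_nan_not_zero(self):
        g = GridSpec(shape=(10, 10, 10), spacing=(1, 1, 1))
        terr = self._territory(g, np.s_[:5, :, :])
        off = CenterlineSet(voxels=np.array([[8, 8, 8]]), radius_mm=np.array([1.0]))
        assert np.isnan(territory_mean_radius(off, terr, "ACA_L"))
        assert np.isnan(artery_mean_radius(off, terr, "ACA_L"))

    def test_artery_mask_on_radius_step(self):
        """A mask straddling a 2 mm -> 1 mm step averages between the radii."""
        g = GridSpec(shape=(14, 14, 40), spacing=(1, 1, 1))
        ph = make_tube_phantom(PhantomSpec(
            segments=[((7, 7, 3), (7, 7, 20), 2.0), ((7, 7, 20), (7, 7, 36), 1.0)],
            grid=g, seed=0))
        cl = centerline_radii(skeletonize3d(ph.mask), distance_transform(ph.mask))
        arte = np.zeros(g.shape, dtype=np.int32)
        arte[5:10, 5:10, 14:27] = 1
        vol = LabelVolume(data=arte, grid=g, label_names={1: "step"})
        m = artery_mean_radius(cl, vol, "step")
        assert 1.0 <= m <= 2.0 + 0.5


class TestICV:
    @pytest.mark.parametrize("count,spacing,expected", [
        (1000, 1.0, 1.0),
        (1000, 0.7, 0.343),
        (1_402_440, 1.0, 1402.44),
    ])
    def test_volume_conversion(self, count, spacing, expected):
        nz = int(np.ceil(count / (128 * 128)))
        g = GridSpec(shape=(128, 128, nz), spacing=(spacing,) * 3)
        data = np.zeros(g.shape, dtype=np.uint8)
        data.flat[:count] = 1
        assert intracranial_volume(bv(data, g)) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intracranial_volume(bv(np.zeros(ISO.shape)))


@pytest.fixture(scope="module")
def standard():
    spec = standard_phantom_spec(seed=3)
    ph = make_tube_phantom(spec)
    meas = extract_measurements(ph.mask, ph.prob_atlas, ph.territories,
                                ph.artery_masks, ph.icv_mask)
    return spec, ph, meas


class TestExtractMeasurements:
    def test_all_fields_populated_radii_near_truth(self, standard):
        spec, ph, meas = standard
        d = meas.as_dict()
        assert len(d) == 25
        assert meas.missing == []
        sp = max(ph.mask.grid.spacing)
        for name, lab in ((n, i) for i, n in enumerate(
                ["ACA_A1_L", "ACA_A1_R", "ACA_A2", "PCA_L", "PCA_R", "MCA_M1_L",
                 "MCA_M1_R", "MCA_M2_L", "MCA_M2_R", "ICA_L", "ICA_R", "BA"])):
            true_r = spec.segments[spec.artery_segment_map[name]][2]
            got = d[f"artery_radius_mm_{name}"]
            assert abs(got - true_r) <= sp / 2 + sp, (name, got, true_r)
        for t in ("ACA_L", "ACA_R", "MCA_L", "MCA_R", "PCA_L", "PCA_R"):
            assert 0 <= d[f"density_pct_{t}"] <= 100

    def test_refinement_annihilation_flags_qc(self, standard):
        _, ph, _ = standard
        g = ph.mask.grid
        low = ProbabilityVolume(data=np.full(g.shape, 0.005), grid=g)
        meas = extract_measurements(ph.mask, low, ph.territories,
                                    ph.artery_masks, ph.icv_mask)
        assert meas.qc_empty_after_refinement
        vals = meas.as_dict()
        assert all(np.isnan(v) for k, v in vals.items() if k != "icv_cm3")
        assert len(meas.missing) == 24

    def test_determinism(self, standard):
        _, ph, meas = standard
        again = extract_measurements(ph.mask, ph.prob_atlas, ph.territories,
                                     ph.artery_masks, ph.icv_mask)
        assert again.as_dict() == meas.as_dict()

    def test_merged_subterritories_union(self):
        """proximal/middle/distal sub-labels are unioned before measuring."""
        spec = standard_phantom_spec(seed=1)
        ph = make_tube_phantom(spec)
        g = ph.mask.grid
        terr = ph.territories
        # split each territory into a proximal (lower z) and distal half
        data = terr.data.copy()
        names = {}
        nz = g.shape[2]
        for lab, name in terr.label_names.items():
            band, side = name.rsplit("_", 1)
            hi = (terr.data == lab) & (np.arange(nz)[None, None, :] >= nz // 2)
            data[hi] = lab + 100
            names[lab] = f"{band}_proximal_{side}"
            names[lab + 100] = f"{band}_distal_{side}"
        split = LabelVolume(data=data, grid=g, label_names=names)
        merged = extract_measurements(ph.mask, ph.prob_atlas, split,
                                      ph.artery_masks, ph.icv_mask)
        plain = extract_measurements(ph.mask, ph.prob_atlas, terr,
                                     ph.artery_masks, ph.icv_mask)
        for k, v in plain.as_dict().items():
            assert merged.as_dict()[k] == pytest.approx(v, nan_ok=True)
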