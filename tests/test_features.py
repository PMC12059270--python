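"""Feature extraction: slice selection, discretization, the 93-feature set."""

import numpy as np
import pytest

from radstab import _texture as tx
from radstab.features import (
    FAMILY_COUNTS,
    DiscretizationConfig,
    discretize,
    extract_features,
    feature_frame,
    feature_manifest,
    first_order_features,
    select_2d_slice,
)
from radstab.fitting import ParametricMapSet


class TestManifest:
    def test_family_counts_and_total(self):
        man = feature_manifest()
        assert len(man) == 93
        for family, count in FAMILY_COUNTS.items():
            assert sum(m.startswith(family + "_") for m in man) == count

    def test_ids_unique(self):
        man = feature_manifest()
        assert len(set(man)) == len(man)


class TestSelect2dSlice:
    def test_tie_broken_by_lowest_index(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:3, 0, 0] = True       # area 3
        mask[:3, :3, 1] = False
        mask[0:3, 0:3, 1] = np.array([[1, 1, 1], [1, 1, 1], [1, 0, 0]], dtype=bool)
        mask[0:3, 0:3, 2] = np.array([[1, 1, 1], [1, 1, 1], [1, 0, 0]], dtype=bool)
        mask[:2, 0, 3] = True       # area 2
        roi = select_2d_slice(mask)
        assert roi.slice_index == 1
        assert roi.mask[:, :, 1].sum() == 7
        assert roi.mask.sum() == 7

    def test_single_slice_mask(self):
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[1:3, 1:3, 2] = True
        roi = select_2d_slice(mask)
        assert roi.slice_index == 2

    def test_ellipsoid_equatorial_slice(self):
        z, y, x = np.ogrid[:17, :17, :17]
        mask = ((z - 8) / 6.0) ** 2 + ((y - 8) / 6.0) ** 2 + ((x - 8) / 4.0) ** 2 <= 1
        roi = select_2d_slice(mask)
        assert roi.slice_index == 8

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_2d_slice(np.zeros((3, 3, 3), dtype=bool))


class TestDiscretize:
    def test_bin_edge_arithmetic(self):
        lv, ng = discretize([0.0, 0.5, 1.0], DiscretizationConfig(n_bins=2))
        assert lv.tolist() == [1, 2, 2] and ng == 2

    def test_constant_region_single_level(self):
        lv, ng = discretize([3.3, 3.3, 3.3])
        assert ng == 1 and set(lv.tolist()) == {1}

    def test_affine_invariance(self, rng):
        v = rng.integers(0, 64, size=200) / 64.0
        lv1, _ = discretize(v, DiscretizationConfig(n_bins=8))
        lv2, _ = discretize(4.0 * v + 128.0, DiscretizationConfig(n_bins=8))
        assert np.array_equal(lv1, lv2)

    def test_fixed_bin_width(self):
        lv, ng = discretize([0.1, 0.95, 2.4],
                            DiscretizationConfig(method="fixed_bin_width", bin_width=1.0))
        assert lv.tolist() == [1, 1, 3] and ng == 3


class TestFirstOrder:
    def test_hand_computed_values(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == 2.5
        assert f["Median"] == 2.5
        assert f["Energy"] == 30.0
        assert f["Range"] == 3.0
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))

    def test_percentile_linear_interpolation(self):
        f = first_order_features(np.arange(1.0, 11.0))
        assert f["10Percentile"] == pytest.approx(1.9)

    def test_constant_values_degenerate(self):
        f = first_order_features(np.full(9, 4.2))
        assert f["Variance"] == 0.0
        assert f["Range"] == 0.0
        assert f["Uniformity"] == 1.0
        assert np.isnan(f["Skewness"]) and np.isnan(f["Kurtosis"])

    def test_total_energy_scales_with_voxel_volume(self):
        v = np.array([1.0, 2.0])
        f = first_order_features(v, voxel_volume=2.5)
        assert f["TotalEnergy"] == pytest.approx(2.5 * f["Energy"])


def _map_set_from(array, fit_mask=None):
    """Wrap one array as all six maps of a ParametricMapSet."""
    grid = array.shape
    ones = np.ones(grid)
    if fit_mask is None:
        fit_mask = np.ones(grid, dtype=bool)
    return ParametricMapSet(
        adc=array, d=array, d_star=array, f=array, md=array, mk=array,
        r2_ivim=ones, r2_dki=ones, fit_mask=fit_mask,
    )


class TestExtractFeatures:
    def test_93_per_map_558_per_mode(self, rng):
        arr = rng.random((8, 8, 4))
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:7, 2:7, 1:3] = True
        ms = _map_set_from(arr)
        from radstab.features import RoiMask

        out = extract_features(ms, RoiMask(mask=mask, mode="3D"))
        assert len(out) == 6
        for fv in out.values():
            assert len(fv.values) == 93
        frame = feature_frame(out.values())
        assert len(frame) == 558

    def test_2d_equals_3d_for_single_slice_lesion(self, rng):
        arr = rng.random((8, 8, 4))
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:7, 2:7, 2] = True
        ms = _map_set_from(arr)
        from radstab.features import RoiMask

        roi2 = select_2d_slice(mask)
        roi3 = RoiMask(mask=mask, mode="3D")
        f2 = extract_features(ms, roi2)["ADC"].values
        f3 = extract_features(ms, roi3)["ADC"].values
        for key in f2:
            if key.startswith("firstorder_"):
                assert f2[key] == pytest.approx(f3[key], rel=1e-12)

    def test_affine_shift_changes_mean_not_texture(self, rng):
        vals = rng.integers(0, 64, size=(8, 8, 4)) / 64.0
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[1:7, 1:7, 1:3] = True
        from radstab.features import RoiMask

        roi = RoiMask(mask=mask, mode="3D")
        f1 = extract_features(_map_set_from(vals), roi)["ADC"].values
        f2 = extract_features(_map_set_from(vals + 100.0), roi)["ADC"].values
        assert f2["firstorder_Mean"] == pytest.approx(f1["firstorder_Mean"] + 100.0)
        for key in f1:
            fam = key.split("_")[0]
            if fam in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
                assert f2[key] == pytest.approx(f1[key], rel=1e-10), key

    def test_single_voxel_roi_degenerate_flagged(self):
        arr = np.ones((5, 5, 3))
        mask = np.zeros((5, 5, 3), dtype=bool)
        mask[2, 2, 1] = True
        from radstab.features import RoiMask

        fv = extract_features(_map_set_from(arr), RoiMask(mask=mask, mode="3D"))["ADC"]
        assert len(fv.values) == 93
        assert all(np.isfinite(v) for v in fv.values.values())
        assert any(fv.flags.values())  # texture features flagged degenerate

    def test_fit_mask_respected_and_missing_flag(self, rng):
        arr = rng.random((6, 6, 3))
        mask = np.zeros((6, 6, 3), dtype=bool)
        mask[1:5, 1:5, 1] = True
        fm = np.zeros((6, 6, 3), dtype=bool)  # empty fit mask
        from radstab.features import RoiMask

        out = extract_features(_map_set_from(arr, fit_mask=fm),
                               RoiMask(mask=mask, mode="3D"))
        assert all(fv.missing for fv in out.values())
        assert feature_frame(out.values()).empty

    def test_rotation_invariance_2d(self, rng):
        # 90-degree in-plane rotation leaves direction-averaged 2D features
        # unchanged (the 4 directions map onto each other)
        vals = rng.random((9, 9, 1))
        mask = rng.random((9, 9, 1)) > 0.3
        mask[..., 0][0, :] = False
        if mask.sum() < 5:
            mask[3:6, 3:6, 0] = True
        lv = np.zeros((9, 9), dtype=int)
        lv_vals, ng = discretize(vals[mask], DiscretizationConfig(n_bins=5))
        lv[mask[..., 0]] = lv_vals
        rot_lv = np.rot90(lv).copy()
        rot_mask = np.rot90(mask[..., 0]).copy()
        for fam in (tx.glcm_features, tx.glrlm_features, tx.glszm_features,
                    tx.ngtdm_features, tx.gldm_features):
            f1 = fam(lv, mask[..., 0], ng)
            f2 = fam(rot_lv, rot_mask, ng)
            for k in f1:
                if np.isnan(f1[k]) and np.isnan(f2[k]):
                    continue
                assert f1[k] == pytest.approx(f2[k], rel=1e-10), (fam.__name__, k)


class TestTextureExamples:
    """Spec'd hand-enumerated single-matrix examples."""

    def test_glcm_2x2_horizontal(self):
        lv = np.array([[1, 2], [1, 2]])
        P = tx.glcm_matrix(lv, np.ones((2, 2), bool), (0, 1), 2)
        np.testing.assert_allclose(P, [[0, 0.5], [0.5, 0]])
        f = tx.glcm_features_single(P)
        assert f["Contrast"] == 1.0
        assert f["JointEntropy"] == 1.0

    def test_glcm_constant_image(self):
        lv = np.ones((3, 3), dtype=int)
        f = tx.glcm_features(lv, np.ones((3, 3), bool), 1)
        assert f["Contrast"] == 0.0
        assert f["MaximumProbability"] == 1.0

    def test_glrlm_run_enumeration(self):
        lv = np.array([[1, 1, 2]])
        M = tx.glrlm_matrix(lv, np.ones((1, 3), bool), (0, 1), 2)
        f = tx._rlm_style_features(M, 3, "ShortRun", "LongRun", tx._GLRLM_MAP)
        assert f["GrayLevelNonUniformity"] == 1.0
        assert f["RunLengthNonUniformity"] == 1.0

    def test_glrlm_single_run_long_run_emphasis(self):
        L = 6
        lv = np.ones((1, L), dtype=int)
        M = tx.glrlm_matrix(lv, np.ones((1, L), bool), (0, 1), 1)
        f = tx._rlm_style_features(M, L, "ShortRun", "LongRun", tx._GLRLM_MAP)
        assert f["LongRunEmphasis"] == L**2

    def test_glrlm_checkerboard_all_short_runs(self):
        lv = np.indices((4, 4)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4), bool)
        M = tx.glrlm_matrix(lv, mask, (0, 1), 2)
        nr = M.sum()
        assert nr == 16  # all runs length 1
        f = tx._rlm_style_features(M, 16, "ShortRun", "LongRun", tx._GLRLM_MAP)
        assert f["RunLengthNonUniformity"] == nr

    def test_glszm_zone_enumeration(self):
        lv = np.array([[1, 1], [2, 3]])
        f = tx.glszm_features(lv, np.ones((2, 2), bool), 3)
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["SizeZoneNonUniformity"] == pytest.approx(5.0 / 3.0)

    def test_glszm_constant_zone_entropy(self):
        lv = np.ones((3, 3), dtype=int)
        f = tx.glszm_features(lv, np.ones((3, 3), bool), 1)
        assert f["ZoneEntropy"] == 0.0

    def test_ngtdm_constant(self):
        lv = np.ones((3, 3), dtype=int)
        f = tx.ngtdm_features(lv, np.ones((3, 3), bool), 1)
        assert f["Contrast"] == 0.0
        assert f["Complexity"] == 0.0

    def test_ngtdm_center_bump(self):
        # center level 2 in a field of 1s: s1 = 4/3 + 4/5, s2 = 1
        lv = np.ones((3, 3), dtype=int)
        lv[1, 1] = 2
        f = tx.ngtdm_features(lv, np.ones((3, 3), bool), 2)
        s1 = 4 * (1 / 3) + 4 * (1 / 5)
        s2 = 1.0
        sum_ps = (8 / 9) * s1 + (1 / 9) * s2
        assert f["Coarseness"] == pytest.approx(1.0 / sum_ps, rel=1e-12)
        contrast = (2 * (8 / 9) * (1 / 9) / 2) * ((s1 + s2) / 9)
        assert f["Contrast"] == pytest.approx(contrast, rel=1e-12)

    def test_ngtdm_coarseness_guard(self):
        # a single-voxel "region with neighbors" where s = 0 -> 1/eps guard
        lv = np.ones((2, 2), dtype=int)
        f = tx.ngtdm_features(lv, np.ones((2, 2), bool), 1)
        assert f["Coarseness"] == pytest.approx(1e6)

    def test_gldm_constant_2x2(self):
        lv = np.ones((2, 2), dtype=int)
        f = tx.gldm_features(lv, np.ones((2, 2), bool), 1)
        assert f["DependenceNonUniformity"] == pytest.approx(4.0)
        assert f["GrayLevelNonUniformity"] == pytest.approx(4.0)

    def test_gldm_constant_gln_equals_n(self):
        lv = np.ones((3, 4), dtype=int)
        f = tx.gldm_features(lv, np.ones((3, 4), bool), 1)
        assert f["GrayLevelNonUniformity"] == pytest.approx(12.0)
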