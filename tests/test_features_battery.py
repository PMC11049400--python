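import numpy as np
import pytest

from dceradiomics.features import (ExtractionConfig, extract_all,
                                   first_order_features, glcm_features,
                                   texture_features, discretize_volume)
from dceradiomics.features.texture import (ANGLES_13, glcm_matrices,
                                           glrlm_matrices, glszm_matrix)
from dceradiomics.phantom import PhantomSpec, generate_patient


class TestFirstOrder:
    def test_mean_and_range(self):
        feats, _ = first_order_features([1, 2, 3], bin_width=1, shift=0)
        assert feats["Mean"] == pytest.approx(2.0)
        assert feats["Range"] == pytest.approx(2.0)

    def test_energy_without_shift(self):
        feats, _ = first_order_features([1, 2], bin_width=1, shift=0)
        assert feats["Energy"] == pytest.approx(5.0)

    def test_shift_enters_energy_family_only(self):
        plain, _ = first_order_features([1, 2], bin_width=1, shift=0)
        shifted, _ = first_order_features([1, 2], bin_width=1, shift=10)
        assert shifted["Energy"] == pytest.approx(11**2 + 12**2)
        assert shifted["Mean"] == plain["Mean"]
        assert shifted["Entropy"] == plain["Entropy"]

    def test_uniform_two_level_histogram(self):
        feats, _ = first_order_features([0, 0, 30, 30], bin_width=25, shift=0)
        assert feats["Entropy"] == pytest.approx(1.0, abs=1e-9)
        assert feats["Uniformity"] == pytest.approx(0.5, abs=1e-9)

    def test_order_invariance(self, rng):
        vals = rng.normal(size=50)
        a, _ = first_order_features(vals, bin_width=1, shift=0)
        b, _ = first_order_features(rng.permutation(vals), bin_width=1, shift=0)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_constant_roi_flags_moment_features(self):
        feats, flags = first_order_features([5.0] * 10, bin_width=1, shift=0)
        assert feats["Skewness"] == 0.0 and feats["Kurtosis"] == 0.0
        assert {"Skewness", "Kurtosis"} <= flags


class TestGlcm:
    def test_two_by_two_row_direction_matrix(self):
        # grid [[1,1],[2,2]]: along the row direction the symmetric GLCM
        # has mass 0.5 at (1,1) and 0.5 at (2,2)
        levels = np.array([[[1, 1], [2, 2]]])
        mask = np.ones_like(levels, bool)
        mats = glcm_matrices(levels, mask)
        row_dir = mats[0]  # first angle with pairs is (0,0,1)
        np.testing.assert_allclose(row_dir, [[0.5, 0.0], [0.0, 0.5]])
        assert row_dir.max() == pytest.approx(0.5)

    def test_constant_roi_correlation_fallback(self):
        levels = np.ones((3, 3, 3), dtype=int)
        mask = np.ones((3, 3, 3), bool)
        feats, flags = glcm_features(levels, mask)
        assert feats["Correlation"] == 1.0
        assert "Correlation" in flags

    def test_single_voxel_roi_flagged_not_crashed(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        levels[1, 1, 1] = 1
        feats, flags = glcm_features(levels, mask)
        assert all(np.isnan(v) for v in feats.values())
        assert len(flags) == 22

    def test_symmetry_and_normalization(self, rng):
        levels = rng.integers(1, 5, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        for P in glcm_matrices(levels, mask):
            assert P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(P, P.T)
            assert (P >= 0).all()


class TestRunAndZoneMatrices:
    def test_glszm_constant_roi_single_zone(self):
        levels = np.ones((3, 3, 3), dtype=int)
        mask = np.ones((3, 3, 3), bool)
        P = glszm_matrix(levels, mask)
        assert P.shape == (1, 27)
        assert P[0, 26] == 1 and P.sum() == 1

    def test_glrlm_strip_runs(self):
        # 1D strip [1,1,2] along x: one run of length 2 (level 1), one of 1
        levels = np.array([[[1, 1, 2]]])
        mask = np.ones_like(levels, bool)
        mats = glrlm_matrices(levels, mask)
        x_dir = mats[ANGLES_13.index((0, 0, 1))]
        assert x_dir[0, 1] == 1  # level 1, run length 2
        assert x_dir[1, 0] == 1  # level 2, run length 1
        assert x_dir.sum() == 2

    def test_matrices_nonnegative(self, rng):
        levels = rng.integers(1, 4, (4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        mask[0, 0, 0] = True
        from dceradiomics.features.texture import gldm_matrix
        assert (gldm_matrix(levels * mask, mask) >= 0).all()
        assert (glszm_matrix(levels * mask, mask) >= 0).all()
        for P in glrlm_matrices(levels * mask, mask):
            assert (P >= 0).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            texture_features(np.ones((2, 2, 2), int), np.ones((2, 2, 2), bool), "XXX")


@pytest.fixture(scope="module")
def phantom_roi():
    pat = generate_patient(PhantomSpec(), 0)
    return pat.series.volumes[14], pat.masks["tumor"]


class TestExtractAll:
    def test_ct_preset_feature_count(self, phantom_roi):
        vol, mask = phantom_roi
        fv = extract_all(vol, mask, ExtractionConfig.ct_default())
        assert len(fv) == 1204

    def test_mr_preset_feature_count(self, phantom_roi):
        vol, mask = phantom_roi
        fv = extract_all(vol, mask, ExtractionConfig.mr_default())
        assert len(fv) == 1118

    def test_count_follows_image_set_arithmetic(self, phantom_roi):
        vol, mask = phantom_roi
        cfg = ExtractionConfig(log_sigmas=(1.0, 2.0), wavelet=False)
        fv = extract_all(vol, mask, cfg)
        assert len(fv) == 86 * 3

    def test_deterministic(self, phantom_roi):
        vol, mask = phantom_roi
        cfg = ExtractionConfig(log_sigmas=(2.0,), wavelet=False)
        a = extract_all(vol, mask, cfg)
        b = extract_all(vol, mask, cfg)
        assert a.values == b.values and a.flags == b.flags

    def test_flagged_features_hold_defined_values(self, phantom_roi):
        vol, mask = phantom_roi
        fv = extract_all(vol, mask, ExtractionConfig.ct_default())
        for name in fv.flags:
            assert name in fv.values
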