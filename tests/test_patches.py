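"""Patch sampling, per-eye preprocessing and PCA whitening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereoisa.patches import (
    PatchMatrix,
    apply_whitening,
    filters_to_pixel_space,
    fit_whitening,
    preprocess_patches,
    preprocess_vector,
    sample_patches,
)
from stereoisa.synthetic import DisparityFieldSpec, StereoImagePair, generate_stereo_pair


@pytest.fixture(scope="module")
def small_pairs():
    field = DisparityFieldSpec(mode="smooth-random", amplitude=1.0, seed=0)
    return [generate_stereo_pair(96, 96, field, seed=s) for s in range(2)]


class TestSamplePatches:
    def test_shape_is_n_by_two_eyes(self, small_pairs):
        pm = sample_patches(small_pairs, 10, 25, seed=0)
        assert pm.data.shape == (10, 1250)
        assert pm.stage == "raw"

    def test_constant_image_gives_constant_rows(self):
        pair = StereoImagePair(left=np.full((64, 64), 3.0), right=np.full((64, 64), 5.0))
        pm = sample_patches([pair], 4, 8, seed=0)
        assert np.all(pm.data[:, :64] == 3.0)
        assert np.all(pm.data[:, 64:] == 5.0)

    def test_same_seed_same_patches(self, small_pairs):
        a = sample_patches(small_pairs, 20, 12, seed=7)
        b = sample_patches(small_pairs, 20, 12, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_corresponding_locations_in_both_eyes(self):
        """The left and right halves come from identical image coordinates."""
        base = np.arange(64.0 * 64).reshape(64, 64)
        pair = StereoImagePair(left=base, right=base)
        pm = sample_patches([pair], 5, 9, seed=1)
        np.testing.assert_array_equal(pm.data[:, : 81], pm.data[:, 81:])

    def test_invalid_requests_rejected(self, small_pairs):
        with pytest.raises(ValueError):
            sample_patches(small_pairs, 0, 8)
        with pytest.raises(ValueError):
            sample_patches(small_pairs, 5, 500)


class TestPreprocess:
    def test_row_and_half_norms(self, small_pairs):
        pm = preprocess_patches(sample_patches(small_pairs, 50, 10, seed=2))
        half = 100
        np.testing.assert_allclose(np.linalg.norm(pm.data, axis=1), 1.0, atol=1e-10)
        for sl in (slice(0, half), slice(half, None)):
            np.testing.assert_allclose(
                np.linalg.norm(pm.data[:, sl], axis=1), 1 / np.sqrt(2), atol=1e-10
            )
            np.testing.assert_allclose(pm.data[:, sl].mean(axis=1), 0.0, atol=1e-12)

    def test_hand_computed_row(self):
        """Independent hand computation of the centring/normalisation chain."""
        row = np.array([[1.0, 2.0, 3.0, 4.0, 4.0, 6.0, 8.0, 10.0]])
        # left [1,2,3,4]: mean 2.5, centred [-1.5,-0.5,0.5,1.5], norm sqrt(5)
        # right [4,6,8,10]: mean 7, centred [-3,-1,1,3], norm sqrt(20)
        # after per-eye unit norm both halves are [-3,-1,1,3]/sqrt(20);
        # the concatenated norm is sqrt(2), so the final halves get 1/sqrt(2).
        half = np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(20.0) / np.sqrt(2.0)
        expected = np.concatenate([half, half])
        out = preprocess_patches(PatchMatrix(data=row, patch_px=2, stage="raw"))
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)

    def test_degenerate_half_dropped_and_counted(self):
        data = np.vstack([
            np.concatenate([np.full(4, 2.0), np.arange(4.0)]),  # left constant
            np.concatenate([np.arange(4.0), np.arange(4.0)]),
        ])
        out = preprocess_patches(PatchMatrix(data=data, patch_px=2, stage="raw"))
        assert out.n == 1
        assert out.n_dropped == 1

    def test_vector_matches_matrix_path(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(2 * 9)
        mat = preprocess_patches(PatchMatrix(data=row[None, :], patch_px=3, stage="raw"))
        np.testing.assert_allclose(preprocess_vector(row, 3), mat.data[0], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_normalisation(self, seed):
        """Re-normalising preprocessed rows changes nothing."""
        rng = np.random.default_rng(seed)
        raw = PatchMatrix(data=rng.standard_normal((3, 2 * 16)), patch_px=4, stage="raw")
        pre = preprocess_patches(raw)
        again = pre.data / np.linalg.norm(pre.data, axis=1, keepdims=True)
        np.testing.assert_allclose(again, pre.data, atol=1e-13)


class TestWhitening:
    def test_two_d_toy_closed_form(self):
        """Covariance diag(4, 1): eigenvalues recovered, output exactly white."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20_000, 2)) * np.array([2.0, 1.0])
        pm = PatchMatrix(data=x, patch_px=1, stage="preprocessed")
        t = fit_whitening(pm, 2)
        assert t.eigenvalues[0] == pytest.approx(4.0, rel=0.05)
        assert t.eigenvalues[1] == pytest.approx(1.0, rel=0.05)
        z = apply_whitening(t, pm)
        cov = z.data.T @ z.data / z.n
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-6)

    def test_whitened_covariance_identity(self, small_pairs):
        pm = preprocess_patches(sample_patches(small_pairs, 4000, 8, seed=3))
        t = fit_whitening(pm, 20)
        z = apply_whitening(t, pm)
        cov = (z.data - z.data.mean(0)).T @ (z.data - z.data.mean(0)) / z.n
        assert np.abs(cov - np.eye(20)).max() < 1e-6

    def test_already_white_data_gives_orthogonalish_forward(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50_000, 4))
        t = fit_whitening(PatchMatrix(data=x, patch_px=1, stage="preprocessed"), 4)
        gram = t.forward @ t.forward.T
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=0.05)

    def test_forward_inverse_identity_and_reconstruction(self, small_pairs):
        pm = preprocess_patches(sample_patches(small_pairs, 2000, 6, seed=4))
        t = fit_whitening(pm, 15)
        np.testing.assert_allclose(t.forward @ t.inverse, np.eye(15), atol=1e-8)
        x = pm.data[:5]
        recon = (t.forward @ (x - t.mean).T).T @ t.inverse.T + t.mean
        # residual orthogonal to retained subspace: re-projecting changes nothing
        re_recon = (t.forward @ (recon - t.mean).T).T @ t.inverse.T + t.mean
        np.testing.assert_allclose(re_recon, recon, atol=1e-10)

    def test_rank_deficient_request_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 3)) @ rng.standard_normal((3, 10))
        with pytest.raises(ValueError, match="rank"):
            fit_whitening(PatchMatrix(data=x, patch_px=1, stage="preprocessed"), 5)


class TestFiltersToPixelSpace:
    def test_two_path_response_equality(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3000, 8))
        pm = PatchMatrix(data=x, patch_px=2, stage="preprocessed")
        t = fit_whitening(pm, 8)
        w = rng.standard_normal((5, 8))
        v = filters_to_pixel_space(t, w)
        patch = rng.standard_normal(8)
        np.testing.assert_allclose(v @ patch, w @ (t.forward @ patch), atol=1e-10)

    def test_identity_whitening_leaves_filters(self):
        from stereoisa.patches import WhiteningTransform

        t = WhiteningTransform(mean=np.zeros(4), forward=np.eye(4),
                               inverse=np.eye(4), eigenvalues=np.ones(4))
        w = np.arange(8.0).reshape(2, 4)
        np.testing.assert_array_equal(filters_to_pixel_space(t, w), w)

    def test_zero_filter_maps_to_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((300, 6))
        t = fit_whitening(PatchMatrix(data=x, patch_px=1, stage="preprocessed"), 4)
        assert np.all(filters_to_pixel_space(t, np.zeros((1, 4))) == 0.0)
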