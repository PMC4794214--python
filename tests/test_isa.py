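"""Subspace model likelihood, optimisation and recovery behaviour."""

import numpy as np
import pytest

from stereoisa.isa import (
    ISAModel,
    ISAOptions,
    fit_isa,
    isa_objective,
    subspace_norm,
    subspace_recovery_score,
    _sym_orth,
)
from stereoisa.patches import apply_whitening, filters_to_pixel_space, fit_whitening
from stereoisa.synthetic import generate_isa_ground_truth_patches

FAST_OPTS = ISAOptions(n_restarts=3, burn_in=80, max_iter=300)


def make_model(w, n_subspaces, d=2):
    return ISAModel(W=w, n_subspaces=n_subspaces, subunits_per_subspace=d)


class TestSubspaceNorm:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.w = _sym_orth(rng.standard_normal((4, 4)))
        self.model = make_model(self.w, 2)

    def test_orthogonal_vector_gives_zero(self):
        # component orthogonal to subspace 0 = any combination of rows 2,3
        z = self.w[2] + 0.5 * self.w[3]
        assert subspace_norm(self.model, 0, z) == pytest.approx(0.0, abs=1e-10)

    def test_subunit_itself_gives_one(self):
        assert subspace_norm(self.model, 0, self.w[0]) == pytest.approx(1.0, abs=1e-10)

    def test_matches_explicit_two_dot_products(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(4)
        expected = np.sqrt((self.w[2] @ z) ** 2 + (self.w[3] @ z) ** 2)
        assert subspace_norm(self.model, 1, z) == pytest.approx(expected, abs=1e-12)

    def test_bad_index_rejected(self):
        with pytest.raises(IndexError):
            subspace_norm(self.model, 2, np.zeros(4))


class TestObjective:
    def test_all_zero_responses_closed_form(self):
        model = make_model(np.eye(4), 2)
        z = np.zeros((3, 4))
        opts = ISAOptions(eps=1e-4)
        expected = -np.sqrt(1e-4) * 2
        assert isa_objective(model, z, opts) == pytest.approx(expected, abs=1e-12)

    def test_three_four_five_triangle(self):
        """One subspace with responses (3, 4) scores -5 as eps -> 0."""
        model = make_model(np.eye(2), 1)
        z = np.array([[3.0, 4.0]])
        assert isa_objective(model, z, ISAOptions(eps=1e-12)) == pytest.approx(-5.0, abs=1e-5)

    def test_sparse_sources_beat_gaussian_at_matched_variance(self):
        """Monte-Carlo: E[-sqrt(u)] is larger for heavy-tailed sources."""
        rng = np.random.default_rng(2)
        n = 40_000
        gauss = rng.standard_normal((n, 2))
        # sparse radial sources, scaled to unit per-dim variance
        u_dir = rng.standard_normal((n, 2))
        u_dir /= np.linalg.norm(u_dir, axis=1, keepdims=True)
        r = rng.exponential(size=(n, 1))
        sparse = u_dir * r
        sparse /= sparse.std(axis=0, keepdims=True)
        model = make_model(np.eye(2), 1)
        opts = ISAOptions()
        assert isa_objective(model, sparse, opts) > isa_objective(model, gauss, opts)

    def test_invariant_under_in_subspace_rotation(self):
        rng = np.random.default_rng(3)
        w = _sym_orth(rng.standard_normal((4, 6)))
        z = rng.standard_normal((500, 6))
        opts = ISAOptions()
        base = isa_objective(make_model(w, 2), z, opts)
        for theta in (0.3, 1.2, -2.0):
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            w2 = w.copy()
            w2[:2] = rot @ w2[:2]
            assert abs(isa_objective(make_model(w2, 2), z, opts) - base) < 1e-8


class TestFitIsa:
    def test_recovers_ground_truth_subspaces(self):
        pm, true_comp = generate_isa_ground_truth_patches(20_000, 6, 3, 2, seed=5)
        t = fit_whitening(pm, 6)
        z = apply_whitening(t, pm)
        model = fit_isa(z, 3, 2, ISAOptions(seed=5))
        learned = filters_to_pixel_space(t, model.W)
        assert subspace_recovery_score(learned, true_comp, 2) > 0.95

    def test_gaussian_data_stays_at_chance(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((20_000, 8))
        model = fit_isa(z, 4, 2, FAST_OPTS)
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        score = subspace_recovery_score(model.W, q.T, 2)
        # chance for random 2-dim subspaces of an 8-dim space
        chance = np.mean([
            subspace_recovery_score(
                np.linalg.qr(rng.standard_normal((8, 8)))[0].T, q.T, 2
            )
            for _ in range(20)
        ])
        assert score < chance + 0.15

    def test_objective_trace_non_decreasing(self):
        pm, _ = generate_isa_ground_truth_patches(5_000, 5, 2, 2, seed=7)
        t = fit_whitening(pm, 4)
        model = fit_isa(apply_whitening(t, pm), 2, 2, FAST_OPTS)
        assert np.all(np.diff(model.objective_trace) >= -1e-12)

    def test_orthonormal_throughout(self):
        pm, _ = generate_isa_ground_truth_patches(5_000, 5, 2, 2, seed=8)
        t = fit_whitening(pm, 4)
        model = fit_isa(apply_whitening(t, pm), 2, 2, FAST_OPTS)
        np.testing.assert_allclose(model.W @ model.W.T, np.eye(4), atol=1e-6)

    def test_deterministic_under_seed(self):
        pm, _ = generate_isa_ground_truth_patches(3_000, 4, 2, 2, seed=9)
        t = fit_whitening(pm, 4)
        z = apply_whitening(t, pm)
        a = fit_isa(z, 2, 2, ISAOptions(seed=1, n_restarts=2, burn_in=40, max_iter=100))
        b = fit_isa(z, 2, 2, ISAOptions(seed=1, n_restarts=2, burn_in=40, max_iter=100))
        np.testing.assert_array_equal(a.W, b.W)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_isa(np.zeros((10, 4)), 3, 2, FAST_OPTS)

    def test_recovery_monotone_in_sample_size(self):
        """More patches never hurt recovery (averaged over 3 seeds)."""
        means = []
        for n in (5_000, 20_000, 50_000):
            scores = []
            for seed in (1, 2, 3):
                pm, tc = generate_isa_ground_truth_patches(n, 8, 4, 2, seed=seed)
                t = fit_whitening(pm, 8)
                m = fit_isa(apply_whitening(t, pm), 4, 2, ISAOptions(seed=seed))
                scores.append(
                    subspace_recovery_score(filters_to_pixel_space(t, m.W), tc, 2)
                )
            means.append(np.mean(scores))
        assert np.all(np.diff(means) >= -0.02)
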