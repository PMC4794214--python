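"""Disparity tuning, DDI, symmetry classification and population summaries."""

import numpy as np
import pytest

from stereoisa.cells import make_ideal_detector, make_monocular_detector
from stereoisa.gabor import ProbeParams
from stereoisa.metrics import (
    DisparityCharacterization,
    DisparityTuning,
    SineFit,
    bootstrap_histogram,
    characterize_map,
    classify_symmetry,
    compute_ddi,
    disparity_tuning,
    fit_sine,
    population_summary,
    response_phase,
)
from stereoisa.probing import ResponseMap, phase_phase_map

PROBE = ProbeParams(frequency=0.12, orientation=0.3)


def uniform_tuning(responses):
    """A bare tuning curve: one sample per disparity, no residual map spread."""
    d = len(responses)
    grid = -np.pi + 2 * np.pi * np.arange(d) / d
    return DisparityTuning(disparities=grid, responses=np.asarray(responses, float),
                           n_samples_per_bin=1, within_ss=0.0)


class TestDisparityTuning:
    def test_ideal_detector_peaks_at_zero(self):
        det = make_ideal_detector(25, 0.12, 0.3, 0.0)
        t = disparity_tuning(phase_phase_map(det, PROBE, 100))
        assert abs(t.disparities[np.argmax(t.responses)]) < 2 * np.pi / 100 + 1e-9

    def test_detector_phase_disparity_moves_peak(self):
        det = make_ideal_detector(25, 0.12, 0.3, np.pi / 2)
        t = disparity_tuning(phase_phase_map(det, PROBE, 100))
        peak = t.disparities[np.argmax(t.responses)]
        assert abs(peak - np.pi / 2) <= 2 * np.pi / 100 + 1e-9

    def test_monocular_model_flat_curve(self):
        det = make_monocular_detector(25, 0.12, 0.3)
        t = disparity_tuning(phase_phase_map(det, PROBE, 60))
        assert t.responses.std() / t.responses.mean() < 1e-6

    def test_every_cell_counted_once(self):
        rng = np.random.default_rng(0)
        n = 16
        axis = -np.pi + 2 * np.pi * np.arange(n) / n
        vals = rng.random((n, n))
        rmap = ResponseMap(values=vals, left_axis=axis, right_axis=axis,
                           stimulus_kind="grating")
        t = disparity_tuning(rmap)
        assert t.responses.sum() * n == pytest.approx(vals.sum())

    def test_non_uniform_grid_rejected(self):
        axis = np.array([-3.0, -1.0, 0.0, 2.0])
        rmap = ResponseMap(values=np.ones((4, 4)), left_axis=axis, right_axis=axis,
                           stimulus_kind="grating")
        with pytest.raises(ValueError):
            disparity_tuning(rmap)


class TestFitSine:
    def test_exact_sinusoid_recovered(self):
        d = -np.pi + 2 * np.pi * np.arange(32) / 32
        fit = fit_sine(uniform_tuning(2.0 * np.sin(d + 0.3) + 5.0))
        assert fit.amplitude == pytest.approx(2.0, abs=1e-10)
        assert fit.phase == pytest.approx(0.3, abs=1e-10)
        assert fit.offset == pytest.approx(5.0, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_curve_zero_amplitude(self):
        fit = fit_sine(uniform_tuning(np.full(16, 3.5)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_second_harmonic_orthogonal(self):
        d = -np.pi + 2 * np.pi * np.arange(64) / 64
        fit = fit_sine(uniform_tuning(np.cos(2 * d)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sine(uniform_tuning(np.ones(4)))


class TestDDI:
    def test_constant_curve_scores_zero(self):
        t = uniform_tuning(np.full(16, 2.0))
        assert compute_ddi(t, fit_sine(t)) == 0.0

    def test_noiseless_sinusoid_scores_one(self):
        d = -np.pi + 2 * np.pi * np.arange(16) / 16
        t = uniform_tuning(3.0 + np.sin(d + 0.5))
        assert compute_ddi(t, fit_sine(t)) == pytest.approx(1.0, abs=1e-9)

    def test_constructed_residual_two_thirds(self):
        """Unit-amplitude sinusoid plus a residual with RMS 0.5 gives 2/3."""
        n = 8
        d = -np.pi + 2 * np.pi * np.arange(n) / n
        clean = 2.0 + np.sin(d)  # grid contains +-pi/2, so range is exactly 2
        resid = np.cos(2 * d)  # orthogonal to the fit basis
        resid *= 0.5 * np.sqrt(n - 3) / np.linalg.norm(resid)  # RMS over N-3 dof = 0.5
        t = uniform_tuning(clean + resid)
        fit = fit_sine(t)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-12)
        assert compute_ddi(t, fit) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_noise_does_not_inflate_ddi(self):
        """Expected DDI never rises when i.i.d. noise is added to a curve."""
        d = -np.pi + 2 * np.pi * np.arange(64) / 64
        clean = 1.0 + 0.8 * np.sin(d)
        t0 = uniform_tuning(clean)
        base = compute_ddi(t0, fit_sine(t0))
        rng = np.random.default_rng(1)
        for sigma in (0.05, 0.2, 0.8):
            ddis = []
            for _ in range(20):
                t = uniform_tuning(clean + rng.normal(0, sigma, 64))
                ddis.append(compute_ddi(t, fit_sine(t)))
            assert np.mean(ddis) <= base + 1e-9

    def test_underdetermined_rejected(self):
        t = uniform_tuning(np.ones(8))
        fit = SineFit(amplitude=0, phase=0, offset=1, sse=0, n_points=3)
        with pytest.raises(ValueError):
            compute_ddi(t, fit)


class TestSymmetry:
    @pytest.mark.parametrize(
        "psi, expected",
        [(0.0, "TE"), (np.pi, "TI"), (np.pi / 2, "NEAR"), (-np.pi / 2, "FAR")],
    )
    def test_response_phase_bins(self, psi, expected):
        # build a fit whose tuning peaks at disparity psi
        fit = SineFit(amplitude=1.0, phase=np.pi / 2 - psi, offset=2.0, sse=0.0,
                      n_points=100)
        assert response_phase(fit) == pytest.approx(psi, abs=1e-12)
        assert classify_symmetry(fit, ddi=0.9) == expected

    def test_low_ddi_unclassified(self):
        fit = SineFit(amplitude=1.0, phase=0.0, offset=2.0, sse=0.0, n_points=100)
        assert classify_symmetry(fit, ddi=0.3) == "UNCLASSIFIED"

    @pytest.mark.parametrize(
        "disparity, expected",
        [(0.0, "TE"), (np.pi, "TI"), (np.pi / 2, "NEAR"), (-np.pi / 2, "FAR")],
    )
    def test_ideal_detectors_classified(self, disparity, expected):
        det = make_ideal_detector(25, 0.12, 0.3, disparity)
        char = characterize_map(phase_phase_map(det, PROBE, 100), "energy")
        assert char.ddi > 0.9
        assert char.symmetry == expected

    def test_monocular_detector_unclassified(self):
        det = make_monocular_detector(25, 0.12, 0.3)
        char = characterize_map(phase_phase_map(det, PROBE, 100), "energy")
        assert char.ddi < 0.05
        assert char.symmetry == "UNCLASSIFIED"


class TestBootstrapHistogram:
    def test_single_bin_degenerate(self):
        out = bootstrap_histogram([0.5] * 20, 50, [0.0, 1.0], seed=0)
        assert out["median"][0] == 1.0
        assert out["ci_high"][0] - out["ci_low"][0] == 0.0

    def test_deterministic_under_seed(self):
        vals = list(np.random.default_rng(3).random(40))
        a = bootstrap_histogram(vals, 100, np.linspace(0, 1, 5), seed=9)
        b = bootstrap_histogram(vals, 100, np.linspace(0, 1, 5), seed=9)
        np.testing.assert_array_equal(a["median"], b["median"])
        np.testing.assert_array_equal(a["ci_low"], b["ci_low"])

    def test_bootstrap_spread_matches_binomial(self):
        """Bootstrap proportion s.d. tracks sqrt(p(1-p)/n) at the empirical p."""
        rng = np.random.default_rng(4)
        vals = rng.random(400)
        edges = np.array([0.0, 0.5, 1.0])
        p = np.mean(vals < 0.5)
        rng2 = np.random.default_rng(5)
        props = []
        for _ in range(400):
            sample = vals[rng2.integers(0, 400, 400)]
            props.append(np.mean(sample < 0.5))
        sd = np.std(props)
        assert sd == pytest.approx(np.sqrt(p * (1 - p) / 400), rel=0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_histogram([], 10, [0, 1])


class TestPopulationSummary:
    @staticmethod
    def make_char(ddi, label):
        fit = SineFit(amplitude=1, phase=0, offset=1, sse=0, n_points=10)
        return DisparityCharacterization(model_id=0, rule="energy", ddi=ddi,
                                         sine=fit, symmetry=label,
                                         response_phase=0.0)

    def test_identical_ddis(self):
        chars = [self.make_char(0.5, "UNCLASSIFIED") for _ in range(10)]
        s = population_summary(chars)
        assert s["ddi_percentiles"]["95"] == 0.5
        assert s["ddi_max"] == 0.5

    def test_label_counting(self):
        chars = [self.make_char(0.9, lab) for lab in ("TE", "TE", "TI")]
        s = population_summary(chars, n_boot=50)
        assert s["symmetry_proportions"]["TE"]["proportion"] == pytest.approx(2 / 3)
        assert s["symmetry_proportions"]["TI"]["proportion"] == pytest.approx(1 / 3)

    def test_proportions_partition_to_one(self):
        rng = np.random.default_rng(6)
        labs = rng.choice(["TE", "TI", "NEAR", "FAR"], size=30)
        chars = [self.make_char(0.8, lab) for lab in labs]
        s = population_summary(chars, n_boot=20)
        total = sum(v["proportion"] for v in s["symmetry_proportions"].values())
        assert total == pytest.approx(1.0)
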