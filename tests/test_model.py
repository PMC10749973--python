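"""Unit and property tests for the trimodal radiodensity model."""

import math

import numpy as np
import pytest
import sympy
from scipy.integrate import quad

from thighasym.model import (
    PARAM_NAMES,
    TISSUE_WINDOWS,
    EmptyHistogramError,
    FitOptions,
    HUHistogram,
    InvalidParameterError,
    ModeParams,
    NTRAParams,
    default_init,
    evaluate_mode,
    evaluate_trimodal,
    fit_ntra,
    histogram_from_hu_values,
    mode_mass,
)
from conftest import random_truth


def quad_mass(mode: ModeParams) -> float:
    """Quadrature oracle for the mode integral, well beyond [-200, 200]."""
    val, _ = quad(
        lambda x: evaluate_mode(x, mode),
        mode.mu - 60 * mode.sigma, mode.mu + 60 * mode.sigma, limit=800,
    )
    return val


class TestEvaluateMode:
    def test_peak_value_unskewed(self):
        m = ModeParams(N=5.0, mu=-30.0, sigma=4.0, alpha=0.0)
        assert evaluate_mode(-30.0, m) == pytest.approx(5.0 / (4.0 * math.sqrt(2 * math.pi)))

    def test_zero_amplitude_is_zero_everywhere(self):
        m = ModeParams(N=0.0, mu=20.0, sigma=3.0, alpha=1.0)
        assert np.all(evaluate_mode(np.linspace(-200, 200, 50), m) == 0.0)

    def test_against_arbitrary_precision_oracle(self):
        # independent evaluation with sympy's arbitrary-precision erfc/exp
        m = ModeParams(N=1.0, mu=0.0, sigma=1.0, alpha=2.0)
        x = 1.0
        expected = sympy.N(
            1 / sympy.sqrt(2 * sympy.pi) * sympy.exp(-sympy.Rational(1, 2))
            * sympy.erfc(2 / sympy.sqrt(2)),
            30,
        )
        assert evaluate_mode(x, m) == pytest.approx(float(expected), rel=1e-12)

    def test_nonnegative_and_continuous(self, rng):
        m = ModeParams(N=3.0, mu=50.0, sigma=7.0, alpha=-2.5)
        x = np.linspace(-200, 200, 4001)
        y = evaluate_mode(x, m)
        assert np.all(y >= 0)
        assert np.max(np.abs(np.diff(y))) < 0.05 * np.max(y)  # no jumps

    def test_invalid_sigma_raises(self):
        with pytest.raises(InvalidParameterError):
            evaluate_mode(0.0, ModeParams(N=1.0, mu=0.0, sigma=0.0, alpha=0.0))
        with pytest.raises(InvalidParameterError):
            evaluate_mode(0.0, ModeParams(N=1.0, mu=0.0, sigma=-2.0, alpha=0.0))

    def test_alpha_zero_reduces_to_gaussian(self):
        m = ModeParams(N=2.5, mu=15.0, sigma=6.0, alpha=0.0)
        x = np.linspace(-40, 70, 301)
        gauss = 2.5 / (6.0 * math.sqrt(2 * math.pi)) * np.exp(-((x - 15.0) ** 2) / (2 * 36.0))
        np.testing.assert_allclose(evaluate_mode(x, m), gauss, atol=1e-12)


class TestTrimodal:
    def test_additivity(self, truth_params):
        x = np.arange(-200, 201, dtype=float)
        total = evaluate_trimodal(x, truth_params)
        parts = sum(
            evaluate_mode(x, truth_params.mode(t)) for t in ("fat", "connective", "muscle")
        )
        np.testing.assert_allclose(total, parts, rtol=1e-14)

    def test_all_zero_amplitudes(self):
        p = NTRAParams(
            fat=ModeParams(0, -60, 20, 0.5),
            connective=ModeParams(0, 10, 10, 0),
            muscle=ModeParams(0, 60, 12, 2),
        )
        assert np.all(evaluate_trimodal(np.arange(-200, 201), p) == 0)

    def test_quadrature_equals_sum_of_amplitudes(self, rng):
        for _ in range(5):
            p = random_truth(rng)
            total = sum(quad_mass(p.mode(t)) for t in ("fat", "connective", "muscle"))
            expected = p.fat.N + p.connective.N + p.muscle.N
            assert total == pytest.approx(expected, rel=1e-6)

    def test_canonical_vector_roundtrip(self, truth_params):
        v = truth_params.to_vector()
        assert v.shape == (11,)
        assert NTRAParams.from_vector(v).to_vector() == pytest.approx(v)

    def test_connective_skew_forbidden(self):
        with pytest.raises(InvalidParameterError):
            NTRAParams(
                fat=ModeParams(1, -60, 20, 0),
                connective=ModeParams(1, 10, 10, 0.5),
                muscle=ModeParams(1, 60, 12, 0),
            )

    def test_windows_partition_hu_axis(self):
        w = TISSUE_WINDOWS
        assert (w["fat"].lo, w["fat"].hi) == (-200, -10)
        assert (w["connective"].lo, w["connective"].hi) == (-9, 40)
        assert (w["muscle"].lo, w["muscle"].hi) == (41, 200)
        covered = sorted(
            hu for t in w.values() for hu in range(t.lo, t.hi + 1)
        )
        assert covered == list(range(-200, 201))


class TestModeMass:
    @pytest.mark.parametrize("N,alpha", [(7.0, 3.0), (7.0, -4.5), (3.0, 0.0), (0.0, 1.0)])
    def test_analytic_mass_equals_amplitude(self, N, alpha):
        m = ModeParams(N=N, mu=-50.0, sigma=12.0, alpha=alpha)
        assert mode_mass(m) == N
        if N > 0:
            assert quad_mass(m) == pytest.approx(N, rel=1e-8)


class TestHistogramFromValues:
    def test_values_near_zero_land_in_bin_zero(self):
        h = histogram_from_hu_values([0.2, -0.3, 0.4])
        assert h.counts[200] == 3  # bin centre 0
        assert h.total_mass == 3
        assert h.n_discarded == 0

    def test_all_out_of_range_raises(self):
        with pytest.raises(EmptyHistogramError):
            histogram_from_hu_values([-300.0, 250.0])

    def test_partial_discard_counted(self):
        h = histogram_from_hu_values([-300.0, 0.0, 250.0, 10.2])
        assert h.n_discarded == 2
        assert h.total_mass == 2

    def test_bin_edges_half_open(self):
        # bin k covers [k-0.5, k+0.5)
        h = histogram_from_hu_values([9.5, 10.49, 10.5])
        assert h.counts[200 + 10] == 2
        assert h.counts[200 + 11] == 1

    def test_sampled_counts_match_density(self, rng, truth_params):
        # sampling check: counts of model draws track the expected curve
        from thighasym.synthetic import sample_histogram

        h = sample_histogram(truth_params, rng)
        x = np.arange(-200, 201, dtype=float)
        expected = evaluate_trimodal(x, truth_params)
        resid = np.abs(h.counts - expected)
        assert np.all(resid <= 6.0 * np.sqrt(expected + 1.0))


class TestFitNtra:
    def test_noiseless_self_consistency(self, truth_params, exact_histogram):
        fr = fit_ntra(exact_histogram)
        assert fr.converged
        rel = np.abs(fr.params.to_vector() - truth_params.to_vector()) / np.abs(
            truth_params.to_vector()
        )
        assert np.max(rel) < 1e-3
        assert fr.residual_sse < 1e-10 * exact_histogram.total_mass ** 2

    def test_amplitude_linearity(self, truth_params, exact_histogram):
        doubled = HUHistogram(counts=2.0 * exact_histogram.counts)
        fr = fit_ntra(doubled)
        v, t = fr.params.to_vector(), truth_params.to_vector()
        for tissue, sl in (("fat", slice(0, 4)), ("conn", slice(4, 7)), ("mus", slice(7, 11))):
            assert v[sl][0] == pytest.approx(2.0 * t[sl][0], rel=1e-3)   # N doubles
            np.testing.assert_allclose(v[sl][1:], t[sl][1:], rtol=1e-3, atol=1e-3)

    def test_single_bin_histogram_is_degenerate(self):
        counts = np.zeros(401)
        counts[200] = 1000.0
        fr = fit_ntra(HUHistogram(counts=counts))
        assert not fr.converged

    def test_empty_histogram_raises(self):
        with pytest.raises(EmptyHistogramError):
            fit_ntra(HUHistogram(counts=np.zeros(401)))

    def test_nonfinite_counts_rejected(self):
        counts = np.ones(401)
        counts[0] = np.nan
        with pytest.raises(ValueError):
            HUHistogram(counts=counts)

    def test_objective_never_worse_than_init(self, exact_histogram, truth_params):
        # start from a deliberately poor but valid initialisation
        bad = NTRAParams(
            fat=ModeParams(1.0, -150.0, 60.0, 0.0),
            connective=ModeParams(1.0, 35.0, 30.0, 0.0),
            muscle=ModeParams(1.0, 180.0, 60.0, 0.0),
        )
        x = exact_histogram.bin_centers
        sse0 = float(np.sum((exact_histogram.counts - evaluate_trimodal(x, bad)) ** 2))
        fr = fit_ntra(exact_histogram, init=bad)
        assert fr.residual_sse <= sse0

    def test_residual_sse_recomputable(self, exact_histogram, rng):
        noisy = HUHistogram(counts=rng.poisson(exact_histogram.counts).astype(float))
        fr = fit_ntra(noisy)
        x = noisy.bin_centers
        sse = float(np.sum((noisy.counts - evaluate_trimodal(x, fr.params)) ** 2))
        assert fr.residual_sse == pytest.approx(sse, rel=1e-9)

    def test_density_objective_same_shape_rescaled_amplitude(self, exact_histogram, truth_params):
        fr = fit_ntra(exact_histogram, options=FitOptions(objective="density"))
        v, t = fr.params.to_vector(), truth_params.to_vector()
        np.testing.assert_allclose(v, t, rtol=5e-3, atol=5e-3)

    def test_empty_tissue_window_allows_zero_amplitude(self, rng):
        # a leg with essentially no fat signal still fits
        p = NTRAParams(
            fat=ModeParams(0.0, -60.0, 20.0, 0.0),
            connective=ModeParams(2e4, 12.0, 10.0, 0.0),
            muscle=ModeParams(5e4, 58.0, 12.0, 2.0),
        )
        x = np.arange(-200, 201, dtype=float)
        h = HUHistogram(counts=evaluate_trimodal(x, p))
        fr = fit_ntra(h)
        assert fr.params.fat.N < 1e-3 * h.total_mass
        assert fr.params.muscle.N == pytest.approx(5e4, rel=1e-3)

    def test_reflection_equivariance_symmetric_fixture(self):
        # purpose-built fixture: unskewed modes placed symmetrically about 0,
        # so reflecting the histogram swaps the fat and muscle roles
        p = NTRAParams(
            fat=ModeParams(3e4, -70.0, 14.0, 0.0),
            connective=ModeParams(2e4, 4.0, 8.0, 0.0),
            muscle=ModeParams(4e4, 70.0, 11.0, 0.0),
        )
        x = np.arange(-200, 201, dtype=float)
        h = HUHistogram(counts=evaluate_trimodal(x, p))
        reflected = HUHistogram(counts=h.counts[::-1].copy())
        fr = fit_ntra(reflected)
        assert fr.params.fat.mu == pytest.approx(-70.0, abs=1e-2)
        assert fr.params.fat.N == pytest.approx(4e4, rel=1e-3)
        assert fr.params.connective.mu == pytest.approx(-4.0, abs=1e-2)
        assert fr.params.muscle.mu == pytest.approx(70.0, abs=1e-2)
        assert fr.params.muscle.N == pytest.approx(3e4, rel=1e-3)

    def test_default_init_uses_window_moments(self, exact_histogram, truth_params):
        init = default_init(exact_histogram)
        # centroid-based locations should land near the true peaks
        assert abs(init.fat.mu - truth_params.fat.mu) < 15
        assert abs(init.muscle.mu - truth_params.muscle.mu) < 15
        assert init.fat.alpha == 0.0 and init.muscle.alpha == 0.0
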