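"""Perception kernel and Bayesian posterior on the quality grid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repskew import (
    Grids,
    InformationLevel,
    as_information,
    bayes_invert,
    perception_density,
    perception_kernel,
    posterior,
    quad_weights,
)
from repskew.belief import InvalidInformationError, log_unnormalized_density


class TestInformationLevel:
    def test_symbolic_infinity(self):
        info = InformationLevel.perfect()
        assert info.is_perfect and math.isinf(info.omega)
        assert not InformationLevel(1024.0).is_perfect

    def test_negative_or_nan_rejected(self):
        with pytest.raises(InvalidInformationError):
            InformationLevel(-1.0)
        with pytest.raises(InvalidInformationError):
            InformationLevel(float("nan"))

    def test_coercion_from_float_and_string(self):
        assert as_information(16).omega == 16.0
        assert as_information("inf").is_perfect
        assert as_information(InformationLevel(2.0)).omega == 2.0


class TestPerceptionDensity:
    def test_no_information_is_uniform(self):
        z = np.linspace(0, 1, 11)
        assert np.all(perception_density(z, 0.3, 0.0) == 1.0)

    def test_perfect_information_is_point_mass(self):
        assert perception_density(0.3, 0.3, math.inf) == math.inf
        assert perception_density(0.31, 0.3, math.inf) == 0.0

    @pytest.mark.parametrize("omega", [1.0, 16.0, 512.0])
    @pytest.mark.parametrize("x", [0.2, 0.5, 0.8])
    def test_mode_at_true_value_and_beta_mean(self, omega, x):
        z = np.linspace(0, 1, 2001)
        dens = perception_density(z, x, omega)
        assert z[int(np.argmax(dens))] == pytest.approx(x, abs=1e-3)
        mean = np.trapezoid(dens * z, z)
        assert mean == pytest.approx((1 + x * omega) / (2 + omega), abs=1e-3)

    def test_density_at_half_is_symmetric(self):
        z = np.linspace(0, 1, 101)
        dens = perception_density(z, 0.5, 16.0)
        assert np.allclose(dens, dens[::-1], atol=1e-12)

    def test_negative_information_rejected(self):
        with pytest.raises(InvalidInformationError):
            perception_density(0.5, 0.5, -2.0)

    def test_out_of_range_arguments_rejected(self):
        with pytest.raises(ValueError):
            perception_density(1.5, 0.5, 1.0)


class TestPerceptionKernel:
    @pytest.mark.parametrize("omega", [0.0, 1.0, 16.0, 512.0, math.inf])
    def test_rows_are_probability_masses(self, omega, grids):
        k = perception_kernel(grids.x, grids.z, omega)
        sums = k.matrix.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9
        assert np.all(k.matrix >= 0.0)

    def test_no_information_density_uniform(self, grids):
        k = perception_kernel(grids.x, grids.z, 0.0)
        assert np.all(k.density == 1.0)

    def test_perfect_information_rows_one_hot_at_truth(self, grids):
        k = perception_kernel(grids.x, grids.z, math.inf)
        assert np.array_equal(k.matrix, np.eye(grids.nx))

    def test_row_at_half_symmetric_for_any_omega(self, grids):
        k = perception_kernel(grids.x, grids.z, 16.0)
        mid = np.flatnonzero(grids.x == 0.5)[0]
        row = k.matrix[mid]
        assert np.allclose(row, row[::-1], atol=1e-12)

    def test_row_variance_strictly_decreasing_in_information(self, grids):
        for x in (0.3, 0.5, 0.7):
            i = int(np.argmin(np.abs(grids.x - x)))
            variances = []
            for omega in (1.0, 4.0, 16.0, 64.0, 256.0):
                row = perception_kernel(grids.x, grids.z, omega).matrix[i]
                mean = row @ grids.z
                variances.append(row @ (grids.z - mean) ** 2)
            assert np.all(np.diff(variances) < 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            perception_kernel(np.array([]), np.linspace(0, 1, 5), 1.0)


class TestPosterior:
    def test_no_information_returns_prior(self, grids):
        prior = np.linspace(1, 2, grids.nx)
        prior /= prior.sum()
        belief = posterior(0.7, 0.0, grids.x, prior)
        assert np.allclose(belief.weights, prior)

    def test_observation_at_half_carries_no_directional_information(self, grids):
        """At z = 0.5 the x-dependent exponential part of the likelihood,
        z**(x*omega) * (1-z)**((1-x)*omega), reduces to 0.5**omega for
        every x — exactly — so the posterior cannot lean toward low or
        high quality: it stays symmetric about 0.5 with mean 0.5. (The
        beta normalizer still concentrates it around 0.5, as perceiving
        an intermediate value through a narrow kernel should.)"""
        for omega in (1.0, 16.0, 1024.0):
            ll = log_unnormalized_density(0.5, grids.x, omega)
            assert np.allclose(ll, ll[0], atol=1e-12)  # exact cancellation
            w = posterior(0.5, omega, grids.x).weights
            assert np.allclose(w, w[::-1], atol=1e-12)
            assert w @ grids.x == pytest.approx(0.5, abs=1e-12)

    def test_perfect_information_concentrates_on_nearest_grid_point(self, grids):
        belief = posterior(0.503, math.inf, grids.x)
        assert belief.weights.max() == 1.0
        assert grids.x[int(np.argmax(belief.weights))] == pytest.approx(0.505)

    def test_log_likelihood_linear_in_quality(self, grids):
        """The perception likelihood is log-linear in x with slope
        omega * ln(z / (1 - z)): increasing for z > 0.5, decreasing below."""
        for z, omega in ((0.7, 16.0), (0.2, 4.0), (0.9, 512.0)):
            ll = log_unnormalized_density(z, grids.x, omega)
            slopes = np.diff(ll) / np.diff(grids.x)
            expected = omega * math.log(z / (1 - z))
            assert np.allclose(slopes, expected, rtol=1e-9)

    def test_likelihood_ratio_monotone_in_quality(self, grids):
        """Monotone likelihood ratio: the log-ratio of the likelihoods of
        two perceptions is exactly linear in x (the beta normalizer
        cancels between them), so higher perceptions shift belief toward
        higher quality."""
        lo = log_unnormalized_density(0.2, grids.x, 16.0)
        hi = log_unnormalized_density(0.8, grids.x, 16.0)
        ratio = hi - lo
        slopes = np.diff(ratio) / np.diff(grids.x)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)
        assert slopes[0] > 0

    def test_posterior_concentrates_near_observation(self, grids):
        for z in (0.3, 0.6, 0.8):
            w = posterior(z, 64.0, grids.x).weights
            assert abs(grids.x[int(np.argmax(w))] - z) < 0.05

    @given(z=st.floats(0.05, 0.95), omega=st.sampled_from([1.0, 8.0, 64.0]))
    def test_posterior_weights_normalized(self, z, omega):
        grid = np.linspace(0, 1, 101)
        belief = posterior(z, omega, grid)
        assert abs(belief.weights.sum() - 1.0) < 1e-9
        assert np.all(belief.weights >= 0)

    def test_posterior_mean_between_prior_mean_and_observation(self, grids):
        for z in (0.1, 0.3, 0.8):
            means = []
            for omega in (0.0, 2.0, 16.0, 256.0, math.inf):
                means.append(posterior(z, omega, grids.x).mean())
            lo, hi = min(0.5, z), max(0.5, z)
            assert all(lo - 1e-9 <= m <= hi + 1e-9 for m in means)
            # approaches the observation as information grows
            assert abs(means[-1] - z) <= abs(means[1] - z) + 1e-9

    def test_matches_bayes_inversion_column(self, grids):
        k = perception_kernel(grids.x, grids.z, 16.0)
        post, _ = bayes_invert(k)
        j = 137
        belief = posterior(float(grids.z[j]), 16.0, grids.x, z_grid=grids.z)
        assert np.abs(belief.weights - post[:, j]).max() < 1e-12


class TestJointConsistency:
    @pytest.mark.parametrize("omega", [0.0, 1.0, 16.0, 512.0, math.inf])
    def test_law_of_total_probability_recovers_prior(self, omega, grids):
        k = perception_kernel(grids.x, grids.z, omega)
        post, evidence = bayes_invert(k)
        recovered = post @ evidence
        assert np.abs(recovered - 1.0 / grids.nx).max() < 1e-6

    def test_recovery_with_nonuniform_prior(self, grids):
        prior = np.exp(-((grids.x - 0.3) ** 2) / 0.1)
        prior /= prior.sum()
        k = perception_kernel(grids.x, grids.z, 16.0)
        post, evidence = bayes_invert(k, prior)
        assert np.abs(post @ evidence - prior).max() < 1e-6

    def test_quadrature_weights_sum_to_span(self):
        grid = np.linspace(0, 1, 201)
        assert quad_weights(grid).sum() == pytest.approx(1.0)
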