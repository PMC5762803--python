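"""Unit and property tests for the forward model and closed-form inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from abiret.model import (
    ParametricResult,
    PixelTriple,
    RockingCurve,
    WorkingPoints,
    forward_intensity,
    rc_transmission,
    retrieve_apparent_absorption,
    retrieve_parametric_images,
    retrieve_pixel,
    retrieve_refraction,
    retrieve_scatter_variance,
    retrieve_two_image_absorption_norefraction,
    retrieve_two_image_absorption_noscatter,
    retrieve_two_image_refraction,
    retrieve_two_image_scatter_norefraction,
)

from conftest import HALF_SLOPE


def make_triple(i_r, dtheta_r, sigma_s, thetas, rc):
    """Noiseless intensities from the closed-form forward model."""
    wp = WorkingPoints(tuple(thetas))
    vals = tuple(forward_intensity(i_r, dtheta_r, sigma_s, t, rc) for t in wp.thetas)
    return PixelTriple(vals, wp)


def convolution_intensity(i_r, dtheta_r, sigma_s, theta, sigma):
    """Independent oracle: numerical quadrature of the Gaussian convolution."""
    if sigma_s == 0:
        return i_r * math.exp(-((theta + dtheta_r) ** 2) / (2 * sigma**2))

    # substitute ds = sigma_s * u so the unit-variance density is explicit
    # and the quadrature stays stable for arbitrarily small sigma_s
    def integrand(u):
        return (
            math.exp(-((theta + dtheta_r + sigma_s * u) ** 2) / (2 * sigma**2))
            * math.exp(-(u**2) / 2)
            / math.sqrt(2 * math.pi)
        )

    val, err = quad(integrand, -np.inf, np.inf, epsabs=1e-14, epsrel=1e-12)
    return i_r * val


class TestRockingCurve:
    def test_peak_is_unity(self, rc):
        assert rc_transmission(0.0, rc) == 1.0

    def test_one_sigma_point(self, rc):
        assert rc_transmission(8.6, rc) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_half_maximum_offset(self, rc):
        # theta = sigma * sqrt(2 ln 2)
        assert rc_transmission(HALF_SLOPE, rc) == pytest.approx(0.5, rel=1e-12)

    @given(theta=st.floats(-50, 50))
    def test_even_and_bounded(self, theta):
        rc = RockingCurve(sigma=8.6)
        t = rc_transmission(theta, rc)
        assert rc_transmission(-theta, rc) == t
        assert 0.0 < t <= 1.0

    def test_nonfinite_theta_rejected(self, rc):
        with pytest.raises(ValueError):
            rc_transmission(float("nan"), rc)
        with pytest.raises(ValueError):
            rc_transmission(float("inf"), rc)

    @pytest.mark.parametrize("sigma", [0.0, -1.0, float("nan")])
    def test_invalid_sigma_rejected(self, sigma):
        with pytest.raises(ValueError):
            RockingCurve(sigma=sigma)

    def test_array_input(self, rc):
        thetas = np.array([0.0, 8.6, -8.6])
        out = rc_transmission(thetas, rc)
        assert out.shape == (3,)
        assert out[1] == out[2]


class TestForwardIntensity:
    def test_no_object(self, rc):
        assert forward_intensity(1.0, 0.0, 0.0, 0.0, rc) == 1.0

    def test_equal_width_convolution_at_peak(self, rc):
        assert forward_intensity(1.0, 0.0, 8.6, 0.0, rc) == pytest.approx(
            1 / math.sqrt(2), rel=1e-12
        )

    def test_reduces_to_shifted_curve_without_scatter(self, rc):
        for theta in (-5.0, 0.0, 7.3):
            assert forward_intensity(0.8, 3.0, 0.0, theta, rc) == pytest.approx(
                0.8 * rc_transmission(theta + 3.0, rc), rel=1e-12
            )

    def test_negative_sigma_s_rejected(self, rc):
        with pytest.raises(ValueError):
            forward_intensity(1.0, 0.0, -1.0, 0.0, rc)

    def test_decreasing_in_sigma_s_at_shifted_peak(self, rc):
        vals = [forward_intensity(1.0, -4.0, s, 4.0, rc) for s in (0.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_quadrature_oracle(self, rc):
        val = forward_intensity(0.79, 5.0, 6.42, HALF_SLOPE, rc)
        oracle = convolution_intensity(0.79, 5.0, 6.42, HALF_SLOPE, 8.6)
        assert val == pytest.approx(oracle, rel=1e-8)

    @given(
        i_r=st.floats(0.05, 1.0),
        dtheta=st.floats(-20, 20),
        sigma_s=st.floats(0.0, 25.0),
        theta=st.floats(-25, 25),
    )
    @settings(max_examples=50, deadline=None)
    def test_quadrature_agreement_property(self, i_r, dtheta, sigma_s, theta):
        rc = RockingCurve(sigma=8.6)
        val = forward_intensity(i_r, dtheta, sigma_s, theta, rc)
        oracle = convolution_intensity(i_r, dtheta, sigma_s, theta, 8.6)
        assert val == pytest.approx(oracle, rel=1e-8, abs=1e-300)


class TestThreeImageRetrieval:
    def test_symmetric_pixel_has_zero_refraction(self, rc, cardinal_points):
        triple = make_triple(1.0, 0.0, 6.42, cardinal_points.thetas, rc)
        assert retrieve_refraction(triple) == pytest.approx(0.0, abs=1e-12)

    def test_refraction_round_trip(self, rc, cardinal_points):
        triple = make_triple(1.0, 5.0, 6.42, cardinal_points.thetas, rc)
        assert retrieve_refraction(triple) == pytest.approx(5.0, abs=1e-9)

    def test_refraction_asymmetric_triad(self, rc):
        triple = make_triple(1.0, -3.0, 6.42, (-HALF_SLOPE, 0.0, 4.3), rc)
        assert retrieve_refraction(triple) == pytest.approx(-3.0, abs=1e-9)

    @pytest.mark.parametrize(
        "sigma_s,expected",
        [(6.42, 41.2164), (0.0, 0.0), (21.41, 458.3881)],
    )
    def test_scatter_variance_round_trip(self, rc, cardinal_points, sigma_s, expected):
        triple = make_triple(0.9, 2.0, sigma_s, cardinal_points.thetas, rc)
        assert retrieve_scatter_variance(triple, rc) == pytest.approx(
            expected, abs=1e-9 if expected == 0 else None, rel=1e-9
        )

    def test_absorption_object_free_pixel(self, rc, cardinal_points):
        vals = tuple(rc_transmission(t, rc) for t in cardinal_points.thetas)
        triple = PixelTriple(vals, cardinal_points)
        for which in (1, 2, 3):
            assert retrieve_apparent_absorption(
                triple, 0.0, 0.0, rc, which
            ) == pytest.approx(1.0, rel=1e-12)

    def test_absorption_round_trip_index_invariant(self, rc, cardinal_points):
        triple = make_triple(0.79, 5.0, 6.42, cardinal_points.thetas, rc)
        dtheta = retrieve_refraction(triple)
        svar = retrieve_scatter_variance(triple, rc)
        results = [
            retrieve_apparent_absorption(triple, dtheta, svar, rc, which)
            for which in (1, 2, 3)
        ]
        for r in results:
            assert r == pytest.approx(0.79, rel=1e-9)
        assert max(results) - min(results) < 1e-9 * 0.79

    def test_forward_consistency_invariant(self, rc, cardinal_points):
        # plugging the retrieved parameters back into the forward model
        # reproduces the inputs
        triple = make_triple(0.66, -7.5, 12.85, cardinal_points.thetas, rc)
        res = retrieve_pixel(triple, rc)
        assert res.valid
        for intensity, theta in zip(triple.intensities, cardinal_points.thetas):
            again = forward_intensity(
                res.apparent_absorption,
                res.refraction,
                math.sqrt(res.scatter_variance),
                theta,
                rc,
            )
            assert again == pytest.approx(intensity, rel=1e-9)

    def test_nonpositive_intensity_invalid(self, rc, cardinal_points):
        triple = PixelTriple((0.5, 0.0, 0.5), cardinal_points)
        assert math.isnan(retrieve_refraction(triple))
        assert not retrieve_pixel(triple, rc).valid

    def test_degenerate_denominator_invalid(self, rc, cardinal_points):
        # identical intensities at a symmetric triad: both log-ratios vanish
        triple = PixelTriple((0.7, 0.7, 0.7), cardinal_points)
        res = retrieve_pixel(triple, rc)
        assert isinstance(res, ParametricResult)
        assert not res.valid
        assert math.isnan(res.refraction)

    @given(
        i_r=st.floats(0.01, 1.0),
        dtheta=st.floats(-30, 30),
        svar=st.floats(0.0, 900.0),
        t1=st.floats(-25.8, -1.0),
        t3=st.floats(1.0, 25.8),
        t2=st.floats(-0.4, 0.4),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_inversion_property(self, i_r, dtheta, svar, t1, t2, t3):
        rc = RockingCurve(sigma=8.6)
        sigma_s = math.sqrt(svar)
        triple = make_triple(i_r, dtheta, sigma_s, (t1, t2, t3), rc)
        if min(triple.intensities) < 1e-290:
            return  # intensity underflow: physically no photons
        res = retrieve_pixel(triple, rc)
        assert res.valid
        assert res.refraction == pytest.approx(dtheta, rel=1e-8, abs=1e-6)
        assert res.scatter_variance == pytest.approx(svar, rel=1e-8, abs=1e-5)
        assert res.apparent_absorption == pytest.approx(i_r, rel=1e-8)


class TestTwoImageFormulas:
    def test_refraction_round_trip(self, rc):
        thetas = (-HALF_SLOPE, HALF_SLOPE)
        vals = [forward_intensity(1.0, 2.5, 0.0, t, rc) for t in thetas]
        assert retrieve_two_image_refraction(vals, thetas, rc) == pytest.approx(
            2.5, abs=1e-10
        )

    def test_equal_intensities_symmetric_angles(self, rc):
        assert retrieve_two_image_refraction(
            (0.5, 0.5), (-HALF_SLOPE, HALF_SLOPE), rc
        ) == pytest.approx(0.0, abs=1e-12)

    def test_equal_angles_rejected(self, rc):
        with pytest.raises(ValueError):
            retrieve_two_image_refraction((0.5, 0.6), (1.0, 1.0), rc)

    def test_biased_when_scatter_present(self, rc, cardinal_points):
        # formula assumes no scattering; on a scattering pixel it deviates
        # from the three-image truth
        triple = make_triple(1.0, 4.0, 6.42, cardinal_points.thetas, rc)
        two = retrieve_two_image_refraction(
            (triple.intensities[0], triple.intensities[2]),
            (cardinal_points.thetas[0], cardinal_points.thetas[2]),
            rc,
        )
        assert abs(two - 4.0) > 0.1

    def test_matches_three_image_without_scatter(self, rc, cardinal_points):
        triple = make_triple(0.9, 3.0, 0.0, cardinal_points.thetas, rc)
        three = retrieve_refraction(triple)
        two = retrieve_two_image_refraction(
            (triple.intensities[0], triple.intensities[1]),
            (cardinal_points.thetas[0], cardinal_points.thetas[1]),
            rc,
        )
        assert two == pytest.approx(three, abs=1e-9)

    def test_absorption_noscatter_object_free(self, rc):
        intensity = rc_transmission(HALF_SLOPE, rc)
        assert retrieve_two_image_absorption_noscatter(
            intensity, HALF_SLOPE, 0.0, rc
        ) == pytest.approx(1.0, rel=1e-12)

    def test_absorption_noscatter_round_trip(self, rc):
        intensity = forward_intensity(0.66, 3.0, 0.0, 5.0, rc)
        assert retrieve_two_image_absorption_noscatter(
            intensity, 5.0, 3.0, rc
        ) == pytest.approx(0.66, rel=1e-12)

    def test_absorption_noscatter_degenerates_from_full_formula(self, rc, cardinal_points):
        triple = make_triple(0.7, 2.0, 0.0, cardinal_points.thetas, rc)
        full = retrieve_apparent_absorption(triple, 2.0, 0.0, rc, which=1)
        reduced = retrieve_two_image_absorption_noscatter(
            triple.intensities[0], cardinal_points.thetas[0], 2.0, rc
        )
        assert reduced == pytest.approx(full, rel=1e-12)

    def test_scatter_norefraction_round_trip(self, rc):
        thetas = (0.0, HALF_SLOPE)
        vals = [forward_intensity(1.0, 0.0, 8.57, t, rc) for t in thetas]
        assert retrieve_two_image_scatter_norefraction(vals, thetas, rc) == pytest.approx(
            73.4449, rel=1e-9
        )

    def test_scatter_norefraction_zero(self, rc):
        thetas = (0.0, HALF_SLOPE)
        vals = [forward_intensity(1.0, 0.0, 0.0, t, rc) for t in thetas]
        assert retrieve_two_image_scatter_norefraction(vals, thetas, rc) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_scatter_norefraction_symmetric_degenerate(self, rc):
        assert math.isnan(
            retrieve_two_image_scatter_norefraction(
                (0.5, 0.5), (-HALF_SLOPE, HALF_SLOPE), rc
            )
        )

    def test_absorption_norefraction_object_free(self, rc):
        assert retrieve_two_image_absorption_norefraction(
            rc_transmission(5.0, rc), 5.0, 0.0, rc
        ) == pytest.approx(1.0, rel=1e-12)

    def test_absorption_norefraction_round_trip(self, rc):
        intensity = forward_intensity(0.9, 0.0, 4.28, 5.0, rc)
        assert retrieve_two_image_absorption_norefraction(
            intensity, 5.0, 4.28**2, rc
        ) == pytest.approx(0.9, rel=1e-12)

    def test_absorption_norefraction_equals_full_at_zero_refraction(
        self, rc, cardinal_points
    ):
        triple = make_triple(0.8, 0.0, 4.28, cardinal_points.thetas, rc)
        full = retrieve_apparent_absorption(triple, 0.0, 4.28**2, rc, which=2)
        reduced = retrieve_two_image_absorption_norefraction(
            triple.intensities[1], cardinal_points.thetas[1], 4.28**2, rc
        )
        assert reduced == pytest.approx(full, rel=1e-12)


class TestParametricImages:
    def test_object_free_images(self, rc, cardinal_points):
        shape = (8, 9)
        images = [
            np.full(shape, rc_transmission(t, rc)) for t in cardinal_points.thetas
        ]
        result = retrieve_parametric_images(images, cardinal_points, rc)
        assert result.mask.all()
        np.testing.assert_allclose(result.apparent_absorption, 1.0, rtol=1e-10)
        np.testing.assert_allclose(result.refraction, 0.0, atol=1e-9)
        np.testing.assert_allclose(result.scatter_variance, 0.0, atol=1e-7)

    def test_zero_intensity_pixel_masked_not_propagating(self, rc, cardinal_points):
        images = [
            np.full((4, 4), rc_transmission(t, rc)) for t in cardinal_points.thetas
        ]
        images[1][2, 2] = 0.0
        result = retrieve_parametric_images(images, cardinal_points, rc)
        assert not result.mask[2, 2]
        assert np.isnan(result.refraction[2, 2])
        good = np.ones((4, 4), dtype=bool)
        good[2, 2] = False
        assert np.isfinite(result.refraction[good]).all()

    def test_shape_mismatch_rejected(self, rc, cardinal_points):
        images = [np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 5))]
        with pytest.raises(ValueError):
            retrieve_parametric_images(images, cardinal_points, rc)

    def test_pixelwise_matches_scalar_retrieval(self, rc, cardinal_points, rng):
        shape = (5, 6)
        i_r = rng.uniform(0.3, 1.0, shape)
        dtheta = rng.uniform(-10, 10, shape)
        sigma_s = rng.uniform(0, 15, shape)
        images = [
            forward_intensity(i_r, dtheta, sigma_s, t, rc)
            for t in cardinal_points.thetas
        ]
        result = retrieve_parametric_images(images, cardinal_points, rc)
        assert result.mask.all()
        np.testing.assert_allclose(result.refraction, dtheta, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(
            result.scatter_variance, sigma_s**2, rtol=1e-8, atol=1e-6
        )
        np.testing.assert_allclose(result.apparent_absorption, i_r, rtol=1e-8)

    def test_sigma_s_map_clamps_negative_variance(self, rc, cardinal_points):
        images = [
            np.full((2, 2), rc_transmission(t, rc)) for t in cardinal_points.thetas
        ]
        # slope images slightly low: the local curve looks narrower than
        # the analyzer curve, so the computed variance goes negative
        images[0][0, 0] *= 0.999
        images[2][0, 0] *= 0.999
        result = retrieve_parametric_images(images, cardinal_points, rc)
        assert result.scatter_variance[0, 0] < 0
        assert result.sigma_s[0, 0] == 0.0
        assert result.negative_variance_fraction > 0

    def test_triad_invariance(self, rc):
        # same pixel retrieved from different triads gives the same parameters
        triads = [
            (-HALF_SLOPE, 0.0, HALF_SLOPE),
            (-12.988, 0.0, 8.6),  # low 22%, peak, one-sigma high
            (-2.755, 0.0, 12.988),  # low 95%, peak, high 22%
            (-10.1257, -2.755, 8.52),
        ]
        for thetas in triads:
            triple = make_triple(0.85, 4.0, 6.42, thetas, rc)
            res = retrieve_pixel(triple, rc)
            assert res.valid
            assert res.refraction == pytest.approx(4.0, abs=1e-8)
            assert res.scatter_variance == pytest.approx(6.42**2, rel=1e-8)
            assert res.apparent_absorption == pytest.approx(0.85, rel=1e-8)
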