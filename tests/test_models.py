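"""Unit and property tests for the response-probability models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import choicebias as cb
from choicebias.models import InvalidParameterError


class TestSymmetric:
    def test_neutral_point_is_half(self):
        """At theta = delta_d - delta_s the lapse-free curve crosses 0.5."""
        p = cb.SymmetricParams(delta_s=0.7, delta_d=0.2, sigma_primary=0.4)
        assert cb.p_choice_symmetric(0.2 - 0.7, p, "primary") == pytest.approx(0.5)

    def test_no_decisional_bias_collapses_sides(self):
        """delta_d = 0 makes the two reference mappings identical curves."""
        p = cb.SymmetricParams(delta_s=0.6, delta_d=0.0, sigma_primary=0.5)
        th = np.linspace(-2, 2, 17)
        np.testing.assert_allclose(
            cb.p_choice_symmetric(th, p, "primary"),
            cb.p_choice_symmetric(th, p, "mirrored"))

    def test_value_matches_cdf_oracle(self, phi):
        """theta=1, delta_s=0.5, delta_d=0.25, sigma=0.5 gives Phi(2.5)."""
        p = cb.SymmetricParams(delta_s=0.5, delta_d=0.25, sigma_primary=0.5)
        expect = phi((1.0 - (0.25 - 0.5)) / 0.5)
        assert expect == pytest.approx(phi(2.5))
        assert cb.p_choice_symmetric(1.0, p, "primary") == pytest.approx(
            expect, abs=1e-9)

    def test_lapse_asymptotes(self):
        """theta -> -inf gives lam1; theta -> +inf gives 1 - lam2."""
        p = cb.SymmetricParams(sigma_primary=0.5, lam1=0.05, lam2=0.12)
        assert cb.p_choice_symmetric(-1e3, p, "primary") == pytest.approx(0.05)
        assert cb.p_choice_symmetric(1e3, p, "primary") == pytest.approx(0.88)

    def test_lambda_star_placement(self):
        """lam_star lowers the primary upper asymptote and raises the
        mirrored lower asymptote (key preference for one alternative)."""
        p = cb.SymmetricParams(sigma_primary=0.5, lam1=0.02, lam2=0.03,
                               lam1p=0.04, lam2p=0.05, lam_star=0.1)
        assert cb.p_choice_symmetric(1e3, p, "primary") == pytest.approx(
            1 - 0.03 - 0.1)
        assert cb.p_choice_symmetric(-1e3, p, "primary") == pytest.approx(0.02)
        assert cb.p_choice_symmetric(-1e3, p, "mirrored") == pytest.approx(
            0.04 + 0.1)
        assert cb.p_choice_symmetric(1e3, p, "mirrored") == pytest.approx(
            1 - 0.05)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(sigma_primary=0.0), "sigma_primary"),
        (dict(sigma_primary=0.5, lam1=0.6), "lam1"),
        (dict(sigma_primary=0.5, lam1=0.4, lam2=0.4, lam_star=0.3), "lam1"),
    ])
    def test_invalid_parameters_raise(self, kwargs, msg):
        with pytest.raises(InvalidParameterError, match=msg):
            cb.SymmetricParams(**kwargs)


class TestIndecision:
    def test_symmetric_guessing_neutral(self):
        """tau1 = -tau2, xi = 0.5: probability is 0.5 at theta = delta_s."""
        p = cb.IndecisionParams(delta_s=0.3, tau1=-0.7, tau2=0.7, xi=0.5,
                                sigma=0.6)
        assert cb.p_choice_indecision(0.3, p, "primary") == pytest.approx(0.5)

    def test_degenerate_interval_reduces_to_probit(self, phi):
        """tau1 = tau2 = tau removes guessing: Phi((theta-delta_s-tau)/sigma)."""
        p = cb.IndecisionParams(delta_s=0.2, tau1=0.4, tau2=0.4, xi=0.9,
                                sigma=0.5)
        for th in (-1.0, 0.0, 0.8):
            assert cb.p_choice_indecision(th, p, "primary") == pytest.approx(
                phi((th - 0.2 - 0.4) / 0.5), abs=1e-9)

    def test_value_composes_from_cdf_oracle(self, phi):
        p = cb.IndecisionParams(delta_s=0.0, tau1=-0.5, tau2=0.5, xi=0.25,
                                sigma=1.0)
        expect = phi(-0.5) + 0.25 * (phi(0.5) - phi(-0.5))
        assert cb.p_choice_indecision(0.0, p, "primary") == pytest.approx(
            expect, abs=1e-9)

    def test_mirrored_guess_complement(self):
        """The mirrored mapping guesses with probability 1 - xi."""
        p = cb.IndecisionParams(tau1=-0.5, tau2=0.5, xi=0.8, sigma=1.0)
        prim = cb.p_choice_indecision(0.0, p, "primary")
        mirr = cb.p_choice_indecision(0.0, p, "mirrored")
        assert prim + mirr == pytest.approx(1.0)

    def test_invalid_interval_raises(self):
        with pytest.raises(InvalidParameterError, match="tau1"):
            cb.IndecisionParams(tau1=0.5, tau2=-0.5, sigma=1.0)


class TestAsymmetric:
    def test_pure_sensory_bias_identical_curves(self):
        """delta_d = 0, equal half-widths: both mappings coincide, peak at
        delta_s."""
        p = cb.AsymmetricParams(delta_s=0.8, delta_d=0.0,
                                half_width_primary=1.0, sigma=0.5)
        th = np.linspace(-2, 2, 41)
        a = cb.p_aligned_asymmetric(th, p, "primary")
        b = cb.p_aligned_asymmetric(th, p, "mirrored")
        np.testing.assert_allclose(a, b)
        assert th[np.argmax(a)] == pytest.approx(0.8, abs=0.11)

    def test_halfwidth_dominance(self):
        """Wider primary interval: same peak location, everywhere >= the
        mirrored curve."""
        p = cb.AsymmetricParams(delta_s=0.5, delta_d=0.0,
                                half_width_primary=1.2,
                                half_width_mirrored=0.7, sigma=0.5)
        th = np.linspace(-3, 3, 61)
        a = cb.p_aligned_asymmetric(th, p, "primary")
        b = cb.p_aligned_asymmetric(th, p, "mirrored")
        assert np.all(a >= b - 1e-12)
        assert th[np.argmax(a)] == pytest.approx(th[np.argmax(b)])

    def test_peak_height_from_cdf_oracle(self, phi):
        """At the center the probability is 2*Phi(h/sigma) - 1."""
        p = cb.AsymmetricParams(half_width_primary=1.0, sigma=1.0)
        assert cb.p_aligned_asymmetric(0.0, p, "primary") == pytest.approx(
            2 * phi(1.0) - 1, abs=1e-9)

    def test_area_invariant_under_center_shift(self):
        """Shifting the interval center must not change the curve's area."""
        th = np.linspace(-30, 30, 4001)
        areas = []
        for dd in (0.0, 0.4, -0.7):
            p = cb.AsymmetricParams(delta_s=0.2, delta_d=dd,
                                    half_width_primary=0.9, sigma=0.6)
            areas.append(np.trapezoid(
                cb.p_aligned_asymmetric(th, p, "primary"), th))
        np.testing.assert_allclose(areas, areas[0], rtol=1e-10)

    def test_invalid_half_width_raises(self):
        with pytest.raises(InvalidParameterError, match="half_width"):
            cb.AsymmetricParams(half_width_primary=-1.0, sigma=0.5)


valid_symmetric = st.builds(
    cb.SymmetricParams,
    delta_s=st.floats(-5, 5), delta_d=st.floats(-5, 5),
    sigma_primary=st.floats(0.05, 5), sigma_mirrored=st.floats(0.05, 5),
    lam1=st.floats(0, 0.3), lam2=st.floats(0, 0.3),
    lam1p=st.floats(0, 0.3), lam2p=st.floats(0, 0.3),
    lam_star=st.floats(0, 0.3))


@settings(deadline=None, derandomize=True, max_examples=80)
@given(params=valid_symmetric, theta=st.floats(-20, 20),
       side=st.sampled_from(["primary", "mirrored"]))
def test_symmetric_probability_in_unit_interval(params, theta, side):
    p = cb.p_choice_symmetric(theta, params, side)
    assert 0.0 <= p <= 1.0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(params=valid_symmetric,
       thetas=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
       side=st.sampled_from(["primary", "mirrored"]))
def test_symmetric_monotone_in_theta(params, thetas, side):
    th = np.sort(np.asarray(thetas))
    p = cb.p_choice_symmetric(th, params, side)
    assert np.all(np.diff(p) >= -1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(delta_s=st.floats(-3, 3), delta_d=st.floats(-3, 3),
       sigma=st.floats(0.1, 3),
       lam_lo=st.floats(0, 0.3), lam_hi=st.floats(0, 0.3),
       theta=st.floats(-10, 10))
def test_mirror_identity(delta_s, delta_d, sigma, lam_lo, lam_hi, theta):
    """Flipping the sign of delta_d swaps the two mappings when slopes and
    lapses are side-symmetric."""
    a = cb.SymmetricParams(delta_s=delta_s, delta_d=delta_d,
                           sigma_primary=sigma, lam1=lam_lo, lam2=lam_hi,
                           lam1p=lam_lo, lam2p=lam_hi)
    b = cb.SymmetricParams(delta_s=delta_s, delta_d=-delta_d,
                           sigma_primary=sigma, lam1=lam_lo, lam2=lam_hi,
                           lam1p=lam_lo, lam2p=lam_hi)
    assert cb.p_choice_symmetric(theta, a, "primary") == pytest.approx(
        cb.p_choice_symmetric(theta, b, "mirrored"), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(delta_s=st.floats(-2, 2), tau=st.floats(0, 3), sigma=st.floats(0.1, 3),
       x=st.floats(0, 8))
def test_indecision_neutral_symmetry(delta_s, tau, sigma, x):
    """With xi = 0.5 and symmetric bounds, P(delta_s+x) + P(delta_s-x) = 1."""
    p = cb.IndecisionParams(delta_s=delta_s, tau1=-tau, tau2=tau, xi=0.5,
                            sigma=sigma)
    tot = (cb.p_choice_indecision(delta_s + x, p, "primary")
           + cb.p_choice_indecision(delta_s - x, p, "primary"))
    assert tot == pytest.approx(1.0, abs=1e-12)


class TestModelSpec:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(), 3),                                    # basic joint model
        (dict(n_sigmas=2, lapse_structure="four"), 8),  # fullest symmetric
        (dict(lapse_structure="four_plus_star", n_sigmas=2), 9),
        (dict(lapse_structure="one"), 4),
        (dict(bias_structure="none"), 1),
        (dict(family="indecision"), 5),
        (dict(family="indecision", symmetric_bounds=True), 4),
        (dict(family="asymmetric_interval"), 4),
        (dict(family="asymmetric_interval", n_sigmas=2,
              lapse_structure="two"), 7),
    ])
    def test_parameter_counts(self, kwargs, expected):
        assert cb.ModelSpec(**kwargs).n_parameters == expected

    def test_star_alias_normalized(self):
        spec = cb.ModelSpec(lapse_structure="four_plus_star")
        assert spec.lapse_structure == "four"
        assert spec.with_lambda_star

    def test_indecision_rejects_lapses(self):
        with pytest.raises(InvalidParameterError):
            cb.ModelSpec(family="indecision", lapse_structure="one")
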