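"""Forward force models: closed forms, continuity, limits, curve generation."""

import math
import warnings

import numpy as np
import pytest

from bluntfit import (
    IndenterGeometry,
    InvalidGeometryError,
    Material,
    SphereCorrectionCoefficients,
    TipFamily,
    contact_radius_from_depth,
    force_axisymmetric,
    force_blunted_cone,
    force_blunted_pyramid,
    force_from_depth,
    force_hertz,
    force_large_depth,
    force_sneddon_cone,
    force_sphere_corrected,
    generate_exact_curve,
    transition_depth,
    transition_radius,
)
from bluntfit.estimators import PowerLawForceFit

# hand-expanded arithmetic: (4/3) * (20e3/0.75) * sqrt(1e-7) * (1e-8)**1.5
HERTZ_F_20KPA_R100_H10 = 1.1243653902820905e-11
# (2/pi) * (1e3/0.75) * tan(25 deg)
SNEDDON_PREFACTOR_1KPA_25DEG = 395.81423358386013


class TestClosedForms:
    def test_hertz_frozen_value(self):
        F = force_hertz(10e-9, 100e-9, Material(E=20e3, nu=0.5))
        assert F == pytest.approx(HERTZ_F_20KPA_R100_H10, rel=1e-12)

    def test_hertz_linear_in_modulus(self):
        F1 = force_hertz(10e-9, 100e-9, Material(E=20e3, nu=0.5))
        F2 = force_hertz(10e-9, 100e-9, Material(E=40e3, nu=0.5))
        assert F2 == pytest.approx(2 * F1, rel=1e-14)
        assert force_hertz(0.0, 100e-9, Material(E=20e3)) == 0.0

    def test_sneddon_frozen_prefactor(self):
        mat = Material(E=1e3, nu=0.5)
        h = 50e-9
        F = force_sneddon_cone(h, math.radians(25), mat)
        assert F / h**2 == pytest.approx(SNEDDON_PREFACTOR_1KPA_25DEG, rel=1e-12)

    @pytest.mark.parametrize("h_nm", [1.0, 10.0, 300.0])
    def test_axisymmetric_reductions(self, h_nm):
        """Sneddon's general law collapses to the cone (n=1) and Hertz (n=2)."""
        h = h_nm * 1e-9
        mat = Material(E=20e3, nu=0.5)
        theta, R = math.radians(35), 100e-9
        assert force_axisymmetric(h, B=1 / math.tan(theta), n=1, mat=mat) == pytest.approx(
            force_sneddon_cone(h, theta, mat), rel=1e-13
        )
        assert force_axisymmetric(h, B=1 / (2 * R), n=2, mat=mat) == pytest.approx(
            force_hertz(h, R, mat), rel=1e-13
        )

    def test_axisymmetric_invalid_shape(self):
        with pytest.raises(ValueError):
            force_axisymmetric(1e-9, B=1.0, n=0.0, mat=Material(E=1e3))


class TestBluntedModels:
    @pytest.mark.parametrize("geom_kw,force_fn", [
        (dict(family="sphero_conical", R=20e-9, theta_deg=25), force_blunted_cone),
        (dict(family="sphero_conical", R=200e-9, theta_deg=35), force_blunted_cone),
        (dict(family="blunted_pyramid", R=200e-9, theta_deg=35, k=4), force_blunted_pyramid),
    ])
    def test_hertz_continuity_at_transition(self, geom_kw, force_fn, soft_gel):
        """The cap and body branches meet with no force jump at a = b."""
        geom = IndenterGeometry(**geom_kw)
        F_blunt = force_fn(transition_radius(geom), geom, soft_gel)
        F_hertz = force_hertz(transition_depth(geom), geom.R, soft_gel)
        assert F_blunt == pytest.approx(F_hertz, rel=1e-12)

    def test_below_transition_rejected(self, cone_25_20, soft_gel):
        with pytest.raises(ValueError):
            force_blunted_cone(0.5 * transition_radius(cone_25_20), cone_25_20, soft_gel)

    def test_family_mismatch_rejected(self, cone_25_20, pyramid_35_200, soft_gel):
        with pytest.raises(InvalidGeometryError):
            force_blunted_pyramid(cone_25_20.b, cone_25_20, soft_gel)
        with pytest.raises(InvalidGeometryError):
            force_blunted_cone(pyramid_35_200.b, pyramid_35_200, soft_gel)

    def test_pyramid_converges_to_cone(self, soft_gel):
        cone = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=100e-9, theta_deg=35)
        pyr = IndenterGeometry(TipFamily.BLUNTED_PYRAMID, R=100e-9, theta_deg=35, k=10_000)
        a = 2.5 * transition_radius(cone)
        assert force_blunted_pyramid(a, pyr, soft_gel) == pytest.approx(
            force_blunted_cone(a, cone, soft_gel), rel=1e-6
        )

    def test_monotone_in_contact_radius(self, cone_35_200, soft_gel):
        b = transition_radius(cone_35_200)
        a = np.linspace(b, 10 * b, 500)
        F = force_blunted_cone(a, cone_35_200, soft_gel)
        assert np.all(np.diff(F) > 0)

    def test_sneddon_limit_at_large_depth(self, cone_35_20, soft_gel):
        """Blunted-cone force approaches the perfect-cone law as h/R grows."""
        ratios = []
        for mult in (10, 100, 10_000):
            h = mult * cone_35_20.R
            a = contact_radius_from_depth(h, cone_35_20).a
            ratios.append(
                force_blunted_cone(a, cone_35_20, soft_gel)
                / force_sneddon_cone(h, cone_35_20.theta, soft_gel)
            )
        assert ratios[0] > ratios[1] > ratios[2] > 1.0
        assert ratios[2] == pytest.approx(1.0, abs=5e-3)


class TestSphereCorrected:
    def test_shallow_limit_is_scaled_hertz(self):
        """F / F_hertz -> c1 = 1.014 as h -> 0."""
        mat = Material(E=20e3, nu=0.5)
        R = 100e-9
        h = 1e-8 * R
        ratio = force_sphere_corrected(h, R, mat) / force_hertz(h, R, mat)
        assert ratio == pytest.approx(1.014, rel=1e-4)

    def test_softening_near_radius(self):
        """Z < 1 close to h = R: a naive Hertz fit underestimates E there."""
        mat = Material(E=20e3, nu=0.5)
        R = 100e-9
        h = 0.95 * R
        assert force_sphere_corrected(h, R, mat) < force_hertz(h, R, mat)

    def test_effective_exponent_below_three_halves(self):
        """Over 0 < h < R the corrected sphere fits a power law with 1 < m < 1.5."""
        mat = Material(E=20e3, nu=0.5)
        R = 100e-9
        h = np.linspace(R / 200, 0.99 * R, 200)
        F = force_sphere_corrected(h, R, mat)
        fit = PowerLawForceFit().fit(h, F)
        assert 1.0 < fit.exponent_ < 1.5

    def test_domain_warning(self):
        with pytest.warns(UserWarning):
            force_sphere_corrected(2e-7, 1e-7, Material(E=1e3))

    def test_custom_coefficients(self):
        # with c2 = c3 = 0 the model is exactly c1-scaled Hertz at any depth
        mat = Material(E=1e3, nu=0.5)
        coeff = SphereCorrectionCoefficients(c1=1.0, c2=0.0, c3=0.0)
        assert force_sphere_corrected(5e-8, 1e-7, mat, coeff) == pytest.approx(
            force_hertz(5e-8, 1e-7, mat), rel=1e-14
        )


class TestLargeDepth:
    @pytest.mark.parametrize("mult,rtol", [(3.0, 0.01), (10.0, 0.02)])
    def test_matches_exact_model(self, cone_35_20, soft_gel, mult, rtol):
        """The deep-contact closed form tracks the exact blunted cone."""
        h = mult * cone_35_20.R
        a = contact_radius_from_depth(h, cone_35_20).a
        exact = force_blunted_cone(a, cone_35_20, soft_gel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            approx = force_large_depth(h, cone_35_20, soft_gel)
        assert approx == pytest.approx(exact, rel=rtol)

    def test_sharp_tip_limit(self, soft_gel):
        geom = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=1e-12, theta_deg=35)
        h = 1e-6
        assert force_large_depth(h, geom, soft_gel) == pytest.approx(
            force_sneddon_cone(h, geom.theta, soft_gel), rel=1e-4
        )

    def test_shallow_warning(self, cone_35_20, soft_gel):
        with pytest.warns(UserWarning):
            force_large_depth(2 * cone_35_20.R, cone_35_20, soft_gel)

    def test_monotone(self, cone_35_20, soft_gel):
        h = np.linspace(3.1, 20, 100) * cone_35_20.R
        F = force_large_depth(h, cone_35_20, soft_gel)
        assert np.all(np.diff(F) > 0)


class TestGenerateExactCurve:
    def test_cap_domain_is_pure_hertz(self, cone_35_200, soft_gel):
        h_T = transition_depth(cone_35_200)
        curve = generate_exact_curve(
            cone_35_200, soft_gel, h_range=(h_T / 100, 0.99 * h_T), n_points=50
        )
        np.testing.assert_allclose(
            curve.F, force_hertz(curve.h, cone_35_200.R, soft_gel), rtol=1e-12
        )

    def test_continuous_across_transition(self, cone_35_200, soft_gel):
        h_T = transition_depth(cone_35_200)
        eps = 1e-9 * h_T
        lo = force_from_depth(h_T - eps, cone_35_200, soft_gel)
        hi = force_from_depth(h_T + eps, cone_35_200, soft_gel)
        assert hi == pytest.approx(lo, rel=1e-7)  # slope * eps bound
        # and exactly at the splice point the two branches are identical
        assert force_from_depth(h_T, cone_35_200, soft_gel) == pytest.approx(
            force_hertz(h_T, cone_35_200.R, soft_gel), rel=1e-12
        )

    @pytest.mark.parametrize("geom_kw", [
        dict(family="sphero_conical", R=200e-9, theta_deg=35),
        dict(family="blunted_pyramid", R=200e-9, theta_deg=35, k=4),
    ])
    def test_strictly_increasing_columns(self, geom_kw, soft_gel):
        geom = IndenterGeometry(**geom_kw)
        curve = generate_exact_curve(geom, soft_gel, h_range=(1e-9, 300e-9))
        assert np.all(np.diff(curve.h) > 0)
        assert np.all(np.diff(curve.F) > 0)

    def test_a_range_sampling(self, cone_25_20, unit_reduced):
        b = transition_radius(cone_25_20)
        curve = generate_exact_curve(cone_25_20, unit_reduced, a_range=(b, 1.25 * b))
        assert len(curve) == 200
        assert curve.h[0] == pytest.approx(transition_depth(cone_25_20), rel=1e-12)

    def test_fit_stable_under_sampling_density(self, cone_25_20, unit_reduced):
        """Power-law coefficients shift < 0.1% between 100 and 1000 points."""
        b = transition_radius(cone_25_20)
        ms = []
        for n in (100, 1000):
            curve = generate_exact_curve(
                cone_25_20, unit_reduced, a_range=(b, 1.25 * b), n_points=n
            )
            ms.append(PowerLawForceFit().fit(curve.h, curve.F).exponent_)
        assert abs(ms[1] - ms[0]) / ms[0] < 1e-3

    @pytest.mark.parametrize("kwargs", [
        dict(),                                        # no domain
        dict(a_range=(0, 1e-8), h_range=(0, 1e-8)),    # both domains
        dict(h_range=(1e-8, 1e-9)),                    # inverted
        dict(h_range=(1e-9, 1e-8), n_points=1),        # too few points
    ])
    def test_invalid_domain(self, cone_25_20, soft_gel, kwargs):
        with pytest.raises(ValueError):
            generate_exact_curve(cone_25_20, soft_gel, **kwargs)
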