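"""Contact-point detection and contact-model modulus fitting."""

import numpy as np
import pytest

from cardioafm import Cantilever, ForceCurve
from cardioafm.elasticity import (ElasticityResult, FitError, NoContactError,
                                  check_thin_sample, contact_model_force,
                                  detect_contact_point, fit_youngs_modulus)
from cardioafm.synthetic import gen_indentation_curve


def _piecewise_curve(kink=500, n=1000, slope=1e-2):
    """Flat baseline then a linear force ramp starting exactly at `kink`."""
    z = np.linspace(0, 2e-6, n)
    f = np.where(np.arange(n) >= kink, slope * (z - z[kink]), 0.0)
    return ForceCurve(time=np.arange(n, dtype=float), piezo_position=z,
                      segment=np.full(n, "approach", dtype=object),
                      force=f, calibrated=True)


class TestContactModels:
    def test_zero_indentation_zero_force(self, any_cantilever):
        assert contact_model_force(any_cantilever, 1e3, 0.0) == 0.0

    def test_sphere_closed_form_value(self):
        # E = 1 kPa, nu = 0.5, R = 1 um, delta = 100 nm:
        # F = (4/3)(1000/0.75) sqrt(1e-6) (1e-7)^1.5 = 5.6218...e-11 N
        cant = Cantilever(0.2, "sphere", tip_radius=1e-6, poisson_ratio_sample=0.5)
        f = contact_model_force(cant, 1e3, 100e-9)
        assert f == pytest.approx(5.621827e-11, rel=1e-6)

    def test_cone_closed_form_value(self):
        # F = (2/pi) (E/(1-nu^2)) tan(alpha) delta^2
        cant = Cantilever(0.2, "cone", half_angle=np.deg2rad(30), poisson_ratio_sample=0.5)
        expect = (2 / np.pi) * (1e3 / 0.75) * np.tan(np.deg2rad(30)) * (100e-9) ** 2
        assert contact_model_force(cant, 1e3, 100e-9) == pytest.approx(expect, rel=1e-12)


class TestContactPoint:
    def test_exact_kink_detected(self):
        curve = _piecewise_curve(kink=500)
        i, _ = detect_contact_point(curve, method="gradient_kink")
        assert abs(i - 500) <= 1

    def test_all_baseline_signals_no_contact(self):
        n = 200
        curve = ForceCurve(time=np.arange(n, dtype=float),
                           piezo_position=np.linspace(0, 1e-6, n),
                           segment=np.full(n, "approach", dtype=object),
                           force=np.zeros(n), calibrated=True)
        with pytest.raises(NoContactError):
            detect_contact_point(curve)

    def test_translation_invariance(self):
        shift = 0.4e-6
        a = _piecewise_curve(kink=400)
        b = _piecewise_curve(kink=400)
        b.piezo_position = b.piezo_position + shift
        _, za = detect_contact_point(a, method="gradient_kink")
        _, zb = detect_contact_point(b, method="gradient_kink")
        assert zb - za == pytest.approx(shift, abs=1e-12)

    def test_ratio_of_variance_on_noisy_curve(self, sphere_cantilever):
        curve, truth = gen_indentation_curve(5e3, sphere_cantilever,
                                             noise_fraction=0.01, seed=3)
        _, z0 = detect_contact_point(curve, method="ratio_of_variance")
        # coarse localization: within 20% of the piezo range of the true contact
        assert abs(z0 - truth["contact_position"]) < 0.4e-6


class TestModulusFit:
    def test_noiseless_recovery_all_geometries(self, any_cantilever):
        curve, _ = gen_indentation_curve(5e3, any_cantilever, seed=0)
        res = fit_youngs_modulus(curve, any_cantilever)
        assert res.youngs_modulus == pytest.approx(5e3, rel=1e-3)

    def test_scaling_law(self, sphere_cantilever):
        # at a fixed indentation axis, scaling all forces by c scales E by c
        n, z0 = 400, 1e-6
        z = np.linspace(0, 2e-6, n)
        delta = np.clip(z - z0, 0.0, None)
        f = contact_model_force(sphere_cantilever, 5e3, delta)

        def fit(scale):
            curve = ForceCurve(time=np.arange(n, dtype=float), piezo_position=z,
                               segment=np.full(n, "approach", dtype=object),
                               deflection=np.zeros(n), force=scale * f,
                               calibrated=True)
            return fit_youngs_modulus(curve, sphere_cantilever,
                                      contact=(n // 2, z0),
                                      refine_contact=False).youngs_modulus

        assert fit(3.0) / fit(1.0) == pytest.approx(3.0, rel=1e-9)

    def test_matched_geometry_beats_mismatched(self, cone_cantilever, sphere_cantilever):
        # conical data fitted with the spherical model leaves structure in the
        # residuals: the model-form dependence of apparent stiffness
        curve, _ = gen_indentation_curve(5e3, cone_cantilever, seed=2)
        matched = fit_youngs_modulus(curve, cone_cantilever)
        sphere_view = Cantilever(cone_cantilever.spring_constant, "sphere",
                                 tip_radius=1e-6)
        mismatched = fit_youngs_modulus(curve, sphere_view)
        assert matched.residual_rms < mismatched.residual_rms

    def test_too_few_points_is_fit_error(self, sphere_cantilever):
        curve, _ = gen_indentation_curve(5e3, sphere_cantilever, seed=0)
        with pytest.raises(FitError):
            fit_youngs_modulus(curve, sphere_cantilever,
                               contact=(0, 1.999e-6), refine_contact=False)


class TestThinSample:
    @pytest.mark.parametrize("delta_frac, valid", [
        (0.05, True),    # within the 10% rule
        (0.10, True),    # inclusive boundary
        (0.20, False),   # violates the rule
    ])
    def test_ten_percent_rule(self, delta_frac, valid):
        h = 10e-6
        res = ElasticityResult(youngs_modulus=1e3, contact_index=0,
                               contact_position=0.0, max_indentation=delta_frac * h,
                               fit_slice=slice(0, 1), residual_rms=0.0)
        assert check_thin_sample(res, h) is valid
        assert res.thin_sample_valid is valid

    def test_nonpositive_height_rejected(self):
        res = ElasticityResult(1e3, 0, 0.0, 1e-7, slice(0, 1), 0.0)
        with pytest.raises(ValueError):
            check_thin_sample(res, 0.0)
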