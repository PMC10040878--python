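"""Forward model: geometry, Laplace stresses, HGO constitutive stresses."""

import numpy as np
import pytest

from aortastress import mechanics
from aortastress.parameters import ModelParameters
from aortastress.units import PA_PER_MMHG

from conftest import random_admissible_states


class TestAreaFromAge:
    @pytest.mark.parametrize(
        "age, sex, expected_mm2",
        [
            (0.0, "male", 19.60),  # regression intercept
            (58.6, "male", 19.60 + 0.80 * 58.6),  # 66.48
            (59.0, "female", 20.52 + 0.56 * 59.0),  # 53.56
        ],
    )
    def test_regression_values(self, age, sex, expected_mm2):
        assert mechanics.area_from_age(age, sex) == pytest.approx(
            expected_mm2 * 1e-6, rel=1e-12
        )

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="unknown sex"):
            mechanics.area_from_age(30.0, "other")

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            mechanics.area_from_age(-1.0, "male")


class TestLaplaceStresses:
    def test_hand_computed_circumferential(self):
        # r0 = 10 mm, A = 66.48 mm^2, P = 134 mmHg
        lp = mechanics.laplace_stresses(
            10e-3, 134 * PA_PER_MMHG, 66.48e-6, force=0.0
        )
        expected = (4 * np.pi * 100 + 66.48) / (2 * 66.48) * 134 * PA_PER_MMHG
        assert lp.sigma_theta_lp == pytest.approx(expected, rel=1e-12)
        assert lp.sigma_theta_lp == pytest.approx(177.8e3, rel=1e-3)

    def test_zero_load_gives_zero_stress(self):
        lp = mechanics.laplace_stresses(9.7e-3, 0.0, 66.48e-6, force=0.0)
        assert lp.sigma_theta_lp == 0.0
        assert lp.sigma_z_lp == 0.0

    def test_linear_in_pressure(self):
        r0, area, force = 8e-3, 50e-6, 0.4
        base = mechanics.laplace_stresses(r0, 10e3, area, force)
        double = mechanics.laplace_stresses(r0, 20e3, area, force)
        # sigma_theta has no force offset; sigma_z is affine with offset F/A
        assert double.sigma_theta_lp == pytest.approx(2 * base.sigma_theta_lp)
        assert double.sigma_z_lp - force / area == pytest.approx(
            2 * (base.sigma_z_lp - force / area)
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            mechanics.laplace_stresses(10e-3, 1e4, 0.0, 0.0)


class TestAxialForce:
    def test_hand_computed_value(self):
        # gamma=0.59, P=13.3 kPa, r=9.7 mm, A=66.48 mm^2 -> F ~ 0.969 N
        f = mechanics.axial_force(0.59, 13.3e3, 9.7e-3, 66.48e-6)
        disc = np.pi * 9.7e-3**2
        expected = disc * 13.3e3 * (2 * 0.59 + 0.59 * 66.48e-6 / (2 * disc) - 1)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f == pytest.approx(0.969, rel=1e-3)

    def test_zero_force_at_critical_gamma(self):
        r_ref, area = 9.7e-3, 66.48e-6
        gamma = 1.0 / (2.0 + area / (2 * np.pi * r_ref**2))
        assert mechanics.axial_force(gamma, 13.3e3, r_ref, area) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("gamma", [0.3, 0.59, 0.8])
    @pytest.mark.parametrize("r_ref_mm, area_mm2", [(7.0, 40.0), (9.7, 66.48)])
    def test_reference_ratio_reproduced_exactly(self, gamma, r_ref_mm, area_mm2):
        """Substituting F back into the Laplace stresses at the reference
        state must return the assumed stress ratio to machine precision."""
        r_ref, area, p_ref = r_ref_mm * 1e-3, area_mm2 * 1e-6, 13.3e3
        force = mechanics.axial_force(gamma, p_ref, r_ref, area)
        lp = mechanics.laplace_stresses(r_ref, p_ref, area, force)
        assert lp.sigma_z_lp / lp.sigma_theta_lp == pytest.approx(gamma, rel=1e-14)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            mechanics.axial_force(1.2, 13.3e3, 9.7e-3, 66.48e-6)


class TestKinematics:
    def test_unloaded_configuration(self):
        params = ModelParameters(
            c=1e5, k1=1e4, k2=10.0, beta_deg=40.0, r0_unloaded=8e-3, lambda_z=1.0
        )
        # at r0 = R0 and lambda_z = 1 the area terms cancel: lambda_theta = 1
        kin = mechanics.kinematics(8e-3, params, 66.48e-6)
        assert kin.lambda_theta == pytest.approx(1.0, rel=1e-14)
        assert kin.i1 == pytest.approx(3.0, abs=1e-14)
        assert kin.i4 == pytest.approx(1.0, abs=1e-14)
        assert kin.psi == pytest.approx(0.0, abs=1e-9)

    def test_midwall_stretch_hand_value(self):
        # R0=7.8 mm, r0=10.0 mm, A=66.48 mm^2, lambda_z=1.03
        lt = mechanics.midwall_stretch(10e-3, 7.8e-3, 1.03, 66.48e-6)
        num = 4 * np.pi * 100 + 66.48
        den = 4 * np.pi * 7.8**2 + 1.03 * 66.48
        assert lt == pytest.approx((7.8 / 10.0) * num / den, rel=1e-12)
        assert lt == pytest.approx(1.239, abs=1e-3)

    def test_circumferential_fibers_drop_out_at_90_degrees(self):
        params = ModelParameters(
            c=1e5, k1=1e4, k2=10.0, beta_deg=90.0, r0_unloaded=7.8e-3, lambda_z=1.05
        )
        kins = [
            mechanics.kinematics(r, params, 66.48e-6) for r in (8e-3, 9e-3, 10e-3)
        ]
        for kin in kins:
            assert kin.i4 == pytest.approx(1.05**2, rel=1e-12)

    def test_zero_k2_rejected(self):
        params = ModelParameters(
            c=1e5, k1=1e4, k2=0.0, beta_deg=40.0, r0_unloaded=7.8e-3, lambda_z=1.03
        )
        with pytest.raises(ValueError, match="k2"):
            mechanics.kinematics(9e-3, params, 66.48e-6)


def _fd_oracle(params, r, area, h=1e-7):
    """Independent stresses via central finite differences of the strain
    energy with three independent stretches (lambda_r held at its
    incompressible value; p = 2 c lambda_r^2 from zero radial stress)."""
    lt = float(mechanics.midwall_stretch(r, params.r0_unloaded, params.lambda_z, area))
    lz = params.lambda_z
    lr = 1.0 / (lt * lz)
    cb2 = np.cos(params.beta_rad) ** 2
    sb2 = np.sin(params.beta_rad) ** 2

    def psi_iso(a, b, cc):
        return params.c * (a**2 + b**2 + cc**2 - 3.0)

    def psi_aniso(a, b, cc):
        i4 = a**2 * cb2 + b**2 * sb2
        return (params.k1 / params.k2) * (np.exp(params.k2 * (i4 - 1.0) ** 2) - 1.0)

    p_mult = 2.0 * params.c * lr**2

    def d_dlt(f):
        return (f(lt + h, lz, lr) - f(lt - h, lz, lr)) / (2 * h)

    def d_dlz(f):
        return (f(lt, lz + h, lr) - f(lt, lz - h, lr)) / (2 * h)

    return {
        "sigma_theta_iso": lt * d_dlt(psi_iso) - p_mult,
        "sigma_theta_aniso": lt * d_dlt(psi_aniso),
        "sigma_z_iso": lz * d_dlz(psi_iso) - p_mult,
        "sigma_z_aniso": lz * d_dlz(psi_aniso),
    }


class TestConstitutiveStresses:
    def test_stress_free_reference(self):
        params = ModelParameters(
            c=1e5, k1=1e4, k2=10.0, beta_deg=40.0, r0_unloaded=8e-3, lambda_z=1.0
        )
        dec = mechanics.constitutive_stresses(8e-3, params, 66.48e-6)
        for v in (
            dec.sigma_theta_iso,
            dec.sigma_theta_aniso,
            dec.sigma_z_iso,
            dec.sigma_z_aniso,
        ):
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_zero_fiber_stiffness_kills_anisotropy(self):
        params = ModelParameters(
            c=1e5, k1=0.0, k2=50.0, beta_deg=40.0, r0_unloaded=7.8e-3, lambda_z=1.03
        )
        dec = mechanics.constitutive_stresses(
            np.linspace(8e-3, 10e-3, 7), params, 66.48e-6
        )
        assert np.all(dec.sigma_theta_aniso == 0.0)
        assert np.all(dec.sigma_z_aniso == 0.0)

    def test_matches_finite_difference_oracle(self):
        """Analytic component formulas agree with lambda*dpsi/dlambda - p
        differentiated numerically, at 120 random admissible states."""
        for params, r, area in random_admissible_states(120, seed=42):
            dec = mechanics.constitutive_stresses(r, params, area)
            oracle = _fd_oracle(params, r, area)
            for name, expected in oracle.items():
                got = float(np.asarray(getattr(dec, name)))
                scale = max(abs(expected), 1e-3 * params.c)
                assert got == pytest.approx(expected, abs=1e-6 * scale + 1e-4), name

    def test_decomposition_additivity_is_exact(self):
        for params, r, area in random_admissible_states(50, seed=7):
            dec = mechanics.constitutive_stresses(r, params, area)
            assert dec.sigma_theta_tot == dec.sigma_theta_iso + dec.sigma_theta_aniso
            assert dec.sigma_z_tot == dec.sigma_z_iso + dec.sigma_z_aniso

    def test_aniso_nonnegative_when_fibers_stretched(self):
        for params, r, area in random_admissible_states(50, seed=11):
            kin = mechanics.kinematics(r, params, area)
            dec = mechanics.constitutive_stresses(r, params, area)
            if np.all(kin.i4 >= 1.0):
                assert np.all(np.asarray(dec.sigma_theta_aniso) >= 0.0)
                assert np.all(np.asarray(dec.sigma_z_aniso) >= 0.0)


class TestPressureFromRadius:
    def test_zero_at_stress_free_reference(self):
        params = ModelParameters(
            c=1e5, k1=1e4, k2=10.0, beta_deg=40.0, r0_unloaded=8e-3, lambda_z=1.0
        )
        assert mechanics.pressure_from_radius(8e-3, params, 66.48e-6) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_roundtrip_reproduces_total_stress(self, physiological_kappa):
        area = 66.48e-6
        r = np.linspace(8.25e-3, 8.5e-3, 9)
        p = mechanics.pressure_from_radius(r, physiological_kappa, area)
        lp = mechanics.laplace_stresses(r, p, area, force=0.0)
        dec = mechanics.constitutive_stresses(r, physiological_kappa, area)
        np.testing.assert_allclose(lp.sigma_theta_lp, dec.sigma_theta_tot, rtol=1e-13)

    def test_monotone_over_physiological_range(self, rep_spec, rep_area):
        r = np.linspace(rep_spec.r_dias, rep_spec.r_sys, 500)
        p = mechanics.pressure_from_radius(r, rep_spec.kappa_true, rep_area)
        assert np.all(np.diff(p) > 0)

    def test_solve_radius_roundtrip(self, rep_spec, rep_area):
        target = 12.0e3
        r = mechanics.solve_radius(rep_spec.kappa_true, rep_area, target)
        assert mechanics.pressure_from_radius(
            r, rep_spec.kappa_true, rep_area
        ) == pytest.approx(target, rel=1e-9)
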