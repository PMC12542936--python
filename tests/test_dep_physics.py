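import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanotwin import dep_physics as dp
from nanotwin.constants import EPS0, KB


class TestComplexPermittivity:
    def test_zero_conductivity_is_real(self):
        m = dp.Medium(rel_permittivity=80.0, conductivity=0.0)
        assert dp.complex_permittivity(m, 1e6) == 80.0 + 0j

    def test_lossy_medium_imaginary_part(self):
        # eps_r=80, sigma=0.03 S/m at 1 MHz: imag = -sigma/(2 pi f eps0)
        m = dp.Medium(rel_permittivity=80.0, conductivity=0.03)
        val = dp.complex_permittivity(m, 1e6)
        expected = -0.03 / (2 * math.pi * 1e6 * EPS0)
        assert val.real == 80.0
        assert val.imag == pytest.approx(expected)
        assert val.imag == pytest.approx(-539.26, rel=1e-3)

    def test_high_frequency_limit(self):
        m = dp.Medium(rel_permittivity=80.0, conductivity=1.0)
        assert abs(dp.complex_permittivity(m, 1e15).imag) < 1e-3

    def test_imaginary_part_nonpositive(self):
        m = dp.Medium(rel_permittivity=80.0, conductivity=0.5)
        assert dp.complex_permittivity(m, 1e4).imag <= 0

    def test_nonpositive_frequency_rejected(self):
        m = dp.Medium()
        with pytest.raises(ValueError):
            dp.complex_permittivity(m, 0.0)


class TestClausiusMossotti:
    def test_index_matched_is_zero(self):
        m = dp.Medium(rel_permittivity=40.0, conductivity=0.1)
        b = dp.DielectricBody(radius=1e-6, rel_permittivity=40.0, conductivity=0.1)
        assert dp.clausius_mossotti(b, m, 1e6) == pytest.approx(0.0)

    def test_ps_bead_in_water_high_frequency(self):
        # closed-form oracle: sigma ~ 0 for both, K = (2.5-80)/(2.5+160)
        m = dp.Medium(rel_permittivity=80.0, conductivity=0.0)
        b = dp.DielectricBody(radius=0.15e-6, rel_permittivity=2.5, conductivity=0.0)
        k = dp.clausius_mossotti(b, m, 1e8)
        assert k.real == pytest.approx((2.5 - 80) / (2.5 + 160), abs=1e-12)
        assert k.real == pytest.approx(-0.477, abs=1e-3)

    def test_default_mitochondrion_positive_dep_at_drive(self, medium, mito):
        assert dp.clausius_mossotti(mito, medium, 1e6).real > 0

    def test_thin_shell_limit_converges_to_homogeneous(self, medium):
        solid = dp.DielectricBody(radius=0.5e-6, rel_permittivity=60.0, conductivity=0.4)
        # convergence error scales as thickness * |eps_core*/eps_shell*| / a,
        # so an insulating shell must be extremely thin to reach 1e-9
        shelled = dp.DielectricBody(
            radius=0.5e-6, rel_permittivity=60.0, conductivity=0.4,
            shell=dp.Shell(thickness=1e-19, rel_permittivity=8.0, conductivity=1e-6))
        for f in (1e5, 1e6, 1e9):
            k0 = dp.clausius_mossotti(solid, medium, f)
            k1 = dp.clausius_mossotti(shelled, medium, f)
            assert abs(k0 - k1) < 1e-9

    def test_shell_matching_core_equals_homogeneous(self, medium):
        solid = dp.DielectricBody(radius=0.5e-6, rel_permittivity=60.0, conductivity=0.4)
        shelled = dp.DielectricBody(
            radius=0.5e-6, rel_permittivity=60.0, conductivity=0.4,
            shell=dp.Shell(thickness=0.1e-6, rel_permittivity=60.0, conductivity=0.4))
        for f in (1e3, 1e6, 1e9):
            assert abs(dp.clausius_mossotti(solid, medium, f)
                       - dp.clausius_mossotti(shelled, medium, f)) < 1e-9

    @settings(max_examples=200, deadline=None)
    @given(
        eps_p=st.floats(1.0, 100.0), sig_p=st.floats(0.0, 10.0),
        eps_m=st.floats(1.0, 100.0), sig_m=st.floats(0.0, 10.0),
        logf=st.floats(2.0, 10.0),
    )
    def test_real_part_bounds_property(self, eps_p, sig_p, eps_m, sig_m, logf):
        m = dp.Medium(rel_permittivity=eps_m, conductivity=sig_m)
        b = dp.DielectricBody(radius=1e-6, rel_permittivity=eps_p, conductivity=sig_p)
        k = dp.clausius_mossotti(b, m, 10.0**logf)
        assert -0.5 - 1e-9 <= k.real <= 1.0 + 1e-9


class TestGradE2:
    def test_voltage_squared_scaling(self, tip):
        d1 = dp.DepDrive(voltage_pp=3.5)
        d2 = dp.DepDrive(voltage_pp=7.0)
        assert dp.grad_E2(tip, d2, 1e-6) == pytest.approx(4 * dp.grad_E2(tip, d1, 1e-6))

    def test_strictly_decreasing_in_distance(self, tip, drive):
        s = np.linspace(0, 5e-6, 200)
        g = dp.grad_E2(tip, drive, s)
        assert np.all(np.diff(g) < 0)

    def test_power_law_ratio(self, tip, drive):
        r0 = tip.tip_radius
        ratio = dp.grad_E2(tip, drive, 9 * r0) / dp.grad_E2(tip, drive, 0.0)
        assert ratio == pytest.approx(1e-7, rel=1e-9)

    def test_uncalibrated_raises(self, drive):
        raw = dp.TipFieldModel()
        with pytest.raises(dp.CalibrationError):
            dp.grad_E2(raw, drive, 1e-6)


class TestDepForce:
    def test_zero_cm_gives_zero_force(self, tip, drive):
        m = dp.Medium(rel_permittivity=40.0, conductivity=0.1)
        b = dp.DielectricBody(radius=1e-6, rel_permittivity=40.0, conductivity=0.1)
        assert dp.dep_force(b, m, tip, drive, 1e-6) == pytest.approx(0.0, abs=1e-30)

    def test_calibration_anchor_one_nanonewton(self, medium, mito, tip, drive):
        f = dp.dep_force(mito, medium, tip, drive, mito.radius)
        assert abs(f) == pytest.approx(1.0e-9, rel=1e-12)
        assert f < 0  # attractive

    def test_voltage_squared_dependence(self, medium, mito, tip):
        f7 = dp.dep_force(mito, medium, tip, dp.DepDrive(voltage_pp=7.0), 1e-6)
        f35 = dp.dep_force(mito, medium, tip, dp.DepDrive(voltage_pp=3.5), 1e-6)
        assert f7 / f35 == pytest.approx(4.0)

    def test_disabled_drive_returns_zero_with_warning(self, medium, mito, tip):
        off = dp.DepDrive(voltage_pp=7.0, frequency=1e6, enabled=False)
        with pytest.warns(UserWarning):
            assert dp.dep_force(mito, medium, tip, off, 1e-6) == 0.0

    def test_cube_radius_scaling(self, medium, tip, drive):
        b1 = dp.DielectricBody(radius=0.2e-6, rel_permittivity=2.5, conductivity=0.013)
        b2 = dp.DielectricBody(radius=0.4e-6, rel_permittivity=2.5, conductivity=0.013)
        f1 = dp.dep_force(b1, medium, tip, drive, 2e-6)
        f2 = dp.dep_force(b2, medium, tip, drive, 2e-6)
        assert f2 / f1 == pytest.approx(8.0)


class TestCalibration:
    def test_fixed_point(self, medium):
        tip = dp.calibrate_tip(dp.TipFieldModel(), medium)
        body, drv = tip.reference_body, tip.reference_drive
        f = dp.dep_force(body, medium, tip, drv, body.radius)
        assert abs(f) == pytest.approx(tip.force_calibration, rel=1e-14)

    def test_linearity_in_force_calibration(self, medium):
        t1 = dp.calibrate_tip(dp.TipFieldModel(force_calibration=1e-9), medium)
        t2 = dp.calibrate_tip(dp.TipFieldModel(force_calibration=2e-9), medium)
        assert t2.g0 == pytest.approx(2 * t1.g0)

    def test_repulsive_reference_rejected(self):
        # PS bead in a conductive medium at 100 MHz has Re[K] < 0
        body = dp.DielectricBody(radius=0.15e-6, rel_permittivity=2.5, conductivity=0.0)
        tip = dp.TipFieldModel(reference_body=body,
                               reference_drive=dp.DepDrive(frequency=1e8))
        with pytest.raises(dp.CalibrationError):
            dp.calibrate_tip(tip, dp.Medium(rel_permittivity=80.0, conductivity=0.0))


class TestPotential:
    def test_vanishes_at_infinity(self, medium, mito, tip, drive):
        assert abs(dp.dep_potential(mito, medium, tip, drive, 1.0)) < 1e-40

    def test_force_is_negative_potential_gradient(self, medium, mito, tip, drive):
        # central-difference oracle on 100 random configurations
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = rng.uniform(0.2e-6, 4e-6)
            v = rng.uniform(1.0, 8.0)
            drv = dp.DepDrive(voltage_pp=v, frequency=1e6)
            h = s * 1e-5
            u_hi = dp.dep_potential(mito, medium, tip, drv, s + h)
            u_lo = dp.dep_potential(mito, medium, tip, drv, s - h)
            f_fd = -(u_hi - u_lo) / (2 * h)
            f = dp.dep_force(mito, medium, tip, drv, s)
            assert f == pytest.approx(f_fd, rel=1e-6)

    def test_contact_depth_closed_form(self, medium, mito, tip, drive):
        # |U(contact)| = F_cal * (a + r0) / 6, i.e. 1e4-1e5 kT
        u = dp.dep_potential(mito, medium, tip, drive, mito.radius)
        expected = tip.force_calibration * (mito.radius + tip.tip_radius) / 6.0
        assert abs(u) == pytest.approx(expected, rel=1e-12)
        kt = KB * medium.temperature
        assert 1e4 < abs(u) / kt < 1e5


class TestTrappingRadius:
    def test_large_threshold_shrinks_to_zero(self, medium, mito, tip, drive):
        assert dp.trapping_radius(mito, medium, tip, drive, threshold_kT=1e30) == 0.0

    def test_voltage_scaling_sixth_root(self, medium, mito, tip):
        r0 = tip.tip_radius
        s1 = dp.trapping_radius(mito, medium, tip, dp.DepDrive(voltage_pp=3.5))
        s2 = dp.trapping_radius(mito, medium, tip, dp.DepDrive(voltage_pp=7.0))
        assert (s2 + r0) / (s1 + r0) == pytest.approx(4.0 ** (1 / 6), rel=1e-9)

    def test_monotone_in_voltage(self, medium, mito, tip):
        radii = [dp.trapping_radius(mito, medium, tip, dp.DepDrive(voltage_pp=v))
                 for v in (1, 2, 4, 7)]
        assert all(a < b for a, b in zip(radii, radii[1:]))

    def test_default_same_order_as_reported_region(self, medium, mito, tip, drive):
        r = dp.trapping_radius(mito, medium, tip, drive)
        assert 0.5e-6 <= r <= 5e-6

    def test_repulsive_returns_zero(self, tip):
        m = dp.Medium(rel_permittivity=80.0, conductivity=0.0)
        b = dp.DielectricBody(radius=0.15e-6, rel_permittivity=2.5, conductivity=0.0)
        assert dp.trapping_radius(b, m, tip, dp.DepDrive(frequency=1e8)) == 0.0


class TestInvariants:
    def test_body_invariants(self):
        with pytest.raises(ValueError):
            dp.DielectricBody(radius=-1e-6, rel_permittivity=2.5, conductivity=0.0)
        with pytest.raises(ValueError):
            dp.DielectricBody(radius=1e-6, rel_permittivity=2.5, conductivity=0.0,
                              shell=dp.Shell(thickness=2e-6, rel_permittivity=8, conductivity=0))

    def test_medium_invariants(self):
        with pytest.raises(ValueError):
            dp.Medium(rel_permittivity=0.5)
        with pytest.raises(ValueError):
            dp.Medium(viscosity=0.0)

    def test_drive_invariants(self):
        with pytest.raises(ValueError):
            dp.DepDrive(voltage_pp=-1.0)
        with pytest.raises(ValueError):
            dp.DepDrive(frequency=0.0)

    def test_rms_convention(self):
        assert dp.DepDrive(voltage_pp=7.0).v_rms == pytest.approx(7.0 / (2 * math.sqrt(2)))
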