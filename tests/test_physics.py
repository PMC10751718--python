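"""Electron kinematics, gyroradius, stopping power and rotation primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fanomc import (B_RIGIDITY, ELECTRON_REST_MEV, collision_stopping_power,
                    gyroradius, lorentz_kinematics, magnetic_deflection,
                    max_em_step, multiple_scattering_sigma, rotate_about_axis)
from fanomc.physics import csda_mass_range, min_stopping_power


class TestKinematics:
    def test_rest_case(self):
        k = lorentz_kinematics(0.0)
        assert k.gamma == 1.0 and k.beta == 0.0 and k.momentum_c == 0.0

    def test_one_rest_mass_of_kinetic_energy(self):
        k = lorentz_kinematics(0.5110)
        assert k.gamma == pytest.approx(2.0, rel=1e-12)
        assert k.beta == pytest.approx(np.sqrt(3.0) / 2.0, rel=1e-12)

    def test_momentum_at_1mev(self):
        # sqrt(T (T + 2 m0c^2)) = sqrt(1 * 2.022)
        assert lorentz_kinematics(1.0).momentum_c == pytest.approx(
            np.sqrt(2.022), rel=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            lorentz_kinematics(-0.1)

    @given(st.floats(min_value=0.0, max_value=100.0))
    def test_invariants(self, T):
        k = lorentz_kinematics(T)
        assert k.gamma == pytest.approx(1.0 + T / ELECTRON_REST_MEV, rel=1e-12)
        assert 0.0 <= k.beta < 1.0
        assert k.beta == pytest.approx(np.sqrt(1.0 - 1.0 / k.gamma**2), abs=1e-12)
        assert k.momentum_c == pytest.approx(
            np.sqrt(T * (T + 2.0 * ELECTRON_REST_MEV)), rel=1e-12)


class TestGyroradius:
    def test_1mev_perpendicular_at_1p5t(self):
        assert gyroradius(1.0, 1.5, 1.0) == pytest.approx(0.31621, rel=1e-4)

    def test_0p1mev_perpendicular_at_1p5t(self):
        # pc = sqrt(0.1 * 1.122) = 0.3349627 MeV
        assert gyroradius(0.1, 1.5, 1.0) == pytest.approx(0.074488, rel=1e-4)

    def test_parallel_motion_gives_no_deflection_sentinel(self):
        assert np.isinf(gyroradius(1.0, 1.5, 0.0))
        assert np.isinf(gyroradius(1.0, 0.0, 1.0))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gyroradius(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            gyroradius(1.0, 1.5, 1.2)

    @given(st.floats(min_value=1e-3, max_value=50.0),
           st.floats(min_value=0.05, max_value=10.0),
           st.floats(min_value=1e-3, max_value=1.0))
    def test_matches_momentum_over_rigidity(self, T, B, sina):
        pc = lorentz_kinematics(T).momentum_c
        assert gyroradius(T, B, sina) == pytest.approx(
            pc / (B_RIGIDITY * B * sina), rel=1e-12)


class TestMaxEmStep:
    def test_one_percent_of_gyroradius(self):
        s = max_em_step(1.0, (0.0, 0.0, 1.5), (1.0, 0.0, 0.0), 0.01)
        assert s == pytest.approx(3.1621e-3, rel=1e-4)

    def test_quarter_fraction(self):
        s = max_em_step(1.0, (0.0, 0.0, 1.5), (1.0, 0.0, 0.0), 0.25)
        assert s == pytest.approx(0.079053, rel=1e-4)

    def test_linear_in_fraction(self):
        s1 = max_em_step(1.0, (0.0, 0.0, 1.5), (0.6, 0.0, 0.8), 0.05)
        s2 = max_em_step(1.0, (0.0, 0.0, 1.5), (0.6, 0.0, 0.8), 0.10)
        assert s2 == 2.0 * s1

    def test_field_off_means_no_limit(self):
        assert np.isinf(max_em_step(1.0, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), 0.1))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            max_em_step(1.0, (0.0, 0.0, 1.5), (1.0, 0.0, 0.0), 1.5)


class TestStoppingPower:
    def test_value_at_1mev(self):
        # frozen from an independent evaluation of the Moller/ICRU form
        assert collision_stopping_power(1.0) == pytest.approx(1.87248, rel=1e-5)

    def test_within_3_percent_of_published_water_tables(self):
        # reference collision stopping powers of liquid water (MeV cm^2/g)
        for energy, published in ((0.1, 4.115), (1.0, 1.849), (0.5, 2.034)):
            assert collision_stopping_power(energy) == pytest.approx(
                published, rel=0.03)

    def test_decreasing_between_0p1_and_1mev(self):
        grid = np.linspace(0.1, 1.0, 50)
        values = [collision_stopping_power(t) for t in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    @given(st.floats(min_value=1e-3, max_value=20.0))
    def test_strictly_positive(self, T):
        assert collision_stopping_power(T) > 0.0

    def test_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            collision_stopping_power(5e-4)

    def test_min_stopping_power_is_a_lower_bound(self):
        smin = min_stopping_power(6.0)
        for t in np.geomspace(1e-3, 6.0, 200):
            assert smin <= collision_stopping_power(t)

    def test_csda_range_of_1mev_electron_in_water(self):
        # independent quadrature oracle
        from scipy.integrate import quad
        oracle, _ = quad(lambda t: 1.0 / collision_stopping_power(t), 1e-3, 1.0,
                         limit=200)
        assert csda_mass_range(1.0) == pytest.approx(oracle, rel=1e-3)


class TestMultipleScatteringSigma:
    def test_zero_thickness(self):
        assert multiple_scattering_sigma(1.0, 0.0) == 0.0

    def test_sqrt_scaling_up_to_log_correction(self):
        t = 0.01
        assert multiple_scattering_sigma(1.0, 4 * t) == pytest.approx(
            2.0 * multiple_scattering_sigma(1.0, t), rel=0.1)

    def test_highland_formula_value(self):
        # independent re-evaluation of the stated formula
        k = lorentz_kinematics(1.0)
        t = 0.01
        x = t / 36.08
        expected = 13.6 / (k.beta * k.momentum_c) * np.sqrt(x) * (
            1.0 + 0.038 * np.log(x))
        assert multiple_scattering_sigma(1.0, t) == pytest.approx(
            expected, rel=1e-12)

    def test_bracket_clamped_below(self):
        # tiny thickness: log correction would go negative, clamps at 0.25
        k = lorentz_kinematics(1.0)
        t = 1e-9
        expected = 13.6 / (k.beta * k.momentum_c) * np.sqrt(t / 36.08) * 0.25
        assert multiple_scattering_sigma(1.0, t) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_width_clamped_above(self):
        assert multiple_scattering_sigma(0.01, 10.0) == 0.5

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            multiple_scattering_sigma(1.0, -1.0)


class TestRotations:
    def test_identity_and_full_turn(self):
        u = np.array([0.6, 0.0, 0.8])
        a = np.array([0.0, 1.0, 0.0])
        assert np.allclose(rotate_about_axis(u, a, 0.0), u)
        assert np.allclose(rotate_about_axis(u, a, 2 * np.pi), u, atol=1e-12)

    def test_quarter_turn(self):
        out = rotate_about_axis((1.0, 0.0, 0.0), (0.0, 0.0, 1.0), np.pi / 2)
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-12)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            rotate_about_axis((2.0, 0.0, 0.0), (0.0, 0.0, 1.0), 0.1)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_norm_preserved(self, k):
        r = np.random.default_rng(k)
        u = r.normal(size=3)
        u /= np.linalg.norm(u)
        a = r.normal(size=3)
        a /= np.linalg.norm(a)
        out = rotate_about_axis(u, a, r.uniform(-10, 10))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


class TestMagneticDeflection:
    B = np.array([0.0, 0.0, 1.5])

    def test_full_gyration_returns_direction(self):
        u = np.array([1.0, 0.0, 0.0])
        r_g = gyroradius(1.0, 1.5, 1.0)
        out = magnetic_deflection(u, self.B, 2 * np.pi * r_g, 1.0)
        assert np.allclose(out, u, atol=1e-9)

    def test_quarter_gyration_rotates_90_degrees(self):
        u = np.array([1.0, 0.0, 0.0])
        r_g = gyroradius(1.0, 1.5, 1.0)
        out = magnetic_deflection(u, self.B, 0.5 * np.pi * r_g, 1.0)
        assert abs(np.dot(out, u)) < 1e-12
        assert abs(out[2]) < 1e-12

    def test_small_step_matches_first_order_of_the_deflection_equation(self):
        # du ~ (s/r_G) * unit(u x B-hat) for s << r_G
        u = np.array([0.8, 0.0, 0.6])
        r_g = gyroradius(1.0, 1.5, 0.8)  # sin angle to B-hat = |u x z| = 0.8
        s = 1e-4 * r_g
        out = magnetic_deflection(u, self.B, s, 1.0)
        du = out - u
        cross = np.cross(u, self.B / 1.5)
        expected = (s / r_g) * cross / np.linalg.norm(cross)
        # second-order terms are O((s/r_G)^2) ~ 1e-8
        assert np.allclose(du, expected, rtol=1e-3, atol=2e-8)

    def test_parallel_component_and_norm_preserved(self):
        r = np.random.default_rng(7)
        for _ in range(50):
            u = r.normal(size=3)
            u /= np.linalg.norm(u)
            out = magnetic_deflection(u, self.B, r.uniform(0, 1.0), 1.0)
            assert out[2] == pytest.approx(u[2], abs=1e-12)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_field_off_leaves_direction_unchanged(self):
        u = np.array([0.0, 1.0, 0.0])
        assert np.array_equal(magnetic_deflection(u, (0, 0, 0), 0.5, 1.0), u)

    def test_first_order_variant_close_to_exact_for_small_steps(self):
        u = np.array([0.0, 1.0, 0.0])
        s = 1e-3 * gyroradius(1.0, 1.5, 1.0)
        exact = magnetic_deflection(u, self.B, s, 1.0)
        approx = magnetic_deflection(u, self.B, s, 1.0, first_order=True)
        assert np.allclose(exact, approx, atol=1e-6)

    def test_vacuum_helix_reverses_transverse_component(self):
        # N chained steps of pi r_G / N reverse u_perp within 1e-6,
        # leaving the energy untouched by construction (field does no work)
        n = 1000
        u = np.array([1.0, 0.0, 0.0])
        r_g = gyroradius(1.0, 1.5, 1.0)
        s = np.pi * r_g / n
        for _ in range(n):
            u = magnetic_deflection(u, self.B, s, 1.0)
        assert abs(u[0] + 1.0) < 1e-6
        assert abs(u[2]) < 1e-9
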