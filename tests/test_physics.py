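"""Closed-form water-hammer physics: spot values, limits, and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydropulse import FluidSpec, ProjectileSpec, SourcePulse, TubeSpec
from hydropulse import physics as ph


def tube_with(**overrides):
    base = dict(
        mean_radius=6e-3,
        wall_thickness=0.25e-3,
        length=0.14,
        wall_modulus=196e9,
        wall_density=7850.0,
        poisson_ratio=0.3,
    )
    base.update(overrides)
    return TubeSpec(**base)


class TestSoundSpeedAndImpedance:
    @pytest.mark.parametrize(
        "bulk_modulus, density, expected",
        [
            (2.25e9, 1000.0, 1500.0),  # perfect square
            (2.24e9, 1000.0, 1496.6629547095765),
            (2.24e9, 4000.0, 1496.6629547095765 / 2),  # rho x4 halves c0
        ],
    )
    def test_fluid_sound_speed(self, bulk_modulus, density, expected):
        fluid = FluidSpec(density=density, bulk_modulus=bulk_modulus)
        assert ph.fluid_sound_speed(fluid) == pytest.approx(expected, rel=1e-12)

    def test_invalid_fluid_rejected(self):
        with pytest.raises(ValueError):
            FluidSpec(density=-1.0, bulk_modulus=2.2e9)
        with pytest.raises(ValueError):
            FluidSpec(density=1000.0, bulk_modulus=0.0)

    @pytest.mark.parametrize(
        "density, speed, expected",
        [(1000.0, 1500.0, 1.5e6), (7850.0, 4996.8, 3.9224880e7), (1.0, 1.0, 1.0)],
    )
    def test_acoustic_impedance(self, density, speed, expected):
        assert ph.acoustic_impedance(density, speed) == pytest.approx(expected, rel=1e-6)

    def test_acoustic_impedance_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ph.acoustic_impedance(0.0, 1500.0)


class TestJoukowsky:
    def test_exact_form_hand_value(self):
        assert ph.joukowsky_peak_exact(1.5e6, 3.922e7, 10.0) == pytest.approx(1.4447e7, rel=1e-4)

    def test_symmetric_impedances_halve_the_limit(self):
        assert ph.joukowsky_peak_exact(2e6, 2e6, 1.0) == pytest.approx(1e6, rel=1e-12)

    def test_rigid_striker_limit(self):
        # Zp >> Zf: exact form approaches Zf*V0 from below
        exact = ph.joukowsky_peak_exact(1.5e6, 1e15, 10.0)
        assert exact == pytest.approx(1.5e7, rel=1e-8)
        assert exact < ph.joukowsky_peak(1.5e6, 10.0)

    def test_limit_form_values(self):
        assert ph.joukowsky_peak(1.5e6, 0.0) == 0.0
        assert ph.joukowsky_peak(1.2e6, 5.0) == pytest.approx(6e6)
        # the bench's high loading level: water at Korteweg celerity, 11.24 m/s
        assert ph.joukowsky_peak(1000.0 * 1201.0, 11.24) == pytest.approx(13.5e6, rel=1e-3)

    @given(
        zf=st.floats(1e5, 1e7),
        ratio=st.floats(19.0, 1e4),
        v0=st.floats(0.1, 100.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_exact_vs_limit_relative_gap(self, zf, ratio, v0):
        """Relative gap between the two forms is Zf/(Zf+Zp); <5% when Zp > 19 Zf."""
        zp = ratio * zf
        exact = ph.joukowsky_peak_exact(zf, zp, v0)
        limit = ph.joukowsky_peak(zf, v0)
        gap = (limit - exact) / limit
        assert gap == pytest.approx(zf / (zf + zp), rel=1e-9)
        assert gap < 0.05 + 1e-12


class TestDecayAndWaveform:
    def test_decay_constant_for_bench_striker(self, projectile):
        theta = ph.decay_time_constant(projectile, 1000.0 * 1201.0)
        assert theta == pytest.approx(163.4e-6, rel=1e-3)

    def test_decay_constant_linearity_and_unit_case(self):
        p1 = ProjectileSpec(density=7850.0, bar_speed=4996.8, length=0.025, velocity=10.0)
        p2 = ProjectileSpec(density=7850.0, bar_speed=4996.8, length=0.050, velocity=10.0)
        zf = 1.2e6
        assert ph.decay_time_constant(p2, zf) == pytest.approx(2 * ph.decay_time_constant(p1, zf), rel=1e-12)
        unit = ProjectileSpec(density=500.0, bar_speed=1.0, length=2.0, velocity=1.0)
        assert ph.decay_time_constant(unit, 1000.0) == pytest.approx(1.0, rel=1e-12)

    def test_waveform_onset_and_efolding(self):
        pulse = SourcePulse(peak_pressure=2e6, decay_constant=1e-4, onset_time=3e-5)
        t = np.array([0.0, 3e-5, 3e-5 + 1e-4])
        p = ph.pressure_waveform(pulse, t)
        assert p[0] == 0.0
        assert p[1] == pytest.approx(2e6)
        assert p[2] == pytest.approx(2e6 / math.e, rel=1e-12)

    def test_waveform_area_is_p0_theta(self):
        """Trapezoidal integral over 20 decay constants conserves P0*theta."""
        pulse = SourcePulse(peak_pressure=5e6, decay_constant=163e-6, onset_time=0.0)
        t = np.linspace(0.0, 20 * pulse.decay_constant, 400_001)
        area = np.trapezoid(ph.pressure_waveform(pulse, t), t)
        assert area == pytest.approx(pulse.peak_pressure * pulse.decay_constant, rel=1e-4)

    def test_waveform_rejects_unsorted_times(self):
        pulse = SourcePulse(peak_pressure=1e6, decay_constant=1e-4)
        with pytest.raises(ValueError):
            ph.pressure_waveform(pulse, np.array([1e-4, 0.0]))


class TestCelerity:
    def test_beta_default_value(self, water, steel_tube):
        assert ph.coupling_beta(water, steel_tube) == pytest.approx(0.5486, rel=1e-3)

    def test_beta_limits_and_scaling(self, water):
        thick = tube_with(wall_thickness=5.9e-3)  # near-rigid wall
        assert ph.coupling_beta(water, thick) < 0.03
        r1 = tube_with(mean_radius=6e-3)
        r2 = tube_with(mean_radius=12e-3)
        assert ph.coupling_beta(water, r2) == pytest.approx(2 * ph.coupling_beta(water, r1), rel=1e-12)

    def test_korteweg_default_matches_bench_theory(self, water, steel_tube):
        assert ph.korteweg_celerity(water, steel_tube) == pytest.approx(1201.0, rel=0.01)

    def test_korteweg_closed_form_beta3(self, water):
        # pick geometry with beta exactly 3 -> cf = c0/2
        c0, cs = water.sound_speed, tube_with().bar_speed
        target_ratio = 3.0 / ((c0**2 / cs**2) * (water.density / 7850.0))
        tube = tube_with(mean_radius=target_ratio * 0.25e-3 / 2, wall_thickness=0.25e-3)
        assert ph.coupling_beta(water, tube) == pytest.approx(3.0, rel=1e-12)
        assert ph.korteweg_celerity(water, tube) == pytest.approx(c0 / 2, rel=1e-12)

    def test_general_celerity_limits(self, water):
        assert ph.general_celerity(water, 0.0) == pytest.approx(water.sound_speed, rel=1e-14)
        assert ph.general_celerity(water, 1.0 / water.bulk_modulus) == pytest.approx(
            water.sound_speed / math.sqrt(2), rel=1e-14
        )

    def test_bar_speed_default_and_scaling(self, steel_tube):
        assert ph.tube_bar_speed(steel_tube) == pytest.approx(4996.8, rel=1e-4)
        quad = tube_with(wall_modulus=4 * 196e9)
        assert ph.tube_bar_speed(quad) == pytest.approx(2 * steel_tube.bar_speed, rel=1e-12)

    @given(
        density=st.floats(600.0, 1600.0),
        bulk=st.floats(0.5e9, 4e9),
        radius=st.floats(2e-3, 30e-3),
        h_frac=st.floats(0.01, 0.5),
        modulus=st.floats(1e9, 400e9),
        wall_density=st.floats(1000.0, 12000.0),
    )
    @settings(derandomize=True, max_examples=1000, deadline=None)
    def test_three_celerity_routes_agree(self, density, bulk, radius, h_frac, modulus, wall_density):
        """Compliance form, Korteweg reciprocal form, and c0/sqrt(1+beta) coincide."""
        fluid = FluidSpec(density=density, bulk_modulus=bulk)
        tube = tube_with(
            mean_radius=radius,
            wall_thickness=h_frac * radius,
            wall_modulus=modulus,
            wall_density=wall_density,
        )
        via_beta = ph.korteweg_celerity(fluid, tube)
        via_compliance = ph.general_celerity(fluid, tube.normalized_compliance)
        via_reciprocal = (
            fluid.sound_speed**-2 + fluid.density * 2 * tube.mean_radius / (tube.wall_modulus * tube.wall_thickness)
        ) ** -0.5
        assert via_compliance == pytest.approx(via_beta, rel=1e-12)
        assert via_reciprocal == pytest.approx(via_beta, rel=1e-12)
        assert via_beta <= fluid.sound_speed

    @given(scale=st.floats(1.01, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_korteweg_monotonicity(self, scale, water, steel_tube):
        """Celerity falls with R/h and rho_f, rises with wall stiffness."""
        base = ph.korteweg_celerity(water, steel_tube)
        wider = tube_with(mean_radius=steel_tube.mean_radius * scale)
        stiffer = tube_with(wall_modulus=steel_tube.wall_modulus * scale)
        denser = FluidSpec(density=water.density * scale, bulk_modulus=water.bulk_modulus)
        assert ph.korteweg_celerity(water, wider) < base
        assert ph.korteweg_celerity(water, stiffer) > base
        assert ph.korteweg_celerity(denser, steel_tube) < ph.general_celerity(denser, 0.0)


class TestStrainRelations:
    def test_hoop_strain_spot_values(self, steel_tube):
        assert ph.hoop_strain_from_pressure(0.0, steel_tube) == 0.0
        # Es h / R = 8.167 GPa: 8.167 MPa of pressure is 1 m-strain
        assert ph.hoop_strain_from_pressure(8.1667e6, steel_tube) == pytest.approx(1e-3, rel=1e-4)

    @given(pressure=st.floats(1e3, 2e7))
    @settings(derandomize=True, max_examples=50)
    def test_hoop_pressure_round_trip(self, pressure, steel_tube):
        eps = ph.hoop_strain_from_pressure(pressure, steel_tube)
        assert ph.pressure_from_hoop_strain(eps, steel_tube) == pytest.approx(pressure, rel=1e-14)

    @pytest.mark.parametrize(
        "hoop, nu, expected",
        [(1e-3, 0.3, -0.3e-3), (0.0, 0.3, 0.0), (2e-3, 0.25, -0.5e-3)],
    )
    def test_axial_strain_is_minus_nu_hoop(self, hoop, nu, expected):
        assert ph.axial_strain_from_hoop(hoop, nu) == pytest.approx(expected, abs=1e-18)

    def test_axial_strain_rejects_bad_poisson(self):
        with pytest.raises(ValueError):
            ph.axial_strain_from_hoop(1e-3, 0.7)


def test_source_pulse_for_bench_defaults(water, steel_tube, projectile):
    pulse = ph.source_pulse_for(water, steel_tube, projectile)
    cf = ph.korteweg_celerity(water, steel_tube)
    assert pulse.peak_pressure == pytest.approx(water.density * cf * projectile.velocity, rel=1e-12)
    assert pulse.decay_constant == pytest.approx(projectile.areal_mass / (water.density * cf), rel=1e-12)
    assert pulse.peak_pressure == pytest.approx(13.5e6, rel=0.005)
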