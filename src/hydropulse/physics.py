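"""Closed-form water-hammer physics for the fluid-filled cell tube.

The loading platform fires a projectile at a confined liquid column.  The
impact launches a weak compression wave whose peak follows the Joukowsky
relation, whose tail decays exponentially with a time constant set by the
projectile's areal mass, and whose propagation speed is reduced below the
free-fluid sound speed by the compliance of the elastic tube wall
(Moens-Korteweg).  Everything here is algebra on the spec records; the
event-driven propagation lives in :mod:`hydropulse.waveguide`.
"""

from __future__ import annotations

import math

import numpy as np

from .specs import FluidSpec, ProjectileSpec, SourcePulse, TubeSpec

__all__ = [
    "fluid_sound_speed",
    "acoustic_impedance",
    "joukowsky_peak",
    "joukowsky_peak_exact",
    "decay_time_constant",
    "pressure_waveform",
    "coupling_beta",
    "korteweg_celerity",
    "general_celerity",
    "tube_bar_speed",
    "hoop_strain_from_pressure",
    "pressure_from_hoop_strain",
    "axial_strain_from_hoop",
    "source_pulse_for",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def fluid_sound_speed(fluid: FluidSpec) -> float:
    """Acoustic speed in the unconfined fluid, c0 = sqrt(K_f / rho_f) [m/s]."""
    return fluid.sound_speed


def acoustic_impedance(density: float, speed: float) -> float:
    """Characteristic impedance rho * c [Pa s/m]."""
    _require_positive(density=density, speed=speed)
    return density * speed


def joukowsky_peak_exact(fluid_impedance: float, projectile_impedance: float, velocity: float) -> float:
    """Peak water-hammer pressure for a finite-impedance striker [Pa].

    P(0) = Zf Zp / (Zf + Zp) * V0 — the series combination of the two
    characteristic impedances.  Always below the rigid-striker limit
    :func:`joukowsky_peak` because part of the momentum stays in the
    projectile.
    """
    _require_positive(
        fluid_impedance=fluid_impedance,
        projectile_impedance=projectile_impedance,
        velocity=velocity,
    )
    zf, zp = fluid_impedance, projectile_impedance
    return zf * zp / (zf + zp) * velocity


def joukowsky_peak(fluid_impedance: float, velocity: float) -> float:
    """Rigid-striker Joukowsky peak, P(0) = Zf V0 [Pa].

    Valid when the projectile impedance dwarfs the fluid impedance
    (steel on water: Zp/Zf ~ 26).
    """
    _require_positive(fluid_impedance=fluid_impedance)
    if velocity < 0:
        raise ValueError(f"velocity must be non-negative, got {velocity!r}")
    return fluid_impedance * velocity


def decay_time_constant(projectile: ProjectileSpec, fluid_impedance: float) -> float:
    """Exponential decay constant theta = rho_p L_p / Zf [s].

    Taylor-type fluid-structure impact decay: the striker decelerates
    against the fluid's acoustic resistance, so its areal mass divided by
    the fluid impedance sets the e-folding time of the transmitted pulse.
    """
    _require_positive(fluid_impedance=fluid_impedance)
    return projectile.areal_mass / fluid_impedance


def pressure_waveform(pulse: SourcePulse, times) -> np.ndarray:
    """Sample the step-then-exponential pulse at `times` [Pa]."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    return pulse.evaluate(t)


def coupling_beta(fluid: FluidSpec, tube: TubeSpec) -> float:
    """Dimensionless fluid-structure coupling parameter.

    beta = (c0^2/c_s^2)(rho_f/rho_s)(2R/h).  beta -> 0 recovers a rigid
    tube; large beta means the wall's hoop compliance dominates the
    fluid's own compressibility.
    """
    c0 = fluid.sound_speed
    cs = tube.bar_speed
    return (c0**2 / cs**2) * (fluid.density / tube.wall_density) * (2.0 * tube.mean_radius / tube.wall_thickness)


def korteweg_celerity(fluid: FluidSpec, tube: TubeSpec) -> float:
    """Moens-Korteweg pressure-wave celerity in the elastic tube [m/s].

    c_f = c0 / sqrt(1 + beta).  Equals :func:`general_celerity` evaluated
    with the thin-wall compliance 2R/(E_s h), and the Korteweg form
    1/c_f^2 = 1/c0^2 + rho_f 2R/(E_s h); never exceeds c0.
    """
    return fluid.sound_speed / math.sqrt(1.0 + coupling_beta(fluid, tube))


def general_celerity(fluid: FluidSpec, normalized_compliance: float) -> float:
    """Pressure-wave celerity for an arbitrary conduit compliance [m/s].

    c_f = 1 / sqrt(rho_f (1/K_f + (1/A) dA/dP)).  Zero compliance gives
    back the free-fluid sound speed.
    """
    if normalized_compliance < 0:
        raise ValueError(f"normalized_compliance must be >= 0, got {normalized_compliance!r}")
    return 1.0 / math.sqrt(fluid.density * (1.0 / fluid.bulk_modulus + normalized_compliance))


def tube_bar_speed(tube: TubeSpec) -> float:
    """Axial bar-wave speed of the wall, c_s = sqrt(E_s / rho_s) [m/s].

    The Poisson-coupled axial precursor travels at this speed, well ahead
    of the fluid-borne pressure wave.
    """
    return tube.bar_speed


def hoop_strain_from_pressure(pressure: float, tube: TubeSpec) -> float:
    """Thin-wall hoop strain produced by internal pressure: P R / (E_s h)."""
    return pressure * tube.strain_coefficient


def pressure_from_hoop_strain(strain: float, tube: TubeSpec) -> float:
    """Internal pressure inferred from hoop strain: eps E_s h / R [Pa]."""
    return strain / tube.strain_coefficient


def axial_strain_from_hoop(hoop_strain: float, poisson_ratio: float) -> float:
    """Axial precursor strain accompanying a hoop strain: -nu * eps_hoop."""
    if not 0 < poisson_ratio < 0.5:
        raise ValueError(f"poisson_ratio must lie in (0, 0.5), got {poisson_ratio!r}")
    return -poisson_ratio * hoop_strain


def source_pulse_for(
    fluid: FluidSpec,
    tube: TubeSpec,
    projectile: ProjectileSpec,
    *,
    onset_time: float = 0.0,
) -> SourcePulse:
    """Predicted source pulse for an impact on the confined fluid column.

    The peak uses the rigid-striker Joukowsky relation with the
    FSI-corrected celerity (P0 = rho_f c_f V0); the decay constant divides
    the projectile areal mass by the same effective impedance.
    """
    zf = fluid.density * korteweg_celerity(fluid, tube)
    return SourcePulse(
        peak_pressure=joukowsky_peak(zf, projectile.velocity),
        decay_constant=decay_time_constant(projectile, zf),
        onset_time=onset_time,
    )
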