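"""Inverse design of loading experiments.

Given a requested peak pressure or pulse duration, solve the closed-form
water-hammer relations backwards for the projectile velocity or length,
and collect the platform's operating checks (membrane impedance match,
pulse-vs-column superposition, gauge timing predictions) into one report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from . import physics
from .specs import FluidSpec, MembraneSpec, ProjectileSpec, TubeSpec

__all__ = [
    "required_velocity",
    "required_projectile_length",
    "superposition_check",
    "SuperpositionCheck",
    "membrane_match_report",
    "MembraneMatch",
    "design_report",
    "DesignReport",
]


def required_velocity(target_peak: float, fluid: FluidSpec, tube: TubeSpec) -> float:
    """Impact velocity producing `target_peak` [Pa] in the confined column.

    Inverts the rigid-striker Joukowsky relation with the FSI-corrected
    celerity: V0 = P / (rho_f c_f).
    """
    if target_peak < 0:
        raise ValueError("target_peak must be >= 0")
    return target_peak / (fluid.density * physics.korteweg_celerity(fluid, tube))


def required_projectile_length(target_theta: float, projectile_density: float, fluid_impedance: float) -> float:
    """Projectile length giving decay constant `target_theta` [s]: L_p = theta Zf / rho_p."""
    if target_theta < 0:
        raise ValueError("target_theta must be >= 0")
    if projectile_density <= 0 or fluid_impedance <= 0:
        raise ValueError("density and impedance must be positive")
    return target_theta * fluid_impedance / projectile_density


@dataclass(frozen=True)
class SuperpositionCheck:
    """Advisory comparison of the pulse's spatial extent with the cell column.

    extent is the 95%-decay length 3 theta c_f.  The flag is advisory:
    short columns with long pulses still load cells, but incident and
    reflected portions of the waveform then overlap inside the column.
    Also reported is the projectile-internal round-trip time 2 L_p / c_p,
    the timescale on which release waves inside the striker shape the
    pulse.
    """

    ok: bool
    extent: float
    margin: float
    column_length: float


def superposition_check(theta: float, celerity: float, cell_column_length: float) -> SuperpositionCheck:
    if theta <= 0 or celerity <= 0 or cell_column_length <= 0:
        raise ValueError("inputs must be positive")
    extent = 3.0 * theta * celerity
    return SuperpositionCheck(
        ok=extent <= cell_column_length,
        extent=extent,
        margin=cell_column_length - extent,
        column_length=cell_column_length,
    )


@dataclass(frozen=True)
class MembraneMatch:
    reflection_percent: float
    ok: bool


def membrane_match_report(fluid: FluidSpec, membrane: MembraneSpec, *, bound_percent: float = 10.0) -> MembraneMatch:
    """Pressure reflection (%) at the medium/membrane interface.

    100 |Zm - Zf| / (Zm + Zf); flagged ok when below `bound_percent`.
    """
    zf, zm = fluid.impedance, membrane.impedance
    pct = 100.0 * abs(zm - zf) / (zm + zf)
    return MembraneMatch(reflection_percent=pct, ok=pct < bound_percent)


@dataclass(frozen=True)
class DesignReport:
    """All design-level predictions for one experiment configuration.

    Velocities in m/s, pressures in MPa, times in us, lengths in m —
    the display units of the bench.
    """

    required_velocity_m_s: float
    predicted_peak_mpa: float
    decay_constant_us: float
    pulse_extent_m: float
    superposition_ok: bool
    superposition_margin_m: float
    projectile_round_trip_us: float
    membrane_reflection_percent: float
    membrane_ok: bool
    fluid_sound_speed_m_s: float
    korteweg_celerity_m_s: float
    tube_bar_speed_m_s: float
    gauge_separation_m: float | None
    flexural_lag_us: float | None
    precursor_lag_us: float | None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "DesignReport":
        return cls(**json.loads(text))

    def summary(self) -> str:
        fmt = [
            "Experiment design report",
            f"  required velocity     : {self.required_velocity_m_s:.4g} m/s",
            f"  predicted peak        : {self.predicted_peak_mpa:.4g} MPa",
            f"  decay constant theta  : {self.decay_constant_us:.4g} us",
            f"  pulse extent (3 theta): {self.pulse_extent_m:.4g} m "
            f"({'fits' if self.superposition_ok else 'exceeds'} the cell column)",
            f"  projectile round trip : {self.projectile_round_trip_us:.4g} us",
            f"  membrane reflection   : {self.membrane_reflection_percent:.3g} % "
            f"({'ok' if self.membrane_ok else 'NOT ok'})",
            f"  celerities            : c0={self.fluid_sound_speed_m_s:.5g}, "
            f"cf={self.korteweg_celerity_m_s:.5g}, cs={self.tube_bar_speed_m_s:.5g} m/s",
        ]
        if self.gauge_separation_m is not None:
            fmt.append(
                f"  gauge pair ({self.gauge_separation_m * 1e3:.4g} mm): flexural lag "
                f"{self.flexural_lag_us:.4g} us, precursor lag {self.precursor_lag_us:.4g} us"
            )
        return "\n".join(fmt)


def design_report(
    fluid: FluidSpec,
    tube: TubeSpec,
    projectile: ProjectileSpec,
    membrane: MembraneSpec,
    *,
    target_peak: float | None = None,
    cell_column_length: float = 0.12,
    gauge_separation: float | None = None,
) -> DesignReport:
    """Aggregate every design prediction for one configuration.

    If `target_peak` [Pa] is given, the required velocity is solved for;
    otherwise the projectile's own velocity is used and the predicted peak
    follows from it.  Every number equals the corresponding single
    operation applied to the same specs.
    """
    cf = physics.korteweg_celerity(fluid, tube)
    zf_eff = fluid.density * cf
    if target_peak is not None:
        v0 = required_velocity(target_peak, fluid, tube)
        peak = float(target_peak)
    else:
        v0 = projectile.velocity
        peak = physics.joukowsky_peak(zf_eff, v0)
    theta = physics.decay_time_constant(projectile, zf_eff)
    sup = superposition_check(theta, cf, cell_column_length)
    mem = membrane_match_report(fluid, membrane)
    cs = physics.tube_bar_speed(tube)
    return DesignReport(
        required_velocity_m_s=v0,
        predicted_peak_mpa=peak / 1e6,
        decay_constant_us=theta * 1e6,
        pulse_extent_m=sup.extent,
        superposition_ok=sup.ok,
        superposition_margin_m=sup.margin,
        projectile_round_trip_us=2.0 * projectile.length / projectile.bar_speed * 1e6,
        membrane_reflection_percent=mem.reflection_percent,
        membrane_ok=mem.ok,
        fluid_sound_speed_m_s=fluid.sound_speed,
        korteweg_celerity_m_s=cf,
        tube_bar_speed_m_s=cs,
        gauge_separation_m=gauge_separation,
        flexural_lag_us=None if gauge_separation is None else gauge_separation / cf * 1e6,
        precursor_lag_us=None if gauge_separation is None else gauge_separation / cs * 1e6,
    )
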