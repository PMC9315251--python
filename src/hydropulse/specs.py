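"""Material, geometry, and source-pulse records for the loading platform.

All fields are SI (kg/m^3, Pa, m, s, m/s).  Derived quantities that are
pure functions of one record (sound speed, acoustic impedance, thin-wall
compliance, ...) are exposed as properties so that every closed-form
expression in :mod:`hydropulse.physics` reads like the textbook formula.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FluidSpec",
    "TubeSpec",
    "ProjectileSpec",
    "MembraneSpec",
    "SourcePulse",
    "WATER",
    "STEEL_TUBE",
    "STEEL_PROJECTILE",
    "NBR_MEMBRANE",
]


class _Spec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class FluidSpec(_Spec):
    """Compressible working fluid (cell culture medium ~ water)."""

    density: float = Field(gt=0, description="mass density rho_f [kg/m^3]")
    bulk_modulus: float = Field(gt=0, description="bulk modulus K_f [Pa]")

    @property
    def sound_speed(self) -> float:
        """Free-fluid acoustic speed c0 = sqrt(K_f / rho_f) [m/s]."""
        return math.sqrt(self.bulk_modulus / self.density)

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho_f * c0 [Pa s/m]."""
        return self.density * self.sound_speed


class TubeSpec(_Spec):
    """Thin-walled elastic cell tube confining the fluid column."""

    mean_radius: float = Field(gt=0, description="mean radius R [m]")
    wall_thickness: float = Field(gt=0, description="wall thickness h [m]")
    length: float = Field(gt=0, description="tube length L [m]")
    wall_modulus: float = Field(gt=0, description="wall Young's modulus E_s [Pa]")
    wall_density: float = Field(gt=0, description="wall density rho_s [kg/m^3]")
    poisson_ratio: float = Field(gt=0, lt=0.5, description="wall Poisson ratio nu")

    @model_validator(mode="after")
    def _thin_wall(self) -> "TubeSpec":
        if self.wall_thickness >= self.mean_radius:
            raise ValueError(
                "thin-wall regime requires wall_thickness < mean_radius "
                f"(got h={self.wall_thickness}, R={self.mean_radius})"
            )
        return self

    @property
    def bar_speed(self) -> float:
        """Axial (bar) wave speed of the wall, c_s = sqrt(E_s / rho_s) [m/s]."""
        return math.sqrt(self.wall_modulus / self.wall_density)

    @property
    def cross_section_area(self) -> float:
        return math.pi * self.mean_radius**2

    @property
    def normalized_compliance(self) -> float:
        """(1/A) dA/dP = 2R / (E_s h) for a thin elastic ring [1/Pa]."""
        return 2.0 * self.mean_radius / (self.wall_modulus * self.wall_thickness)

    @property
    def strain_coefficient(self) -> float:
        """Hoop strain per unit internal pressure, R / (E_s h) [1/Pa]."""
        return self.mean_radius / (self.wall_modulus * self.wall_thickness)


class ProjectileSpec(_Spec):
    """Striker launched by the gas gun onto the fluid column."""

    density: float = Field(gt=0, description="rho_p [kg/m^3]")
    bar_speed: float = Field(gt=0, description="bar wave speed c_p [m/s]")
    length: float = Field(gt=0, description="projectile length L_p [m]")
    velocity: float = Field(gt=0, description="impact velocity V0 [m/s]")

    @property
    def impedance(self) -> float:
        return self.density * self.bar_speed

    @property
    def areal_mass(self) -> float:
        """Mass per unit cross-section area, rho_p * L_p [kg/m^2]."""
        return self.density * self.length


class MembraneSpec(_Spec):
    """Thin diaphragm separating sterile medium from the extension column."""

    density: float = Field(gt=0, description="rho_m [kg/m^3]")
    sound_speed: float = Field(gt=0, description="c_m [m/s]")
    thickness: float = Field(gt=0, description="membrane thickness [m]")

    @property
    def impedance(self) -> float:
        return self.density * self.sound_speed


class SourcePulse(_Spec):
    """Instantaneous-rise, exponential-decay pressure pulse.

    P(t) = P0 * exp(-(t - t0) / theta)  for t >= t0,  0 before.

    The time integral (impulse per unit area) is P0 * theta.
    """

    peak_pressure: float = Field(gt=0, description="P0 [Pa]")
    decay_constant: float = Field(gt=0, description="theta [s]")
    onset_time: float = Field(default=0.0, description="t0 [s]")

    def evaluate(self, times, *, shift: float = 0.0):
        """Pressure at `times` for a copy of the pulse delayed by `shift` [Pa]."""
        import numpy as np

        t = np.asarray(times, dtype=float)
        dt0 = t - (self.onset_time + shift)
        out = np.where(dt0 >= 0.0, self.peak_pressure * np.exp(-np.maximum(dt0, 0.0) / self.decay_constant), 0.0)
        return out


# Default materials: handbook water, steel, and nitrile rubber.
WATER = FluidSpec(density=1000.0, bulk_modulus=2.24e9)

STEEL_TUBE = TubeSpec(
    mean_radius=6e-3,
    wall_thickness=0.25e-3,
    length=0.14,
    wall_modulus=196e9,
    wall_density=7850.0,
    poisson_ratio=0.3,
)

STEEL_PROJECTILE = ProjectileSpec(
    density=7850.0,
    bar_speed=4996.8,
    length=0.025,
    velocity=11.24,
)

NBR_MEMBRANE = MembraneSpec(density=1000.0, sound_speed=1600.0, thickness=0.5e-3)
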