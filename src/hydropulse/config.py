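"""Experiment configuration: parsing, validation, defaults, waveguide assembly.

A configuration file (YAML or JSON) describes one bench setup: fluid,
tube, projectile, membrane, extension column, sensors, and simulation
controls.  Unknown keys are rejected; omitted sections fall back to the
bench defaults (water / steel tube / 25-mm steel striker / NBR membrane)
and every defaulted section is logged so a run's provenance is explicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import physics
from .specs import (
    NBR_MEMBRANE,
    STEEL_PROJECTILE,
    STEEL_TUBE,
    WATER,
    FluidSpec,
    MembraneSpec,
    ProjectileSpec,
    SourcePulse,
    TubeSpec,
)
from .waveguide import Segment, Sensor, Waveguide

__all__ = ["SimulationControls", "SensorConfig", "ExperimentConfig", "load_config"]

logger = logging.getLogger("hydropulse")


class SimulationControls(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dt: float = Field(default=1e-7, gt=0, description="sampling interval [s]")
    t_end: float = Field(default=2e-3, gt=0, description="record length [s]")
    amplitude_cutoff: float = Field(default=1e-3, gt=0, lt=1)


class SensorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["pressure", "hoop_strain", "axial_strain"]
    position: float = Field(ge=0, description="axial position from the impact end [m]")
    id: str


class ExperimentConfig(BaseModel):
    """Full description of one loading experiment."""

    model_config = ConfigDict(extra="forbid")

    fluid: FluidSpec = WATER
    tube: TubeSpec = STEEL_TUBE
    projectile: ProjectileSpec = STEEL_PROJECTILE
    membrane: MembraneSpec = NBR_MEMBRANE
    cell_column_length: float = Field(default=0.12, gt=0)
    extension_length: float = Field(default=0.12, gt=0)
    sensors: list[SensorConfig] = Field(
        default_factory=lambda: [
            SensorConfig(kind="hoop_strain", position=0.0159, id="g1"),
            SensorConfig(kind="hoop_strain", position=0.07476, id="g2"),
        ]
    )
    simulation: SimulationControls = SimulationControls()
    seed: int = 0

    def source_pulse(self) -> SourcePulse:
        return physics.source_pulse_for(self.fluid, self.tube, self.projectile)

    def sensor_objects(self) -> list[Sensor]:
        return [Sensor(kind=s.kind, position=s.position, id=s.id) for s in self.sensors]

    def _fluid_segment(self, length: float, *, instrumented: bool, name: str) -> Segment:
        # Celerity is the FSI-corrected Moens-Korteweg speed; reflection
        # impedance is the free-fluid rho*c0 (the membrane-match criterion
        # the bench uses).
        return Segment(
            length=length,
            celerity=physics.korteweg_celerity(self.fluid, self.tube),
            impedance=self.fluid.impedance,
            strain_coefficient=self.tube.strain_coefficient if instrumented else 0.0,
            name=name,
        )

    def cell_waveguide(self) -> Waveguide:
        """Cell-loading stack: medium column / NBR membrane / extension column.

        The extension column ends in an anechoic termination (its far end
        is open and long enough that its echo is outside the window of
        interest).
        """
        return Waveguide(
            segments=(
                self._fluid_segment(self.cell_column_length, instrumented=True, name="cell_medium"),
                Segment(
                    length=self.membrane.thickness,
                    celerity=self.membrane.sound_speed,
                    impedance=self.membrane.impedance,
                    name="membrane",
                ),
                self._fluid_segment(self.extension_length, instrumented=False, name="extension"),
            ),
            far_boundary="anechoic",
            source_boundary="anechoic",
            tube_bar_speed=self.tube.bar_speed,
            poisson_ratio=self.tube.poisson_ratio,
        )

    def transducer_waveguide(self) -> Waveguide:
        """Calibration stack: one fluid column closed by the rigid pressure
        transducer at the far end (recorded peak is twice the free-field peak)."""
        return Waveguide(
            segments=(self._fluid_segment(self.cell_column_length, instrumented=True, name="cell_medium"),),
            far_boundary="rigid",
            source_boundary="anechoic",
            tube_bar_speed=self.tube.bar_speed,
            poisson_ratio=self.tube.poisson_ratio,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration.

    Missing sections take bench defaults; each defaulted section is
    logged, along with the config hash, for provenance.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    cfg = ExperimentConfig.model_validate(data)
    defaulted = [name for name in ExperimentConfig.model_fields if name not in data]
    if defaulted:
        logger.info("config %s: defaults applied for %s", path, ", ".join(defaulted))
    logger.info("config %s: hash %s", path, cfg.config_hash())
    return cfg
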