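"""Event-driven 1-D linear acoustic simulation of the loading tube.

The tube is a chain of acoustic segments (cell-medium column, NBR
membrane, extension column).  Because the system is linear and each
material interface is a point scatterer, the field is an exact
superposition of scaled, time-shifted copies of the source pulse: every
wavefront that hits an interface spawns one reflected and one transmitted
descendant with the classical pressure coefficients

    R_p = (Z2 - Z1) / (Z1 + Z2),    T_p = 2 Z2 / (Z1 + Z2),

so no spatial discretization is needed and sensor traces are assembled
analytically at any sampling rate.  Wavefronts are retired when their
amplitude falls below a cutoff fraction of the source peak or when they
can no longer reach the time window.

Hoop-strain gauges read local pressure times the segment's strain
coefficient.  The weak axial precursor is modeled one-way: a -nu-scaled
copy of the hoop waveform whose arrival is set by the wall bar speed
rather than the fluid celerity (the pressure perturbation it carries is
negligible, so it does not feed back into the fluid).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .specs import SourcePulse

__all__ = [
    "Segment",
    "Sensor",
    "Trace",
    "Waveguide",
    "interface_coefficients",
    "simulate",
    "reflected_fraction",
    "make_noisy_traces",
]

BoundaryKind = Literal["rigid", "anechoic"]
SensorKind = Literal["pressure", "hoop_strain", "axial_strain"]


@dataclass(frozen=True)
class Segment:
    """Homogeneous acoustic stretch of the waveguide.

    strain_coefficient is hoop strain per Pa of local pressure; zero for
    stretches without an instrumented elastic wall (e.g. the membrane).
    """

    length: float
    celerity: float
    impedance: float
    strain_coefficient: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0 or self.celerity <= 0 or self.impedance <= 0:
            raise ValueError("segment length, celerity and impedance must be positive")
        if self.strain_coefficient < 0:
            raise ValueError("strain_coefficient must be >= 0")


@dataclass(frozen=True)
class Sensor:
    """Virtual gauge at a fixed axial position (measured from the source end)."""

    kind: SensorKind
    position: float
    id: str


@dataclass
class Trace:
    """Uniformly sampled sensor time series."""

    sensor_id: str
    dt: float
    start_time: float
    values: np.ndarray
    kind: SensorKind = "pressure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.values.size)

    @property
    def units(self) -> str:
        return "Pa" if self.kind == "pressure" else "strain"


@dataclass(frozen=True)
class Waveguide:
    """Ordered acoustic segments from the impact end to the far end."""

    segments: tuple[Segment, ...]
    # The impact end is anechoic by default: the source pulse already
    # carries the full striker momentum exchange, so re-reflecting echoes
    # off the striker face would double-count it.
    far_boundary: BoundaryKind = "anechoic"
    source_boundary: BoundaryKind = "anechoic"
    tube_bar_speed: float = 4996.8
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("waveguide needs at least one segment")

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Axial positions of segment edges, source end at 0."""
        return np.concatenate([[0.0], np.cumsum([s.length for s in self.segments])])

    def segment_index(self, position: float) -> int:
        """Index of the segment containing `position` (edges go to the left segment
        except position 0)."""
        if not 0 <= position <= self.total_length * (1 + 1e-12):
            raise ValueError(f"position {position} outside waveguide [0, {self.total_length}]")
        edges = self.boundaries
        idx = int(np.searchsorted(edges, position, side="left")) - 1
        return min(max(idx, 0), len(self.segments) - 1)


def interface_coefficients(z1: float, z2: float) -> tuple[float, float]:
    """Pressure reflection and transmission coefficients for Z1 -> Z2 incidence.

    Satisfies 1 + R_p = T_p identically (pressure continuity).
    """
    if z1 <= 0 or z2 <= 0:
        raise ValueError("impedances must be positive")
    rp = (z2 - z1) / (z1 + z2)
    tp = 1.0 + rp  # 2 Z2/(Z1+Z2), written so pressure continuity is exact in floats
    return rp, tp


@dataclass(frozen=True)
class _Passage:
    """One wavefront sweeping past a fixed axial station."""

    time: float
    scale: float
    n_reflections: int


def _trace_passages(
    guide: Waveguide,
    positions: Sequence[float],
    t_end: float,
    amplitude_cutoff: float,
    onset_time: float,
) -> list[list[_Passage]]:
    """Enumerate every wavefront passage over each station up to t_end.

    Scales are relative to the source peak (the seed front has scale 1).
    Simultaneous interface hits are processed in FIFO creation order;
    superposition makes the summed field independent of that order.
    """
    edges = guide.boundaries
    segs = guide.segments
    nseg = len(segs)
    per_station: list[list[_Passage]] = [[] for _ in positions]
    station_seg = [guide.segment_index(p) for p in positions]

    # (scale, segment index, direction, clock time at the entry boundary, reflections so far)
    queue: deque[tuple[float, int, int, float, int]] = deque()
    queue.append((1.0, 0, +1, onset_time, 0))

    while queue:
        scale, si, direction, t_entry, nref = queue.popleft()
        if abs(scale) < amplitude_cutoff or t_entry > t_end:
            continue
        seg = segs[si]
        transit = seg.length / seg.celerity
        t_exit = t_entry + transit
        x_left, x_right = edges[si], edges[si + 1]

        for k, x in enumerate(positions):
            if station_seg[k] != si:
                continue
            dist = (x - x_left) if direction > 0 else (x_right - x)
            t_pass = t_entry + dist / seg.celerity
            if t_pass <= t_end:
                per_station[k].append(_Passage(t_pass, scale, nref))

        if direction > 0:
            if si == nseg - 1:  # far end
                if guide.far_boundary == "rigid":
                    queue.append((scale, si, -1, t_exit, nref + 1))
            else:
                rp, tp = interface_coefficients(seg.impedance, segs[si + 1].impedance)
                queue.append((scale * tp, si + 1, +1, t_exit, nref))
                queue.append((scale * rp, si, -1, t_exit, nref + 1))
        else:
            if si == 0:  # source end
                if guide.source_boundary == "rigid":
                    queue.append((scale, si, +1, t_exit, nref + 1))
            else:
                rp, tp = interface_coefficients(seg.impedance, segs[si - 1].impedance)
                queue.append((scale * tp, si - 1, -1, t_exit, nref))
                queue.append((scale * rp, si, +1, t_exit, nref + 1))

    for lst in per_station:
        lst.sort(key=lambda p: p.time)
    return per_station


def _synth(pulse: SourcePulse, passages: Sequence[_Passage], times: np.ndarray) -> np.ndarray:
    out = np.zeros_like(times)
    for p in passages:
        out += p.scale * pulse.evaluate(times, shift=p.time - pulse.onset_time)
    return out


def simulate(
    guide: Waveguide,
    pulse: SourcePulse,
    sensors: Sequence[Sensor],
    *,
    t_end: float = 2e-3,
    dt: float = 1e-7,
    amplitude_cutoff: float = 1e-3,
) -> list[Trace]:
    """Propagate one pulse through the waveguide and sample the sensors.

    Parameters
    ----------
    t_end, dt : float
        Record length and sampling interval [s].
    amplitude_cutoff : float
        Wavefronts below this fraction of the source peak are retired.

    Returns
    -------
    list of Trace, one per sensor, all starting at the pulse onset time.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    if not 0 < amplitude_cutoff < 1:
        raise ValueError("amplitude_cutoff must lie in (0, 1)")
    if dt > pulse.decay_constant / 10:
        warnings.warn(
            f"dt={dt} undersamples the pulse (theta={pulse.decay_constant}); "
            "expect peak clipping",
            stacklevel=2,
        )
    for s in sensors:
        guide.segment_index(s.position)  # raises if outside

    times = pulse.onset_time + dt * np.arange(int(round(t_end / dt)) + 1)
    passages = _trace_passages(
        guide, [s.position for s in sensors], pulse.onset_time + t_end, amplitude_cutoff, pulse.onset_time
    )

    traces: list[Trace] = []
    for sensor, plist in zip(sensors, passages):
        pressure = _synth(pulse, plist, times)
        seg = guide.segments[guide.segment_index(sensor.position)]
        if sensor.kind == "pressure":
            values = pressure
        elif sensor.kind == "hoop_strain":
            values = pressure * seg.strain_coefficient
        elif sensor.kind == "axial_strain":
            # One-way precursor model: the hoop waveform, scaled by -nu,
            # advanced so its first arrival rides the wall bar wave.
            if not plist:
                values = np.zeros_like(times)
            else:
                t_fluid = min(p.time for p in plist)
                t_bar = pulse.onset_time + sensor.position / guide.tube_bar_speed
                shifted = _synth(pulse, plist, times + (t_fluid - t_bar))
                values = -guide.poisson_ratio * seg.strain_coefficient * shifted
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown sensor kind {sensor.kind!r}")
        traces.append(Trace(sensor.id, dt, times[0], values, kind=sensor.kind))
    return traces


def reflected_fraction(
    guide: Waveguide,
    pulse: SourcePulse,
    gauge_position: float,
    *,
    t_end: float = 2e-3,
    amplitude_cutoff: float = 1e-4,
) -> float:
    """Peak of the first reflected arrival at the gauge as % of the primary peak.

    Arrival amplitudes are taken from the event list, so the figure is the
    clean per-arrival ratio even when the reflection rides on the tail of
    the primary pulse.
    """
    if len(guide.segments) < 2:
        raise ValueError("reflected_fraction needs a waveguide with >= 2 segments")
    (plist,) = _trace_passages(
        guide, [gauge_position], pulse.onset_time + t_end, amplitude_cutoff, pulse.onset_time
    )
    primary = next((p for p in plist if p.n_reflections == 0), None)
    echo = next((p for p in plist if p.n_reflections >= 1), None)
    if primary is None:
        raise ValueError("primary wave never reached the gauge within t_end")
    if echo is None:
        mismatched = any(
            abs(interface_coefficients(a.impedance, b.impedance)[0]) >= amplitude_cutoff
            for a, b in zip(guide.segments, guide.segments[1:])
        )
        if not mismatched:
            return 0.0  # impedance-matched stack: nothing comes back
        raise ValueError("no reflected arrival reached the gauge within t_end")
    return 100.0 * abs(echo.scale) / abs(primary.scale)


def make_noisy_traces(
    guide: Waveguide,
    pulse: SourcePulse,
    sensors: Sequence[Sensor],
    *,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_end: float = 2e-3,
    dt: float = 1e-7,
    amplitude_cutoff: float = 1e-3,
) -> list[Trace]:
    """Simulated traces plus i.i.d. Gaussian noise (test-fixture generator).

    noise_sd is expressed as a fraction of each trace's own peak absolute
    value, so pressure and strain channels get comparable signal-to-noise.
    Identical seeds give bitwise-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traces = simulate(guide, pulse, sensors, t_end=t_end, dt=dt, amplitude_cutoff=amplitude_cutoff)
    if noise_sd == 0:
        return traces
    rng = np.random.default_rng(seed)
    for tr in traces:
        peak = float(np.max(np.abs(tr.values)))
        tr.values = tr.values + rng.normal(0.0, noise_sd * peak, size=tr.values.shape)
    return traces
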