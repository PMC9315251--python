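"""Gauge-trace analysis: arrival picking, two-gauge celerity, strain calibration.

The platform is validated by (i) timing the pressure wave between two
hoop-strain gauges a known distance apart and comparing the speed with
the Moens-Korteweg prediction, and (ii) regressing peak pressure on peak
hoop strain across shots at several projectile velocities, which yields
the device's strain-to-pressure conversion.  The regression is exposed
statsmodels-style: build a :class:`StrainPressureCalibration` from the
per-shot peaks, call :meth:`~StrainPressureCalibration.fit`, and read the
estimates off the returned :class:`CalibrationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal

from .waveguide import Trace

__all__ = [
    "peak_amplitude",
    "detect_arrival",
    "estimate_celerity",
    "CelerityEstimate",
    "StrainPressureCalibration",
    "CalibrationResult",
    "fit_pressure_strain",
    "strain_trace_to_pressure",
]

CelerityMethod = Literal["threshold", "cross_correlation"]


def peak_amplitude(trace: Trace, smooth_window: int = 1) -> float:
    """Peak value of a trace, optionally after a moving-average smooth.

    Picking the raw maximum of a noisy record biases the peak upward (it is
    a maximum over many noise draws); a short moving average — a few
    samples, well under the pulse decay time — removes most of that bias
    at the cost of slightly clipping the true peak.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    v = trace.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kernel, mode="valid")
    return float(np.max(v))


def detect_arrival(trace: Trace, threshold_fraction: float = 0.1) -> float:
    """First sample time at which the trace reaches a fraction of its peak.

    Simple level-crossing picker suited to instantaneous-rise pulses.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    peak = float(np.max(trace.values))
    if peak <= 0:
        raise ValueError("trace has no positive peak; cannot detect an arrival")
    idx = np.nonzero(trace.values >= threshold_fraction * peak)[0]
    return float(trace.times[idx[0]])


@dataclass(frozen=True)
class CelerityEstimate:
    """Wave speed inferred from a gauge pair."""

    speed: float
    lag: float
    method: CelerityMethod
    separation: float


def _xcorr_lag(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Lag (s) by which `b` trails `a`, from the cross-correlation argmax."""
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(b.size, a.size, mode="full")
    return float(lags[int(np.argmax(corr))]) * dt


def estimate_celerity(
    trace_a: Trace,
    trace_b: Trace,
    separation: float,
    method: CelerityMethod = "cross_correlation",
    threshold_fraction: float = 0.1,
) -> CelerityEstimate:
    """Wave celerity from the time lag between two gauges.

    `trace_a` is the gauge nearer the source.  A non-positive lag (the
    wave apparently reaching the far gauge first) raises, since it means
    the gauge order or separation sign is inconsistent.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if abs(trace_a.dt - trace_b.dt) > 1e-15:
        raise ValueError("traces must share the same sampling interval")
    if method == "threshold":
        lag = detect_arrival(trace_b, threshold_fraction) - detect_arrival(trace_a, threshold_fraction)
    elif method == "cross_correlation":
        lag = _xcorr_lag(trace_a.values, trace_b.values, trace_a.dt) + (trace_b.start_time - trace_a.start_time)
    else:
        raise ValueError(f"unknown method {method!r}")
    if lag <= 0:
        raise ValueError(f"non-positive lag ({lag} s): gauge order inconsistent with propagation")
    return CelerityEstimate(speed=separation / lag, lag=lag, method=method, separation=separation)


@dataclass(frozen=True)
class CalibrationResult:
    """OLS max-pressure vs max-hoop-strain calibration.

    slope/intercept are in MPa per m-strain and MPa when the inputs use
    those units (the fit itself is unit-agnostic).  `slope_through_origin`
    is the companion zero-intercept fit, reported alongside because the
    physical line P = (E_s h / R) eps passes through the origin.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: np.ndarray
    slope_se: float
    intercept_se: float
    slope_through_origin: float
    r_squared_through_origin: float

    def predict(self, strains) -> np.ndarray:
        return self.slope * np.asarray(strains, dtype=float) + self.intercept

    def summary(self) -> str:
        lines = [
            "Strain-to-pressure calibration (OLS)",
            f"  n points            : {self.n_points}",
            f"  slope               : {self.slope:.6g} +/- {self.slope_se:.3g}",
            f"  intercept           : {self.intercept:.6g} +/- {self.intercept_se:.3g}",
            f"  R^2                 : {self.r_squared:.6f}",
            f"  slope (origin fit)  : {self.slope_through_origin:.6g}",
            f"  R^2  (origin fit)   : {self.r_squared_through_origin:.6f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "slope_through_origin": self.slope_through_origin,
            "r_squared_through_origin": self.r_squared_through_origin,
            "residuals": list(map(float, self.residuals)),
        }


@dataclass
class StrainPressureCalibration:
    """Per-shot peak pressures regressed on peak hoop strains.

    Parameters
    ----------
    max_pressures, max_strains : sequence of float
        One entry per shot; conventionally MPa and m-strain.
    """

    max_pressures: Sequence[float]
    max_strains: Sequence[float]
    _x: np.ndarray = field(init=False, repr=False)
    _y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.max_pressures, dtype=float)
        x = np.asarray(self.max_strains, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("max_pressures and max_strains must be equal-length 1-D sequences")
        if y.size < 2:
            raise ValueError("need at least two shots to calibrate")
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: all strains identical")
        self._x, self._y = x, y

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pressure: str = "max_pressure_mpa", strain: str = "max_strain_me"
    ) -> "StrainPressureCalibration":
        return cls(df[pressure].to_numpy(), df[strain].to_numpy())

    def fit(self) -> CalibrationResult:
        with_c = sm.OLS(self._y, sm.add_constant(self._x)).fit()
        origin = sm.OLS(self._y, self._x[:, None]).fit()
        return CalibrationResult(
            slope=float(with_c.params[1]),
            intercept=float(with_c.params[0]),
            r_squared=float(with_c.rsquared),
            n_points=int(self._y.size),
            residuals=np.asarray(with_c.resid, dtype=float),
            slope_se=float(with_c.bse[1]),
            intercept_se=float(with_c.bse[0]),
            slope_through_origin=float(origin.params[0]),
            r_squared_through_origin=float(origin.rsquared),
        )


def fit_pressure_strain(max_pressures: Sequence[float], max_strains: Sequence[float]) -> CalibrationResult:
    """Convenience wrapper: build the calibration model and fit it."""
    return StrainPressureCalibration(max_pressures, max_strains).fit()


def strain_trace_to_pressure(trace: Trace, slope: float, intercept: float = 0.0) -> Trace:
    """Affine per-sample conversion of a strain trace to pressure units.

    With slope in MPa per m-strain and the trace in strain, the output is
    in MPa; the function itself just applies slope*x + intercept.
    """
    if slope <= 0:
        raise ValueError("calibrated slope must be positive")
    return Trace(
        sensor_id=trace.sensor_id,
        dt=trace.dt,
        start_time=trace.start_time,
        values=slope * trace.values + intercept,
        kind="pressure",
    )
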