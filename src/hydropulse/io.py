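"""File formats: wide trace CSV, plate CSV, JSON reports.

Trace CSV layout: header ``time_s,<sensor_id_1>,<sensor_id_2>,...`` with
one row per sample.  Numbers are written with 9 significant digits —
enough to round-trip the physics stably while keeping diffs readable;
JSON reports keep full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .waveguide import Trace

__all__ = ["write_traces_csv", "read_traces_csv", "write_plate_csv", "read_plate_csv", "write_json_report"]

_CSV_FLOAT_FORMAT = "%.9g"


def write_traces_csv(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces sharing one time base to a wide CSV."""
    if not traces:
        raise ValueError("no traces to write")
    t0, dt, n = traces[0].start_time, traces[0].dt, traces[0].values.size
    for tr in traces[1:]:
        if tr.values.size != n or abs(tr.dt - dt) > 1e-18 or abs(tr.start_time - t0) > 1e-18:
            raise ValueError("all traces must share the same time base to share a CSV")
    df = pd.DataFrame({"time_s": traces[0].times})
    for tr in traces:
        df[tr.sensor_id] = tr.values
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_traces_csv(path: str | Path, kind: str = "pressure") -> list[Trace]:
    """Read a wide trace CSV back into Trace objects.

    The sampling interval is taken from the first time step; the file is
    required to be uniformly sampled to within 1 ppm of that step.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError("trace CSV needs a time_s column plus at least one sensor column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=0):
        raise ValueError("trace CSV is not uniformly sampled")
    return [
        Trace(sensor_id=c, dt=dt, start_time=float(t[0]), values=df[c].to_numpy(dtype=float), kind=kind)
        for c in df.columns
        if c != "time_s"
    ]


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
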