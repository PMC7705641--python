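"""Delimited-text I/O for waveforms.

Waveform files are CSV/TSV with a header row naming a ``time`` column (s)
plus ``pressure`` and optionally ``flow`` or ``velocity`` columns.  Units
travel in a JSON sidecar/config, e.g.::

    {"pressure_units": "mmHg", "flow_units": "mL/s", "dt": 0.001}

``dt`` may be omitted when a time column is present; nonuniform time stamps
are linearly resampled onto a uniform grid at ingest.  All indices in
machine output are 0-based; times are seconds.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .waveforms import BeatSegment, UniformSeries, WaveformError, resample_uniform

__all__ = ["read_waveforms", "write_waveforms", "read_sidecar", "atomic_write_json"]

_FLOW_QUANTITY = {"mL/s": "flow_volumetric", "ml/s": "flow_volumetric", "m/s": "flow_velocity"}


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise WaveformError("sidecar must be a JSON object")
    return cfg


def read_waveforms(
    path: str | Path, config: dict | None = None
) -> tuple[UniformSeries, UniformSeries | None]:
    """Read (pressure, flow-or-None) from a delimited text file.

    ``config`` mirrors the JSON sidecar: ``pressure_units`` (only "mmHg"
    supported), ``flow_units`` ("mL/s" or "m/s"), and ``dt`` in seconds if
    there is no time column.  A ``velocity`` column implies m/s.
    """
    config = dict(config or {})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "pressure" not in df.columns:
        raise WaveformError("waveform file needs a 'pressure' column")
    if config.get("pressure_units", "mmHg") != "mmHg":
        raise WaveformError("pressure must be in mmHg")

    flow_col = next((c for c in ("flow", "velocity") if c in df.columns), None)
    if "time" in df.columns:
        t = df["time"].to_numpy(dtype=float)
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise WaveformError("time column must be strictly increasing")
        dt = float(config.get("dt") or np.median(dts))
        uniform = np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12)
        if uniform:
            p = UniformSeries(float(t[0]), float(dts[0]), df["pressure"].to_numpy(float), "pressure")
        else:
            p = resample_uniform(t, df["pressure"].to_numpy(float), dt, "pressure")
    else:
        if "dt" not in config:
            raise WaveformError("no time column: sidecar must give dt")
        dt = float(config["dt"])
        p = UniformSeries(0.0, dt, df["pressure"].to_numpy(float), "pressure")
        t = p.times
        uniform = True

    flow = None
    if flow_col is not None:
        default_units = "m/s" if flow_col == "velocity" else "mL/s"
        units = config.get("flow_units", default_units)
        if units not in _FLOW_QUANTITY:
            raise WaveformError(f"unsupported flow units {units!r}")
        qty = _FLOW_QUANTITY[units]
        vals = df[flow_col].to_numpy(dtype=float)
        if uniform:
            flow = UniformSeries(p.t0, p.dt, vals, qty)
        else:
            flow = resample_uniform(t, vals, p.dt, qty)
    return p, flow


def write_waveforms(
    path: str | Path,
    pressure: UniformSeries,
    flow: UniformSeries | None = None,
    extra: dict[str, np.ndarray] | None = None,
) -> None:
    """Write time/pressure(/flow/extras) as CSV with 0-based uniform grid."""
    cols: dict[str, np.ndarray] = {"time": pressure.times, "pressure": pressure.values}
    if flow is not None:
        name = "velocity" if flow.quantity == "flow_velocity" else "flow"
        cols[name] = flow.values
    for k, v in (extra or {}).items():
        cols[k] = np.asarray(v)
    pd.DataFrame(cols).to_csv(path, index=False)


def atomic_write_json(path: str | Path, payload: dict) -> None:
    """Write JSON via a temp file + rename so readers never see partial output."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def beat_frame(beat: BeatSegment, result=None) -> pd.DataFrame:
    """Per-sample table for a beat: time, P and, if given, P_res and P_xs."""
    cols = {"time": beat.pressure.times, "pressure": beat.pressure.values}
    if beat.flow is not None:
        cols["flow"] = beat.flow.values
    if result is not None:
        cols["p_res"] = result.P_res.values
        cols["p_xs"] = result.P_xs.values
    return pd.DataFrame(cols)
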