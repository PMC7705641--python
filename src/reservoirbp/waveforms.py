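"""Uniformly sampled pressure/flow waveforms and beat fiducials.

The data model is deliberately small: a :class:`UniformSeries` is an evenly
sampled physiological signal with a quantity tag that fixes its units
(pressure in mmHg, volumetric flow in mL/s, flow velocity in m/s), and a
:class:`BeatSegment` is one cardiac cycle of pressure — optionally with
simultaneous flow on the same grid — annotated with the two fiducials the
reservoir analysis needs: the beat foot (onset of the systolic upstroke) and
end-systole.

End-systole is located as the time of maximum negative rate of pressure
change (max −dP/dt), which in invasive animal studies coincides with the
cessation of aortic flow to well under a millisecond.  Because a raw
derivative is noise-sensitive, the derivative is taken by central
differences after Savitzky–Golay local-polynomial smoothing with a
configurable window (default 20 ms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Quantity",
    "UniformSeries",
    "BeatSegment",
    "WaveformError",
    "smoothed_derivative",
    "segment_beats",
    "detect_end_systole",
    "resample_uniform",
]

Quantity = Literal["pressure", "flow_volumetric", "flow_velocity"]

_UNITS: dict[str, str] = {
    "pressure": "mmHg",
    "flow_volumetric": "mL/s",
    "flow_velocity": "m/s",
}


class WaveformError(ValueError):
    """Raised for invalid waveform data or undetectable fiducials."""


@dataclass(frozen=True)
class UniformSeries:
    """An evenly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds; must be positive.
    values : ndarray
        Samples; at least two, all finite.  Units follow ``quantity``:
        mmHg for pressure, mL/s for volumetric flow, m/s for velocity.
    quantity : {"pressure", "flow_volumetric", "flow_velocity"}
    """

    t0: float
    dt: float
    values: np.ndarray
    quantity: Quantity = "pressure"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise WaveformError(f"dt must be positive, got {self.dt}")
        if vals.ndim != 1 or vals.size < 2:
            raise WaveformError("need a 1-D series with at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise WaveformError("all samples must be finite")
        if self.quantity not in _UNITS:
            raise WaveformError(f"unknown quantity {self.quantity!r}")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def units(self) -> str:
        return _UNITS[self.quantity]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return self.dt * (self.values.size - 1)

    def slice(self, i0: int, i1: int) -> "UniformSeries":
        """Sub-series covering sample indices ``[i0, i1)``."""
        if not (0 <= i0 < i1 <= len(self)):
            raise WaveformError(f"invalid slice [{i0}, {i1}) of {len(self)} samples")
        return UniformSeries(self.t0 + i0 * self.dt, self.dt, self.values[i0:i1], self.quantity)

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def _check_compatible(self, other: "UniformSeries") -> None:
        if self.quantity != other.quantity:
            raise WaveformError(
                f"cannot mix quantities {self.quantity!r} and {other.quantity!r}"
            )
        if len(self) != len(other) or not np.isclose(self.dt, other.dt):
            raise WaveformError("series are not on the same grid")

    def __add__(self, other):
        if isinstance(other, UniformSeries):
            self._check_compatible(other)
            return self.with_values(self.values + other.values)
        return self.with_values(self.values + other)

    def __sub__(self, other):
        if isinstance(other, UniformSeries):
            self._check_compatible(other)
            return self.with_values(self.values - other.values)
        return self.with_values(self.values - other)


@dataclass
class BeatSegment:
    """One cardiac cycle of pressure, optionally with simultaneous flow.

    ``i_foot`` marks the beat onset and ``i_es`` end-systole, both as sample
    indices into the pressure array.  ``i_es`` may be left unset and filled
    in later by :func:`detect_end_systole`.
    """

    pressure: UniformSeries
    flow: UniformSeries | None = None
    i_foot: int = 0
    i_es: int | None = None

    def __post_init__(self) -> None:
        if self.pressure.quantity != "pressure":
            raise WaveformError("BeatSegment.pressure must carry quantity 'pressure'")
        n = len(self.pressure)
        if not 0 <= self.i_foot < n:
            raise WaveformError(f"i_foot={self.i_foot} out of range for {n} samples")
        if self.i_es is not None and not (self.i_foot < self.i_es < n):
            raise WaveformError(
                f"need i_foot < i_es < n; got i_foot={self.i_foot}, i_es={self.i_es}, n={n}"
            )
        if self.flow is not None:
            if self.flow.quantity == "pressure":
                raise WaveformError("BeatSegment.flow must be a flow quantity")
            if len(self.flow) != n or not np.isclose(self.flow.dt, self.pressure.dt):
                raise WaveformError("flow must share the pressure grid")

    @property
    def dt(self) -> float:
        return self.pressure.dt

    @property
    def duration(self) -> float:
        return self.pressure.duration

    @property
    def t_es(self) -> float:
        """End-systole time relative to the foot, seconds."""
        if self.i_es is None:
            raise WaveformError("end-systole not set; run detect_end_systole first")
        return (self.i_es - self.i_foot) * self.dt


# ---------------------------------------------------------------------------
# derivative estimation


def _odd_window(window_s: float, dt: float, n: int) -> int:
    """Smoothing window length in samples: odd, >= 3, < n."""
    w = max(3, int(round(window_s / dt)) | 1)
    if w >= n:
        w = (n - 1) if (n - 1) % 2 == 1 else (n - 2)
    return max(w, 3)


def smoothed_derivative(series: UniformSeries, smooth_window: float = 0.02) -> np.ndarray:
    """First time-derivative by central differences after SG smoothing.

    ``smooth_window`` is the local-polynomial window in seconds (cubic
    polynomial).  Set it to 0 to skip smoothing.
    """
    x = series.values
    if smooth_window > 0 and len(x) >= 5:
        w = _odd_window(smooth_window, series.dt, len(x))
        poly = min(3, w - 1)
        x = savgol_filter(x, w, poly)
    return np.gradient(x, series.dt)


# ---------------------------------------------------------------------------
# fiducials


def detect_end_systole(beat: BeatSegment, smooth_window: float = 0.02) -> int:
    """Locate end-systole as the global minimum of smoothed dP/dt.

    Searches strictly after the foot; ties break to the earliest sample.
    Invariant to adding a constant to pressure and to time shifts.

    Raises
    ------
    WaveformError
        If fewer than 10 samples follow the foot, or the derivative is
        nonnegative everywhere after it (no decay, hence no end-systole).
    """
    n = len(beat.pressure)
    if n - beat.i_foot - 1 < 10:
        raise WaveformError("need at least 10 samples after the foot")
    dp = smoothed_derivative(beat.pressure, smooth_window)
    seg = dp[beat.i_foot + 1 :]
    if np.min(seg) >= 0:
        raise WaveformError("no end-systole detectable: dP/dt nonnegative after foot")
    return beat.i_foot + 1 + int(np.argmin(seg))


def segment_beats(
    p: UniformSeries,
    min_period: float,
    smooth_window: float = 0.02,
) -> list[BeatSegment]:
    """Split a multi-beat pressure record into beats delimited at the feet.

    The foot of each beat is the peak of the second derivative of pressure
    in a window immediately preceding each systolic upstroke (the upstroke
    itself located as a prominent maximum of smoothed dP/dt).  Feet closer
    than ``min_period`` are merged (the earlier one kept).  Each returned
    segment runs from one foot up to (not including) the next; the final
    segment runs from the last foot to the end of the record, so
    concatenating all segments reproduces the input samples from the first
    foot onwards.
    """
    if p.quantity != "pressure":
        raise WaveformError("segment_beats expects a pressure series")
    if min_period <= 0:
        raise WaveformError("min_period must be positive")
    if np.ptp(p.values) < 1e-9:
        raise WaveformError("no beats found: pressure is constant")
    dp = smoothed_derivative(p, smooth_window)
    d2p = np.gradient(dp, p.dt)

    dist = max(1, int(round(min_period / p.dt)))
    # systolic upstrokes: tall maxima of dP/dt
    peaks, _ = find_peaks(dp, height=0.4 * np.max(dp), distance=dist)
    if peaks.size == 0:
        # a single beat may start at the record edge where find_peaks is blind
        if np.max(dp) > 0:
            peaks = np.array([int(np.argmax(dp))])
        else:
            raise WaveformError("no beats found")

    look_back = max(2, int(round(min(0.15, min_period / 3) / p.dt)))
    feet: list[int] = []
    for pk in peaks:
        lo = max(0, pk - look_back)
        if pk <= lo:
            feet.append(int(pk))
            continue
        feet.append(lo + int(np.argmax(d2p[lo : pk + 1])))
    # merge feet closer than min_period, keeping the earlier
    merged: list[int] = []
    for f in sorted(set(feet)):
        if not merged or f - merged[-1] >= dist:
            merged.append(f)
    if not merged:
        raise WaveformError("no beats found")

    bounds = merged + [len(p)]
    beats: list[BeatSegment] = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 - i0 < 2:
            continue
        beats.append(BeatSegment(pressure=p.slice(i0, i1), i_foot=0))
    if not beats:
        raise WaveformError("no beats found")
    return beats


def resample_uniform(
    t: np.ndarray, values: np.ndarray, dt: float, quantity: Quantity = "pressure"
) -> UniformSeries:
    """Linearly resample possibly nonuniform samples onto a uniform grid.

    All downstream quadrature assumes uniform sampling, so irregular input
    is interpolated once at ingest.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size != values.size or t.size < 2:
        raise WaveformError("need matching 1-D time and value arrays, length >= 2")
    if np.any(np.diff(t) <= 0):
        raise WaveformError("time stamps must be strictly increasing")
    grid = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    grid = grid[grid <= t[-1] + 1e-12]
    return UniformSeries(float(t[0]), dt, np.interp(grid, t, values), quantity)
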