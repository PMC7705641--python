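"""Synthetic hemodynamic data: inflow, Windkessel, and delayed-reservoir models.

This module generates the ground truth against which all fitting operations
are validated.

*   :func:`half_sine_inflow` — the canonical benchmark aortic inflow: a
    half-sine of duration ``T_sys`` carrying stroke volume ``SV`` each beat,
    zero during diastole.  The end of inflow defines the true end-systole.
*   :func:`simulate_windkessel` — two- or three-element Windkessel pressure
    with a nonzero asymptote ``P_zf`` (the zero-flow / critical closing
    pressure):

        C dP_wk/dt = Q_in − (P_wk − P_zf)/R,      P = P_wk + Z_c·Q_in

    integrated with a per-sample exponential step that is exact for
    piecewise-linear inflow.
*   :func:`simulate_delay_network` — the delayed-reservoir model on a small
    branching tree: a single root pressure history P_res(t), seen at vessel
    n delayed by the wave transit time τ(n), obeying mass conservation

        Q_in − Σ_n C_n dP_res(t−τ(n))/dt − Σ_k (P_res(t−τ(k)) − P_zf)/R_k = 0

    solved by the method of steps on a fixed grid with linear interpolation
    into the stored history.  As all τ → 0 the solution converges to the
    lumped Windkessel ODE with C = ΣC_n and 1/R = Σ1/R_k, with error O(max τ).

Internally SI is used for vessel geometry; interfaces are mmHg / mL / s with
the conversion pinned at 133.322 Pa/mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ode import exp_step_coeffs as _exp_step_coeffs
from ._ode import integrate_linear_ode as _integrate_linear_ode
from .waveforms import BeatSegment, UniformSeries, WaveformError, detect_end_systole

__all__ = [
    "MMHG_PA",
    "InflowSpec",
    "WindkesselSpec",
    "VesselSegment",
    "ReservoirNetwork",
    "DelayNetworkResult",
    "half_sine_inflow",
    "simulate_windkessel",
    "simulate_delay_network",
    "vessel_compliance",
    "vessel_transit_time",
    "windkessel_beat",
    "add_pressure_noise",
]

MMHG_PA = 133.322
"""Pascals per mmHg."""

#: default transit-time budget, s — aorto-iliac transit in humans is < 80 ms
MAX_TRANSIT_TIME = 0.080


@dataclass(frozen=True)
class InflowSpec:
    """Half-sine inflow parameters.

    T_sys : systolic (ejection) duration, s; T_beat : beat period, s;
    SV : stroke volume per beat, mL; n_beats : number of beats;
    dt : sampling interval, s.
    """

    T_sys: float = 0.3
    T_beat: float = 1.0
    SV: float = 70.0
    n_beats: int = 10
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.T_sys < self.T_beat:
            raise ValueError("need 0 < T_sys < T_beat")
        if self.SV <= 0 or self.dt <= 0 or self.n_beats < 1:
            raise ValueError("SV, dt must be positive and n_beats >= 1")

    @property
    def peak_flow(self) -> float:
        """Peak of the half-sine, mL/s: Q_pk = π·SV/(2·T_sys)."""
        return np.pi * self.SV / (2.0 * self.T_sys)


@dataclass(frozen=True)
class WindkesselSpec:
    """Windkessel parameters.

    R : peripheral resistance, mmHg·s/mL; C : total compliance, mL/mmHg;
    Z_c : characteristic impedance, mmHg·s/mL (0 gives the two-element
    model); P_zf : zero-flow pressure asymptote, mmHg; P0 : initial
    pressure, mmHg.
    """

    R: float = 1.0
    C: float = 1.5
    Z_c: float = 0.0
    P_zf: float = 0.0
    P0: float = 80.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0 or self.Z_c < 0:
            raise ValueError("need R > 0, C > 0, Z_c >= 0")


def half_sine_inflow(spec: InflowSpec) -> UniformSeries:
    """Periodic half-sine volumetric inflow.

    Within each beat Q(t) = Q_pk·sin(π t/T_sys) for t in [0, T_sys] and 0
    during diastole, with Q_pk chosen so the per-beat integral equals SV.
    """
    n = int(round(spec.n_beats * spec.T_beat / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    phase = np.mod(t, spec.T_beat)
    q = np.where(
        phase < spec.T_sys,
        spec.peak_flow * np.sin(np.pi * phase / spec.T_sys),
        0.0,
    )
    return UniformSeries(0.0, spec.dt, np.clip(q, 0.0, None), "flow_volumetric")


def simulate_windkessel(inflow: UniformSeries, spec: WindkesselSpec) -> UniformSeries:
    """Pressure from a two- or three-element Windkessel driven by ``inflow``.

    Returns P = P_wk + Z_c·Q_in on the inflow grid.  The compliance state is
    advanced with the exact exponential step for piecewise-linear Q_in, so
    the only discretization error is the linear-in-dt representation of the
    inflow itself (globally O(dt²) for smooth inflow).
    """
    if inflow.quantity != "flow_volumetric":
        raise WaveformError("simulate_windkessel needs volumetric inflow (mL/s)")
    q = inflow.values
    a = 1.0 / (spec.R * spec.C)
    # state x = P_wk − P_zf:  x' = −a x + Q_in/C
    x = _integrate_linear_ode(spec.P0 - spec.P_zf, a, q / spec.C, inflow.dt)
    p = spec.P_zf + x + spec.Z_c * q
    return UniformSeries(inflow.t0, inflow.dt, p, "pressure")


# ---------------------------------------------------------------------------
# branching network


@dataclass(frozen=True)
class VesselSegment:
    """A uniform arterial segment.

    L : length, m; A : cross-sectional area, m²; v : wave speed, m/s;
    rho : blood density, kg/m³ (default 1050).

    Compliance and transit time are always derived from these primitives:
    C_n = L·A/(rho·v²) (converted to mL/mmHg) and τ_n = L/v.
    """

    L: float
    A: float
    v: float
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if min(self.L, self.A, self.v, self.rho) <= 0:
            raise ValueError("vessel primitives must all be positive")

    @property
    def compliance(self) -> float:
        """Segment compliance in mL/mmHg."""
        return vessel_compliance(self)

    @property
    def transit_time(self) -> float:
        """Wave transit time along the segment, s."""
        return vessel_transit_time(self)


def vessel_compliance(seg: VesselSegment) -> float:
    """C_n = L·A/(rho·v²), converted from m³/Pa to mL/mmHg."""
    c_si = seg.L * seg.A / (seg.rho * seg.v**2)  # m^3/Pa
    return c_si * MMHG_PA * 1e6  # -> mL/mmHg


def vessel_transit_time(seg: VesselSegment) -> float:
    """τ_n = L/v, s."""
    return seg.L / seg.v


@dataclass
class ReservoirNetwork:
    """Rooted tree of vessel segments with terminal resistances.

    ``parents[i]`` is the index of vessel i's parent, or ``None`` for the
    single root.  Every leaf (vessel with no children) must have a terminal
    resistance in ``terminal_resistances`` (mmHg·s/mL).  The cumulative
    transit time τ(n) is the sum of segment transit times on the root→n
    path, with τ accumulated up to the *distal* end of each segment's
    parent (the root sees no delay).
    """

    vessels: list[VesselSegment]
    parents: list[int | None]
    terminal_resistances: dict[int, float] = field(default_factory=dict)
    max_transit_time: float = MAX_TRANSIT_TIME

    def __post_init__(self) -> None:
        n = len(self.vessels)
        if n == 0 or len(self.parents) != n:
            raise ValueError("need one parent entry per vessel")
        roots = [i for i, p in enumerate(self.parents) if p is None]
        if len(roots) != 1:
            raise ValueError(f"need exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parents):
            if p is not None and not (0 <= p < n and p != i):
                raise ValueError(f"invalid parent {p} for vessel {i}")
        for k in self.leaves:
            r = self.terminal_resistances.get(k)
            if r is None or r <= 0:
                raise ValueError(f"leaf vessel {k} needs a positive terminal resistance")
        if max(self.transit_times) > self.max_transit_time + 1e-12:
            raise ValueError(
                f"max transit time {max(self.transit_times):.4f} s exceeds the "
                f"budget {self.max_transit_time} s"
            )

    @property
    def root(self) -> int:
        return next(i for i, p in enumerate(self.parents) if p is None)

    @property
    def leaves(self) -> list[int]:
        children = set(p for p in self.parents if p is not None)
        return [i for i in range(len(self.vessels)) if i not in children]

    @property
    def transit_times(self) -> list[float]:
        """Cumulative τ(n): delay from the root to the *entry* of vessel n."""
        tau: list[float | None] = [None] * len(self.vessels)

        def resolve(i: int) -> float:
            if tau[i] is None:
                p = self.parents[i]
                tau[i] = 0.0 if p is None else resolve(p) + self.vessels[p].transit_time
            return tau[i]  # type: ignore[return-value]

        return [resolve(i) for i in range(len(self.vessels))]

    @property
    def total_compliance(self) -> float:
        """ΣC_n, mL/mmHg — the compliance of the equivalent lumped model."""
        return sum(v.compliance for v in self.vessels)

    @property
    def total_resistance(self) -> float:
        """Parallel combination 1/R = Σ1/R_k, mmHg·s/mL."""
        return 1.0 / sum(1.0 / r for r in self.terminal_resistances.values())

    def lumped_spec(self, P_zf: float, P0: float) -> WindkesselSpec:
        """Equivalent two-element Windkessel (the τ → 0 limit)."""
        return WindkesselSpec(
            R=self.total_resistance, C=self.total_compliance, Z_c=0.0, P_zf=P_zf, P0=P0
        )

    def scaled_delays(self, factor: float) -> "ReservoirNetwork":
        """Copy of the network with every transit time scaled by ``factor``.

        Wave speeds are divided by the factor and areas by factor² so each
        C_n = L·A/(rho·v²) is preserved; used for convergence studies of the
        delay model against its lumped limit.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        vessels = [
            VesselSegment(v.L, v.A / factor**2, v.v / factor, v.rho)
            for v in self.vessels
        ]
        return ReservoirNetwork(
            vessels, list(self.parents), dict(self.terminal_resistances),
            self.max_transit_time,
        )


@dataclass(frozen=True)
class DelayNetworkResult:
    """Output of :func:`simulate_delay_network`."""

    root_pressure: UniformSeries
    vessel_pressures: list[UniformSeries]
    outflow: UniformSeries
    transit_times: list[float]


def _interp_history(p: np.ndarray, idx: float, p_init: float) -> float:
    """Linear interpolation of the stored history at fractional index."""
    if idx <= 0.0:
        return p_init
    j = int(np.floor(idx))
    frac = idx - j
    if frac == 0.0:
        return p[j]
    return (1.0 - frac) * p[j] + frac * p[j + 1]


def simulate_delay_network(
    net: ReservoirNetwork,
    inflow: UniformSeries,
    P_zf: float,
    P_init: float,
) -> DelayNetworkResult:
    """Solve the delayed-reservoir mass-conservation equation on a tree.

    The root history P_res(t) satisfies

        Q_in(t) = Σ_n C_n P'_res(t−τ(n)) + Σ_k (P_res(t−τ(k)) − P_zf)/R_k

    with constant history P_res(t ≤ 0) = P_init.  Terms at zero delay are
    advanced exactly (exponential step); positively delayed terms are read
    from the stored history by linear interpolation, with the delayed
    derivative taken by central differences on the stored grid.  Requires
    dt ≤ min positive τ / 4 so every delayed term lies strictly in the past.

    Per-vessel pressures are the root solution shifted by τ(n); the outflow
    is Q_out(t) = Σ_k (P_res(t−τ(k)) − P_zf)/R_k.
    """
    if inflow.quantity != "flow_volumetric":
        raise WaveformError("simulate_delay_network needs volumetric inflow")
    dt = inflow.dt
    q = inflow.values
    n = q.size

    taus = net.transit_times
    comps = [v.compliance for v in net.vessels]
    leaf_taus = [taus[k] for k in net.leaves]
    leaf_res = [net.terminal_resistances[k] for k in net.leaves]

    pos_taus = [t for t in taus if t > 0] + [t for t in leaf_taus if t > 0]
    if pos_taus and dt > min(pos_taus) / 4 + 1e-15:
        raise WaveformError(
            f"refine dt: dt={dt:g} s exceeds min positive delay/4 = {min(pos_taus)/4:g} s"
        )

    c0 = sum(c for c, t in zip(comps, taus) if t == 0)
    g0 = sum(1.0 / r for r, t in zip(leaf_res, leaf_taus) if t == 0)
    if c0 <= 0:
        raise WaveformError("the root vessel must contribute compliance at zero delay")

    delayed_c = [(c, t) for c, t in zip(comps, taus) if t > 0]
    delayed_r = [(r, t) for r, t in zip(leaf_res, leaf_taus) if t > 0]

    p = np.empty(n)
    dp = np.zeros(n)  # derivative estimates on the grid, filled as we go
    p[0] = P_init

    def forcing(i: int) -> float:
        """RHS seen by the zero-delay state at grid time i·dt."""
        f = q[i]
        t = i * dt
        for c, tau in delayed_c:
            f -= c * _interp_history(dp, (t - tau) / dt, 0.0)
        for r, tau in delayed_r:
            f -= (_interp_history(p, (t - tau) / dt, P_init) - P_zf) / r
        return f

    a = g0 / c0
    E, b0, b1 = _exp_step_coeffs(a, dt)
    f_prev = forcing(0)
    for i in range(1, n):
        f_i = forcing(i)
        x_prev = p[i - 1] - P_zf if g0 > 0 else p[i - 1]
        if g0 > 0:
            p[i] = P_zf + E * x_prev + b0 * (f_prev / c0) + b1 * (f_i / c0)
        else:
            # pure integrator at the root: trapezoid, exact for linear f
            p[i] = p[i - 1] + 0.5 * dt * (f_prev + f_i) / c0
        f_prev = f_i
        # central-difference derivative one step back; history indices only
        if i >= 2:
            dp[i - 1] = (p[i] - p[i - 2]) / (2 * dt)
        else:
            dp[0] = (p[1] - p[0]) / dt

    dp[n - 1] = (p[n - 1] - p[n - 2]) / dt

    t_grid = np.arange(n) * dt
    vessel_p = []
    for tau in taus:
        shifted = np.array([_interp_history(p, (t - tau) / dt, P_init) for t in t_grid])
        vessel_p.append(UniformSeries(inflow.t0, dt, shifted, "pressure"))
    qout = np.zeros(n)
    for r, tau in zip(leaf_res, leaf_taus):
        shifted = np.array([_interp_history(p, (t - tau) / dt, P_init) for t in t_grid])
        qout += (shifted - P_zf) / r
    return DelayNetworkResult(
        root_pressure=UniformSeries(inflow.t0, dt, p, "pressure"),
        vessel_pressures=vessel_p,
        outflow=UniformSeries(inflow.t0, dt, qout, "flow_volumetric"),
        transit_times=taus,
    )


def windkessel_beat(
    inflow_spec: InflowSpec,
    wk_spec: WindkesselSpec,
    beat_index: int = -2,
    detect_es: bool = True,
) -> BeatSegment:
    """Simulate to quasi-steady state and cut out one beat with its flow.

    Runs the Windkessel for ``inflow_spec.n_beats`` beats and extracts the
    beat starting at ``beat_index``·T_beat (negative counts from the end;
    the default −2 is the last complete beat, well past the initial
    transient for usual time constants).  End-systole is detected from the
    pressure by max −dP/dt unless ``detect_es`` is False.
    """
    inflow = half_sine_inflow(inflow_spec)
    pressure = simulate_windkessel(inflow, wk_spec)
    idx = beat_index if beat_index >= 0 else inflow_spec.n_beats + beat_index
    if not 0 <= idx < inflow_spec.n_beats:
        raise ValueError("beat_index out of range")
    i0 = int(round(idx * inflow_spec.T_beat / inflow_spec.dt))
    i1 = int(round((idx + 1) * inflow_spec.T_beat / inflow_spec.dt)) + 1
    i1 = min(i1, len(pressure))
    beat = BeatSegment(
        pressure=pressure.slice(i0, i1), flow=inflow.slice(i0, i1), i_foot=0
    )
    if detect_es:
        beat.i_es = detect_end_systole(beat)
    return beat


def add_pressure_noise(
    series: UniformSeries, sigma: float, rng: np.random.Generator | int | None = None
) -> UniformSeries:
    """Additive zero-mean Gaussian measurement noise (mmHg), reproducible.

    All randomness used by fit tests comes through here so every experiment
    is seedable from a single place.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return series.with_values(series.values + gen.normal(0.0, sigma, len(series)))
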