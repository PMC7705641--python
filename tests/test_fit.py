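"""Reservoir / excess pressure fitting: decay fit, both routes, indices."""

import warnings

import numpy as np
import pytest

from reservoirbp.fit import (
    DiastolicFit,
    FitError,
    analyze_p,
    analyze_pq,
    compute_pres_p,
    compute_pres_pq,
    estimate_rc,
    fit_diastolic_decay,
    fit_ks,
    reservoir_indices,
)
from reservoirbp.sim import (
    InflowSpec,
    WindkesselSpec,
    add_pressure_noise,
    windkessel_beat,
)
from reservoirbp.waveforms import BeatSegment, UniformSeries


def _decay_beat(dt=1e-3, t_es=0.2, dur=0.9, kd=1 / 1.5, pinf=30.0, amp=60.0,
                noise=None):
    """Beat whose diastole (t >= t_es) is exactly P_inf + amp·e^{−kd(t−t_es)}."""
    t = np.arange(0.0, dur + dt / 2, dt)
    p = np.where(
        t < t_es,
        pinf + amp + 10.0 * np.sin(np.pi * t / t_es),  # arbitrary systole
        pinf + amp * np.exp(-kd * (t - t_es)),
    )
    series = UniformSeries(0.0, dt, p)
    if noise is not None:
        sigma, seed = noise
        series = add_pressure_noise(series, sigma, seed)
    return BeatSegment(pressure=series, i_foot=0, i_es=int(round(t_es / dt)))


class TestFitDiastolicDecay:
    def test_exact_exponential_recovered_to_machine_precision(self):
        beat = _decay_beat()
        fit = fit_diastolic_decay(beat, window=(0.2, 0.9))
        assert np.isclose(fit.k_d, 1 / 1.5, rtol=1e-6)
        assert np.isclose(fit.P_inf, 30.0, rtol=1e-6)
        assert np.isclose(fit.P_es, 90.0, rtol=1e-6)
        assert fit.rmse < 1e-6
        assert not fit.implausible

    def test_noisy_recovery_bias_and_spread(self):
        # sigma = 0.5 mmHg on a 60 mmHg decay: Monte Carlo over 100 seeds
        errs_kd, errs_pinf = [], []
        for seed in range(100):
            beat = _decay_beat(noise=(0.5, seed))
            fit = fit_diastolic_decay(beat, window=(0.2, 0.9))
            errs_kd.append(fit.k_d / (1 / 1.5) - 1.0)
            errs_pinf.append(fit.P_inf - 30.0)
        # bounds frozen from this Monte Carlo: estimates are unbiased and the
        # spread reflects the weak identification of P_inf over a window
        # spanning less than half a time constant
        assert abs(np.mean(errs_kd)) < 0.02
        assert np.quantile(np.abs(errs_kd), 0.9) < 0.08
        assert abs(np.mean(errs_pinf)) < 0.5
        assert np.quantile(np.abs(errs_pinf), 0.9) < 3.6

    def test_constant_pressure_fails(self):
        p = UniformSeries(0.0, 1e-3, np.full(900, 80.0))
        beat = BeatSegment(pressure=p, i_foot=0, i_es=200)
        with pytest.raises(FitError, match="diastolic fit failed"):
            fit_diastolic_decay(beat)

    def test_default_window_guards(self, wk3_beat):
        fit = fit_diastolic_decay(wk3_beat)
        lo, hi = fit.window
        assert np.isclose(lo, wk3_beat.t_es + 0.030)
        assert np.isclose(hi, wk3_beat.duration - 0.030)

    def test_too_short_window_rejected(self):
        beat = _decay_beat()
        with pytest.raises(FitError, match="fewer than 10"):
            fit_diastolic_decay(beat, window=(0.2, 0.205))

    def test_nonpositive_rate_rejected_by_type(self):
        with pytest.raises(FitError):
            DiastolicFit(P_es=90, k_d=-1.0, P_inf=30, rmse=0.0, window=(0.2, 0.9))


class TestEstimateRC:
    def test_arithmetic(self):
        # mean P = 100, P_inf = 30, mean Q = 70, k_d = 2/3 -> R = 1, C = 1.5
        n = 1000
        p = UniformSeries(0.0, 1e-3, np.full(n, 100.0))
        q = UniformSeries(0.0, 1e-3, np.full(n, 70.0), "flow_volumetric")
        beat = BeatSegment(pressure=p, flow=q, i_foot=0, i_es=300)
        fit = DiastolicFit(P_es=90.0, k_d=2 / 3, P_inf=30.0, rmse=0.0, window=(0.33, 0.97))
        R, C = estimate_rc(beat, fit)
        assert np.isclose(R, 1.0) and np.isclose(C, 1.5)

    def test_two_element_simulation_recovery(self):
        # periodic steady state: long run so the transient has fully decayed
        beat = windkessel_beat(
            InflowSpec(n_beats=20, dt=1e-3),
            WindkesselSpec(R=1.2, C=1.4, Z_c=0.0, P_zf=20.0, P0=104.0),
        )
        fit = fit_diastolic_decay(beat)
        R, C = estimate_rc(beat, fit)
        assert abs(R / 1.2 - 1) < 0.01
        assert abs(C / 1.4 - 1) < 0.02

    def test_flow_rescaling_leaves_rc_product_invariant(self, wk3_beat):
        fit = fit_diastolic_decay(wk3_beat)
        R1, C1 = estimate_rc(wk3_beat, fit)
        scaled = BeatSegment(
            pressure=wk3_beat.pressure,
            flow=UniformSeries(
                wk3_beat.flow.t0, wk3_beat.flow.dt, wk3_beat.flow.values * 2.0,
                "flow_velocity",
            ),
            i_foot=wk3_beat.i_foot,
            i_es=wk3_beat.i_es,
        )
        R2, C2 = estimate_rc(scaled, fit)
        assert np.isclose(R2, R1 / 2) and np.isclose(C2, C1 * 2)
        assert np.isclose(R1 * C1, R2 * C2, rtol=1e-12)

    def test_asymptote_above_mean_pressure_fails(self):
        n = 1000
        p = UniformSeries(0.0, 1e-3, np.full(n, 100.0))
        q = UniformSeries(0.0, 1e-3, np.full(n, 70.0), "flow_volumetric")
        beat = BeatSegment(pressure=p, flow=q, i_foot=0, i_es=300)
        fit = DiastolicFit(P_es=90.0, k_d=2 / 3, P_inf=150.0, rmse=0.0,
                           window=(0.33, 0.97), implausible=True)
        with pytest.raises(FitError, match="nonpositive resistance"):
            estimate_rc(beat, fit)


class TestComputePresPQ:
    def test_zero_inflow_closed_form(self):
        # P_res(1.5 s) = 30 + 60/e = 52.073 for RC = 1.5, P_res0 = 90
        n = 1501
        p = UniformSeries(0.0, 1e-3, np.full(n, 50.0))
        q = UniformSeries(0.0, 1e-3, np.zeros(n), "flow_volumetric")
        beat = BeatSegment(pressure=p, flow=q, i_foot=0, i_es=100)
        res = compute_pres_pq(beat, R=1.5, C=1.0, P_zf=30.0, P_res0=90.0)
        assert np.isclose(res.P_res.values[-1], 30 + 60 / np.e, rtol=1e-9)

    def test_two_element_reservoir_equals_pressure(self, wk2_beat):
        res = compute_pres_pq(wk2_beat, R=1.2, C=1.4, P_zf=20.0,
                              P_res0=wk2_beat.pressure.values[0])
        pp = np.ptp(wk2_beat.pressure.values)
        assert np.max(np.abs(res.P_res.values - wk2_beat.pressure.values)) < 1e-6 * pp
        assert np.max(np.abs(res.P_xs.values)) < 1e-6 * pp

    def test_three_element_excess_is_impedance_times_flow(self, wk3_beat):
        res = compute_pres_pq(wk3_beat, R=1.2, C=1.4, P_zf=20.0,
                              P_res0=wk3_beat.pressure.values[0])
        zq = 0.05 * wk3_beat.flow.values
        assert np.max(np.abs(res.P_xs.values - zq)) < 1e-3 * np.max(zq)

    def test_additivity_to_machine_precision(self, wk3_beat):
        res = compute_pres_pq(wk3_beat, R=1.2, C=1.4, P_zf=20.0)
        np.testing.assert_allclose(
            res.P_res.values + res.P_xs.values, wk3_beat.pressure.values,
            rtol=1e-14, atol=1e-11,
        )

    def test_second_order_convergence_in_dt(self):
        # independent oracle: closed-form Windkessel response to the half-sine
        R, C, pzf = 1.2, 1.4, 20.0
        a, T = 1 / (R * C), 0.3
        w = np.pi / T
        qpk = np.pi * 70.0 / (2 * T)
        errs = []
        for dt in (2e-3, 1e-3):
            t = np.arange(0.0, T + dt / 2, dt)
            q = qpk * np.sin(w * t)
            exact = pzf + (qpk / C) * (
                a * np.sin(w * t) - w * np.cos(w * t) + w * np.exp(-a * t)
            ) / (a**2 + w**2)
            beat = BeatSegment(
                pressure=UniformSeries(0.0, dt, exact),
                flow=UniformSeries(0.0, dt, q, "flow_volumetric"),
                i_foot=0,
                i_es=len(t) - 2,
            )
            res = compute_pres_pq(beat, R, C, pzf, P_res0=pzf)
            errs.append(np.max(np.abs(res.P_res.values - exact)))
        assert errs[0] / errs[1] > 3.4  # O(dt^2)


class TestComputePresP:
    def test_fixed_point_constant_pressure_at_pzf(self):
        p = UniformSeries(0.0, 1e-3, np.full(1000, 50.0))
        beat = BeatSegment(pressure=p, i_foot=0, i_es=300)
        res = compute_pres_p(beat, k_s=5.0, k_d=0.6, P_zf=50.0, P_res0=50.0)
        np.testing.assert_allclose(res.P_res.values, 50.0, atol=1e-10)

    def test_large_ks_limit_tracks_pressure(self, wk3_beat):
        res = compute_pres_p(wk3_beat, k_s=1e6, k_d=0.595, P_zf=20.0,
                             P_res0=wk3_beat.pressure.values[0])
        assert np.max(np.abs(res.P_res.values - wk3_beat.pressure.values)) < 0.05

    def test_cross_method_consistency_on_three_element_beat(self, wk3_beat):
        # matched rates: k_d = 1/RC, k_s = 1/(Z_c C), P_zf as simulated
        kd, ks = 1 / (1.2 * 1.4), 1 / (0.05 * 1.4)
        p0 = wk3_beat.pressure.values[0]
        res_p = compute_pres_p(wk3_beat, ks, kd, 20.0, P_res0=p0)
        res_pq = compute_pres_pq(wk3_beat, 1.2, 1.4, 20.0, P_res0=p0)
        pp = np.ptp(wk3_beat.pressure.values)
        gap = np.max(np.abs(res_p.P_res.values - res_pq.P_res.values))
        assert gap < 0.02 * pp
        peak_diff = abs(np.max(res_p.P_res.values) - np.max(res_pq.P_res.values))
        assert peak_diff < 0.02 * pp


class TestFitKs:
    def test_recovers_characteristic_admittance(self, wk3_beat):
        ks = fit_ks(wk3_beat, k_d=1 / (1.2 * 1.4), P_zf=20.0)
        assert abs(ks / (1 / (0.05 * 1.4)) - 1) < 0.05

    def test_agrees_with_grid_search_oracle(self, wk3_beat):
        kd, pzf = 1 / (1.2 * 1.4), 20.0
        t = np.arange(len(wk3_beat.pressure)) * wk3_beat.dt
        lo, hi = wk3_beat.t_es + 0.03, wk3_beat.duration - 0.03
        mask = (t >= lo) & (t <= hi)
        p = wk3_beat.pressure.values

        # oracle: dense log grid; the estimand is the first local minimum
        # (the diastolic objective always re-descends as k_s -> infinity,
        # where the reservoir degenerates to the measured pressure)
        grid = np.logspace(-3, 3, 10_000)
        sse = np.array([
            np.sum((p[mask] - compute_pres_p(wk3_beat, k, kd, pzf).P_res.values[mask]) ** 2)
            for k in grid
        ])
        interior = np.nonzero((sse[1:-1] <= sse[:-2]) & (sse[1:-1] <= sse[2:]))[0]
        k_grid = grid[int(interior[0]) + 1]
        k_opt = fit_ks(wk3_beat, kd, pzf)
        spacing = np.log(grid[1] / grid[0])
        assert abs(np.log(k_opt / k_grid)) <= spacing * 1.5

    def test_scale_invariance_of_pressure_doubling(self, wk3_beat):
        kd = 1 / (1.2 * 1.4)
        ks1 = fit_ks(wk3_beat, kd, 20.0)
        doubled = BeatSegment(
            pressure=wk3_beat.pressure.with_values(2 * wk3_beat.pressure.values),
            i_foot=wk3_beat.i_foot,
            i_es=wk3_beat.i_es,
        )
        ks2 = fit_ks(doubled, kd, 40.0)
        assert np.isclose(ks1, ks2, rtol=1e-4)

    def test_bound_warning_when_objective_monotone(self):
        # pressure constant at P_zf: any k_s fits equally; minimiser hits a bound
        p = UniformSeries(0.0, 1e-3, np.concatenate([
            np.linspace(50, 80, 200), 80 * np.exp(-np.arange(800) * 1e-3)
        ]))
        beat = BeatSegment(pressure=p, i_foot=0, i_es=200)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            fit_ks(beat, k_d=1e-3, P_zf=0.0)
        # either converges interior or warns; the warning path needs a
        # genuinely monotone objective, exercised here via tiny k_d
        assert all(issubclass(w.category, RuntimeWarning) for w in rec)


class TestIndices:
    def test_all_zero_when_reservoir_sits_at_diastolic(self):
        p = UniformSeries(0.0, 1e-3, np.full(100, 80.0))
        from reservoirbp.fit import ReservoirParams, ReservoirResult

        res = ReservoirResult(
            P_res=p, P_xs=p.with_values(np.zeros(100)),
            params=ReservoirParams(k_d=1.0, P_zf=0.0, P_res0=80.0),
        )
        idx = reservoir_indices(res, P_d=80.0)
        assert all(np.isclose(v, 0.0) for v in idx.values())

    def test_excess_integral_equals_impedance_times_stroke_volume(self, wk3_beat):
        res = compute_pres_pq(wk3_beat, R=1.2, C=1.4, P_zf=20.0,
                              P_res0=wk3_beat.pressure.values[0])
        idx = reservoir_indices(res, P_d=float(np.min(wk3_beat.pressure.values)))
        assert abs(idx["auc_pxs"] - 0.05 * 70.0) < 0.005 * (0.05 * 70.0)

    def test_offset_invariance(self, wk3_beat):
        res = compute_pres_pq(wk3_beat, R=1.2, C=1.4, P_zf=20.0)
        idx1 = reservoir_indices(res, P_d=90.0)
        shifted = BeatSegment(
            pressure=wk3_beat.pressure.with_values(wk3_beat.pressure.values + 7.0),
            flow=wk3_beat.flow, i_foot=wk3_beat.i_foot, i_es=wk3_beat.i_es,
        )
        res2 = compute_pres_pq(shifted, R=1.2, C=1.4, P_zf=27.0)
        idx2 = reservoir_indices(res2, P_d=97.0)
        for k in idx1:
            assert np.isclose(idx1[k], idx2[k], atol=1e-8)


class TestPipelines:
    def test_pressure_only_pipeline_recovers_generating_parameters(self, wk3_beat):
        res = analyze_p(wk3_beat)
        assert abs(res.params.k_d / (1 / (1.2 * 1.4)) - 1) < 0.05
        assert abs(res.params.P_zf - 20.0) < 1.0
        assert abs(res.params.k_s / (1 / (0.05 * 1.4)) - 1) < 0.05

    def test_pq_pipeline_returns_consistent_params(self, wk2_beat):
        res = analyze_pq(wk2_beat)
        assert res.params.R is not None and res.params.C is not None
        assert np.isclose(res.params.k_d * res.params.R * res.params.C, 1.0, rtol=1e-9)
        assert res.fit is not None

    def test_fixed_pzf_mode_overrides_fit(self, wk3_beat):
        res = analyze_p(wk3_beat, pzf_mode="fixed", pzf=0.0)
        assert res.params.P_zf == 0.0
        assert res.params.pzf_mode == "fixed"
        with pytest.raises(FitError, match="requires an explicit"):
            analyze_p(wk3_beat, pzf_mode="fixed")
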