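import numpy as np
import pandas as pd
import pytest

from mesomix import (DeltaQSeries, ExpansivityParams, ThermogramSpec, VolumePolynomial,
                     alpha_bar_from_deltaq, delta_delta_q, deltaq_from_alpha_bar,
                     eval_hydration_model, gen_thermogram, hepler_gradient,
                     hepler_gradient_tabulated, integrate_pulse, invert_hydration_model,
                     load_fixture, reduce_thermogram, window_gradient)

SCHEDULE_TEMPS = 7.0 + np.arange(56)


def _series(temps, dq, dp=4.0, direction="up", label=""):
    return DeltaQSeries(pd.DataFrame({
        "temp_C": temps, "dq_uJ": dq,
        "direction": [direction] * len(temps), "dp_bar": [dp] * len(temps)}), label=label)


def _planted(series, areas):
    return np.array([areas[round(t)] * (1 if d == "up" else -1)
                     for t, d in zip(series.data.temp_C, series.data.direction)])


class TestIntegration:
    def test_rect_spike_area(self):
        spec = ThermogramSpec(7.0, 8.0, {7.0: 300.0, 8.0: 300.0},
                              spike_model="rect", spike_height_uW=10.0)
        pi = integrate_pulse(gen_thermogram(spec), 0)
        assert pi.dq_uJ == pytest.approx(300.0, rel=1e-6)
        assert pi.direction == "up" and pi.dp_bar == 4.0

    def test_gauss_on_drifting_baseline_noise_free(self):
        areas = {float(T): 500.0 for T in (7.0, 8.0, 9.0, 10.0)}
        spec = ThermogramSpec(7.0, 10.0, areas, spike_model="gauss",
                              baseline_offset_uW=3.0, baseline_drift_uW_per_C=0.2)
        tg = gen_thermogram(spec)
        for k in range(tg.n_events):
            pi = integrate_pulse(tg, k)
            assert abs(pi.dq_uJ) == pytest.approx(500.0, rel=0.005)

    def test_noisy_recovery_within_two_percent(self):
        areas = {float(T): 2000.0 + 100.0 * T for T in SCHEDULE_TEMPS}
        spec = ThermogramSpec(7.0, 62.0, areas, spike_model="gauss",
                              baseline_drift_uW_per_C=0.2, noise_sd_uW=0.5, seed=42)
        s = reduce_thermogram(gen_thermogram(spec), trim=None)
        rel = np.abs(s.data.dq_uJ.to_numpy() - _planted(s, areas)) / np.abs(_planted(s, areas))
        assert rel.max() < 0.02

    def test_overrunning_spike_flagged_unreliable(self):
        # 8000 uJ at 10 uW needs 800 s > the 600 s pulse interval
        spec = ThermogramSpec(7.0, 9.0, {7.0: 8000.0, 8.0: 8000.0, 9.0: 8000.0},
                              spike_model="rect", spike_height_uW=10.0)
        pi = integrate_pulse(gen_thermogram(spec), 0)
        assert not pi.reliable


class TestReduce:
    def test_schedule_trims_to_usable_range(self):
        areas = {float(T): 500.0 for T in SCHEDULE_TEMPS}
        tg = gen_thermogram(ThermogramSpec(7.0, 62.0, areas))
        full = reduce_thermogram(tg, trim=None)
        assert len(full.data) == tg.n_events == 56
        trimmed = reduce_thermogram(tg)  # default 9-61 °C
        assert trimmed.data.temp_C.min() == pytest.approx(9.0)
        assert trimmed.data.temp_C.max() == pytest.approx(61.0)
        assert len(trimmed.data) == 53

    def test_round_trip_recovers_planted_areas(self):
        areas = {float(T): -300.0 - 20.0 * T for T in SCHEDULE_TEMPS}
        spec = ThermogramSpec(7.0, 62.0, areas, spike_model="expdecay",
                              baseline_drift_uW_per_C=0.1)
        s = reduce_thermogram(gen_thermogram(spec), trim=None)
        np.testing.assert_allclose(s.data.dq_uJ, _planted(s, areas), rtol=0.005)

    def test_no_events_rejected(self):
        tg = gen_thermogram(ThermogramSpec(7.0, 8.0, {7.0: 1.0, 8.0: 1.0}))
        tg.events = tg.events.iloc[:0]
        with pytest.raises(ValueError, match="no annotated"):
            reduce_thermogram(tg)


class TestGradient:
    def test_exact_line(self):
        temps = np.arange(9.0, 36.0)
        s = _series(temps, -1000.0 + 20.0 * temps, dp=4.0)
        g = window_gradient(s, window=(9.0, 35.0))
        assert g.slope_uJ_per_bar_K == pytest.approx(5.0, abs=1e-12)
        assert g.r_squared == pytest.approx(1.0)
        assert g.n_points == 27
        assert not g.low_confidence

    def test_constant_series_zero_slope(self):
        temps = np.arange(9.0, 36.0)
        g = window_gradient(_series(temps, np.full(len(temps), -5.0)), window=(9.0, 35.0))
        assert g.slope_uJ_per_bar_K == pytest.approx(0.0, abs=1e-12)

    def test_planted_slope_recovered_under_noise(self):
        # 27 points, 1 °C steps over 9-35 °C, noise sd 1% of the data range
        rng = np.random.default_rng(8)
        temps = np.arange(9.0, 36.0)
        slope_true = 20.0
        dq = -1000.0 + slope_true * temps
        noisy = dq + rng.normal(0.0, 0.01 * (dq.max() - dq.min()), size=len(dq))
        g = window_gradient(_series(temps, noisy, dp=4.0), window=(9.0, 35.0))
        assert g.slope_uJ_per_bar_K == pytest.approx(slope_true / 4.0, rel=0.02)

    def test_low_r2_flagged(self):
        rng = np.random.default_rng(0)
        temps = np.arange(9.0, 36.0)
        g = window_gradient(_series(temps, rng.normal(0, 100, len(temps))), window=(9.0, 35.0))
        assert g.low_confidence

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            window_gradient(_series(np.array([10.0, 11.0]), np.array([1.0, 2.0])))


class TestDeltaDeltaQ:
    def test_affine_series_identically_zero(self):
        comps = [0.0, 10.0, 25.0, 60.0, 100.0]
        values = {c: 50.0 - 7.0 * c for c in comps}
        ddq = delta_delta_q(values, at_T=25.5)
        np.testing.assert_allclose(ddq.to_numpy(), 0.0, atol=1e-9)

    def test_endpoints_zero(self):
        ddq = delta_delta_q({0.0: 70.0, 50.0: -100.0, 100.0: -28808.0})
        assert ddq[0.0] == 0.0 and ddq[100.0] == 0.0

    def test_reference_table_20_molpct(self):
        t1 = load_fixture("table1")
        values = dict(zip(t1.mole_percent, t1.delta_q_uJ))
        ddq = delta_delta_q(values, at_T=25.5)
        # hand arithmetic: -21630 - (0.8*70 + 0.2*(-28808)) = -15924.4
        assert ddq[20.0] == pytest.approx(-15924.4, abs=1e-9)

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            delta_delta_q({10.0: 1.0, 100.0: 2.0})


class TestExpansivityModels:
    def test_zero_deltaq_gives_solvent_alpha(self):
        p = ExpansivityParams(T_K=298.65, dp_bar=4.0, alpha0=2.57e-4,
                              v_part_m3_per_kg=1e-3, g_s_kg=1e-3)
        assert alpha_bar_from_deltaq(0.0, p) == pytest.approx(p.alpha0)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = ExpansivityParams(T_K=rng.uniform(280, 340), dp_bar=4.0,
                                  alpha0=rng.uniform(1e-4, 1e-3),
                                  alpha_bar=rng.uniform(1e-4, 2e-3),
                                  v_part_m3_per_kg=rng.uniform(5e-4, 2e-3),
                                  g_s_kg=rng.uniform(1e-5, 1e-3))
            dq = deltaq_from_alpha_bar(p)
            assert alpha_bar_from_deltaq(dq, p) == pytest.approx(p.alpha_bar, rel=1e-12)

    def test_doubling_dp_doubles_heat(self):
        p = ExpansivityParams(T_K=300.0, dp_bar=4.0, alpha0=2.6e-4, alpha_bar=8e-4,
                              v_part_m3_per_kg=1.2e-3, g_s_kg=1e-4)
        p2 = ExpansivityParams(**{**p.__dict__, "dp_bar": 8.0})
        assert deltaq_from_alpha_bar(p2) == pytest.approx(2 * deltaq_from_alpha_bar(p))

    def test_hydration_model_collapses(self):
        p = ExpansivityParams(T_K=300.0, dp_bar=4.0, x_s=0.0, a_prime_uJ=12.5)
        assert eval_hydration_model(p) == pytest.approx(12.5)
        p = ExpansivityParams(T_K=300.0, dp_bar=4.0, x_s=0.1, n=0.0,
                              v_b=1.8e-5, alpha_b=2.6e-4, v_s=7.7e-5, alpha_s=1.1e-3)
        expect = 300.0 * 4.0e5 * 0.1 * (1.8e-5 * 2.6e-4 - 7.7e-5 * 1.1e-3) * 1e6
        assert eval_hydration_model(p) == pytest.approx(expect, rel=1e-12)

    def test_hydration_round_trips(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = ExpansivityParams(
                T_K=rng.uniform(280, 340), dp_bar=4.0, x_s=rng.uniform(0.01, 0.4),
                n=rng.uniform(1, 20), v_b=1.807e-5, alpha_b=2.57e-4,
                v_h_bar=rng.uniform(1.5e-5, 2e-5), alpha_h_bar=rng.uniform(1e-4, 1e-3),
                v_s=7.69e-5, alpha_s=rng.uniform(5e-4, 2e-3),
                a_prime_uJ=rng.uniform(-50, 50))
            dq = eval_hydration_model(p)
            assert invert_hydration_model(dq, p, "alpha_h") == pytest.approx(p.alpha_h_bar, rel=1e-10)
            assert invert_hydration_model(dq, p, "n") == pytest.approx(p.n, rel=1e-10)
            assert invert_hydration_model(dq, p, "a_prime") == pytest.approx(p.a_prime_uJ, rel=1e-8, abs=1e-8)

    def test_solve_for_n_zero_coefficient_rejected(self):
        p = ExpansivityParams(T_K=300.0, dp_bar=4.0, x_s=0.1,
                              v_b=1.8e-5, alpha_b=2.6e-4, v_h_bar=1.8e-5, alpha_h_bar=2.6e-4)
        with pytest.raises(ZeroDivisionError, match="coefficient of n"):
            invert_hydration_model(0.0, p, "n")


class TestHepler:
    def test_linear_volume_zero(self):
        vp = VolumePolynomial((1.0, 0.5))
        assert hepler_gradient(vp, 300.0) == 0.0

    def test_quadratic_closed_form(self):
        c2 = 3.7e-8
        vp = VolumePolynomial((1.0, 0.0, c2))
        for T in (280.0, 300.0, 340.0):
            assert hepler_gradient(vp, T) == pytest.approx(-2.0 * c2 * T, rel=1e-14)

    def test_quartic_matches_finite_differences(self):
        coeffs = (2.0, -1e-3, 4e-6, -2e-9, 5e-13)
        vp = VolumePolynomial(coeffs)
        T = 310.0
        # Richardson-extrapolated central differences (exact through h^4)
        def d2(h):
            return (vp(T + h) - 2 * vp(T) + vp(T - h)) / h ** 2
        oracle = (4.0 * d2(0.5) - d2(1.0)) / 3.0
        assert hepler_gradient(vp, T) == pytest.approx(-T * oracle, rel=1e-8)

    def test_negative_wherever_volume_convex(self):
        vp = VolumePolynomial((1.0, -2e-4, 1e-6))  # V'' = 2e-6 > 0
        T = np.linspace(280.0, 340.0, 7)
        assert (hepler_gradient(vp, T) < 0).all()

    def test_tabulated_first_derivative_form(self):
        T = np.linspace(280.0, 340.0, 61)
        v_alpha = 2e-3 + 1e-5 * (T - 280.0)  # linear product => constant derivative
        out = hepler_gradient_tabulated(T, v_alpha)
        np.testing.assert_allclose(out, -T * 1e-5, rtol=1e-10)
        with pytest.raises(ValueError, match="3 tabulated"):
            hepler_gradient_tabulated([280.0, 281.0], [1.0, 2.0])
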