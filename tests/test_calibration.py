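"""Calibration pipeline: F-v point selection, PASA NLS fit, ND rule, delta estimates."""

import warnings

import numpy as np
import pytest

from sprintfatigue import (
    CrankGeometry,
    LinearFvProfile,
    SprintTrace,
    calibrate_sprint,
    detect_nd,
    estimate_delta,
    fit_pasa,
    goodness,
    optimize_delta,
    pasa_power,
    select_fatigue_free_points,
)
from sprintfatigue.calibration import evaluate_pesa, peak_power
from sprintfatigue.synthetic import NoiseSpec, generate_motoric, generate_sprint, sample_athlete


def _trace_from_powers(powers, target=None, cadence=135.0):
    powers = np.asarray(powers, float)
    n = powers.size
    dt = 60.0 / cadence
    geo = CrankGeometry(0.17)
    speed = float(geo.tangential_speed(cadence))
    return SprintTrace(
        index_n=np.arange(1, n + 1),
        t_s=dt * np.arange(1, n + 1),
        cadence_rpm=np.full(n, cadence),
        force_N=powers / speed,
        power_W=powers,
        target_cadence_rpm=target,
        geometry=geo,
    )


class TestGoodness:
    def test_perfect_prediction(self):
        obs = np.array([100.0, 200.0, 300.0])
        rmse, r2 = goodness(obs, obs)
        assert rmse == 0.0 and r2 == 1.0

    def test_mean_prediction_has_zero_r2(self):
        obs = np.array([100.0, 200.0, 300.0])
        rmse, r2 = goodness(obs, np.full(3, 200.0))
        assert r2 == pytest.approx(0.0)

    def test_hand_rmse(self):
        obs = np.array([10.0, 20.0])
        pred = obs - np.array([3.0, -4.0])
        rmse, _ = goodness(obs, pred)
        assert rmse == pytest.approx(3.5355, abs=5e-4)

    def test_constant_observations_with_error_have_undefined_fit(self):
        _, r2 = goodness(np.array([10.0, 10.0]), np.array([9.0, 11.0]))
        assert r2 == float("-inf")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            goodness(np.zeros(3), np.zeros(4))


class TestDetectNd:
    def test_hand_example(self):
        # the sustained decline starts right after the 1300 peak
        powers = [1250.0, 1270.0, 1290.0, 1300.0, 1295.0, 1280.0, 1270.0, 1255.0, 1240.0, 1230.0]
        trace = _trace_from_powers(powers)
        assert detect_nd(trace, scan_from_target=False) == 4

    def test_monotone_increasing_is_an_error(self):
        trace = _trace_from_powers(np.linspace(100.0, 1000.0, 30))
        with pytest.raises(ValueError):
            detect_nd(trace, scan_from_target=False)

    def test_ties_break_a_run(self):
        powers = [1300.0, 1295.0, 1295.0, 1280.0, 1270.0, 1260.0, 1250.0, 1240.0, 1230.0]
        trace = _trace_from_powers(powers)
        # run cannot start at stroke 1 (tie at strokes 2-3); first strict run starts at 3
        assert detect_nd(trace, scan_from_target=False) == 3

    def test_pesa_truth_round_trip(self, mean_athlete, protocol, no_noise):
        trace = generate_sprint(mean_athlete, protocol, no_noise, truth="pesa")
        assert detect_nd(trace) == mean_athlete.pesa.nd_strokes == 5

    def test_shift_invariance(self):
        powers = np.array(
            [1250.0, 1270.0, 1290.0, 1300.0, 1295.0, 1280.0, 1270.0, 1255.0, 1240.0, 1230.0]
        )
        a = detect_nd(_trace_from_powers(powers), scan_from_target=False)
        b = detect_nd(_trace_from_powers(powers + 500.0), scan_from_target=False)
        assert a == b


class TestEstimateDelta:
    def test_constant_ratio_sequence(self):
        powers = np.concatenate([[1000.0] * 5, 1000.0 * 0.99 ** np.arange(1, 40)])
        trace = _trace_from_powers(powers)
        est = estimate_delta(trace, nd=5, window_end_s=15.0)
        assert est.delta == pytest.approx(0.01, abs=1e-12)
        assert est.sd == pytest.approx(0.0, abs=1e-12)

    def test_exponential_truth_recovery(self, mean_athlete, protocol, no_noise):
        trace = generate_sprint(mean_athlete, protocol, no_noise, truth="pesa")
        est = estimate_delta(trace, nd=5, window_end_s=45.0)
        assert est.delta == pytest.approx(0.0145, abs=1e-12)

    def test_pasa_truth_delta15_in_physiological_band(self, mean_athlete, protocol):
        trace = generate_sprint(mean_athlete, protocol, NoiseSpec(cv=0.03), truth="pasa", seed=5)
        est = estimate_delta(trace, nd=5, window_end_s=15.0)
        assert 0.010 <= est.delta <= 0.020

    def test_empty_window_is_an_error(self):
        trace = _trace_from_powers(np.linspace(1300.0, 300.0, 30))
        with pytest.raises(ValueError):
            estimate_delta(trace, nd=29, window_end_s=5.0)


class TestOptimizeDelta:
    def test_noise_free_recovery_is_exact(self, mean_athlete, protocol, no_noise):
        trace = generate_sprint(mean_athlete, protocol, no_noise, truth="pesa")
        delta_opt, fit = optimize_delta(trace, nd=5)
        assert delta_opt == pytest.approx(0.0145, abs=1e-6)
        assert fit.rmse_W < 1e-4

    def test_optimal_delta_beats_empirical_variants(self, mean_athlete, protocol):
        trace = generate_sprint(mean_athlete, protocol, NoiseSpec(cv=0.03), truth="pasa", seed=9)
        nd = 5
        _, fit_opt = optimize_delta(trace, nd, fit_peak=False)
        for window in (15.0, 45.0):
            est = estimate_delta(trace, nd, window)
            assert fit_opt.rmse_W <= evaluate_pesa(trace, est.delta, nd).rmse_W + 1e-9

    def test_scale_invariance(self, mean_athlete, protocol):
        trace = generate_sprint(mean_athlete, protocol, NoiseSpec(cv=0.03), truth="pasa", seed=3)
        d1, _ = optimize_delta(trace, nd=5)
        scaled = SprintTrace(
            index_n=trace.index_n,
            t_s=trace.t_s,
            cadence_rpm=trace.cadence_rpm,
            force_N=trace.force_N * 2.0,
            power_W=trace.power_W * 2.0,
            target_cadence_rpm=trace.target_cadence_rpm,
            geometry=trace.geometry,
        )
        d2, _ = optimize_delta(scaled, nd=5)
        assert d1 == pytest.approx(d2, rel=1e-6)


class TestSelectPoints:
    def test_counts_acceleration_plus_motoric(self, mean_athlete, protocol, no_noise):
        iso = generate_sprint(mean_athlete, protocol, no_noise)
        motoric = generate_motoric(mean_athlete, 0, protocol, no_noise)
        points = select_fatigue_free_points(iso, [motoric], max_motoric=1)
        assert sum(p.source == "acceleration" for p in points) == 4
        assert sum(p.source == "motoric" for p in points) == 1

    def test_without_motoric_warns(self, mean_athlete, protocol, no_noise):
        iso = generate_sprint(mean_athlete, protocol, no_noise)
        with pytest.warns(UserWarning, match="no motoric"):
            points = select_fatigue_free_points(iso, [])
        assert all(p.source == "acceleration" for p in points)

    def test_noise_free_points_lie_on_the_generating_line(
        self, mean_athlete, protocol, no_noise
    ):
        iso = generate_sprint(mean_athlete, protocol, no_noise)
        motoric = generate_motoric(mean_athlete, 0, protocol, no_noise)
        for p in select_fatigue_free_points(iso, [motoric]):
            expected = mean_athlete.fv.fmax_N + mean_athlete.fv.slope_a * p.cadence_rpm
            assert p.force_N == pytest.approx(expected, rel=1e-12)


class TestFitPasa:
    def test_noise_free_identifiability(self, mean_athlete, protocol, no_noise):
        trace = generate_sprint(mean_athlete, protocol, no_noise, truth="pasa")
        fit = fit_pasa(trace, mean_athlete.fv)
        assert fit.params.tau_s == pytest.approx(38.0, rel=1e-3)
        assert fit.params.cf_N == pytest.approx(483.0, rel=1e-3)
        assert fit.params.td_s == pytest.approx(2.55, rel=1e-3)
        assert fit.rmse_W < 1e-6
        assert not fit.flags["boundary"]

    def test_noisy_single_athlete_within_tolerance(self, mean_athlete, protocol):
        trace = generate_sprint(
            mean_athlete, protocol, NoiseSpec(cv=0.03), truth="pasa", seed=17
        )
        fit = fit_pasa(trace, mean_athlete.fv)
        assert abs(fit.params.tau_s - 38.0) <= 6.0
        assert abs(fit.params.cf_N - 483.0) <= 50.0

    def test_refit_fmax_mode_keeps_identity(self, mean_athlete, protocol, no_noise):
        # With F_max freed and no plateau revolutions in the fit window,
        # (A_F, TD) are identified only jointly; the identity A_F = F_max - C_F
        # and the asymptote/time constant must still hold exactly.
        trace = generate_sprint(mean_athlete, protocol, no_noise, truth="pasa")
        fit = fit_pasa(trace, mean_athlete.fv, fix_fmax=False)
        p = fit.params
        assert p.af_N == pytest.approx(p.base.fmax_N - p.cf_N, rel=1e-12)
        assert p.cf_N == pytest.approx(483.0, rel=5e-3)
        assert p.tau_s == pytest.approx(38.0, rel=5e-3)
        assert fit.rmse_W < 1e-3

    def test_constraint_boundary_is_pinned_and_flagged(self, geometry):
        # data generated from an inadmissible truth (C_F > A_F): the constrained
        # optimum must pin C_F at the ordering boundary F_max/2
        fv = LinearFvProfile(slope_a=-4.53, fmax_N=1207.0)
        cadence, cf_true, tau, td = 135.0, 850.0, 30.0, 2.5
        dt = 60.0 / cadence
        t = dt * np.arange(1, 100)
        fmax_t = (1207.0 - cf_true) * np.exp(np.minimum(0.0, -(t - td) / tau)) + cf_true
        power = (fv.slope_a * cadence + fmax_t) * float(geometry.tangential_speed(cadence))
        trace = SprintTrace(
            index_n=np.arange(1, 100),
            t_s=t,
            cadence_rpm=np.full(99, cadence),
            force_N=power / float(geometry.tangential_speed(cadence)),
            power_W=power,
            target_cadence_rpm=cadence,
            geometry=geometry,
        )
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_pasa(trace, fv)
        assert fit.flags["boundary"]
        assert fit.params.cf_N == pytest.approx(1207.0 / 2.0, rel=1e-6)

    def test_too_few_revolutions(self, geometry):
        trace = _trace_from_powers(np.linspace(1300, 1200, 5), target=135.0)
        with pytest.raises(ValueError):
            fit_pasa(trace, LinearFvProfile(-4.53, 1207.0))


class TestFullCalibration:
    def test_rmse_hierarchy_on_time_based_truth(self):
        """On time-decay truth: PASA <= PESAopt <= PESA(delta15/delta45) in the mean."""
        from sprintfatigue.synthetic import generate_cohort

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = generate_cohort(4, seed=20260925, truth="pasa")
            reports = [calibrate_sprint(tr["isokinetic"], tr["motoric"]) for _, tr in cohort]
        mean = lambda key: np.mean([r[key] for r in reports])
        assert mean("RMSE_PASA") <= mean("RMSE_PESAopt") <= mean("RMSE_PESA15")
        assert mean("RMSE_PESAopt") <= mean("RMSE_PESA45")

    def test_report_contains_conventional_parameter_names(self, mean_athlete, protocol, no_noise):
        iso = generate_sprint(mean_athlete, protocol, no_noise)
        motoric = [generate_motoric(mean_athlete, s, protocol, no_noise) for s in (0, 1)]
        report = calibrate_sprint(iso, motoric)
        for key in ("Fmax", "a", "Pmax", "PRopt", "AF", "tauF", "CF", "TD",
                    "Ppeak", "Delta15", "Delta45", "DeltaOpt", "ND", "R2", "RMSE"):
            assert key in report
        assert report["Fmax"] == pytest.approx(1207.0, rel=1e-9)
        assert report["ND"] == 5
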