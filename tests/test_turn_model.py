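import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemotax.turn_model import (BootstrapComparison, Run, RunEnsemble,
                                 TurnGlmParams, bootstrap_compare,
                                 control_inputs, ensemble_loglik,
                                 estimate_turn_probability, fit_glm,
                                 lambda_of, likelihood_eval_times,
                                 resample_errorbars, run_likelihood,
                                 turn_triggered_average)


def exponential_ensemble(rate, n, seed=0, t_max=60.0, dt=1 / 30):
    """Runs with i.i.d. exponential durations (continuous-time rate)."""
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n):
        d = rng.exponential(1.0 / rate)
        d = max(d, 2 * dt)
        if d >= t_max:
            runs.append(Run(0.0, t_max, False))
        else:
            runs.append(Run(0.0, d, True))
    return RunEnsemble(runs)


class TestLambda:
    def test_reference_value_at_zero_rate(self):
        glm = TurnGlmParams.test_model()
        lam = lambda_of(glm, 0.0)
        assert lam == pytest.approx(1.0 / (1.0 + np.exp(0.3534)), abs=1e-6)
        assert lam == pytest.approx(0.4126, abs=5e-4)

    def test_high_rate_suppresses_turning(self):
        glm = TurnGlmParams.test_model()
        assert lambda_of(glm, 1000.0) < 1e-10
        ys = np.linspace(0, 30, 50)
        assert np.all(np.diff(lambda_of(glm, ys)) < 0)  # monotone in input

    def test_neutral_point(self):
        glm = TurnGlmParams(gamma0=0.0, gamma1=-0.1)
        assert lambda_of(glm, 0.0) == pytest.approx(0.5)

    def test_rectified_link_clamps(self):
        glm = TurnGlmParams.rectified_test_model()
        assert lambda_of(glm, 100.0) == 0.0  # negative combination rectified
        assert lambda_of(glm, 0.0) == pytest.approx(0.3762)
        big = TurnGlmParams(gamma0=2.0, gamma1=0.0, link="rectified_linear")
        assert lambda_of(big, 0.0) == 1.0  # capped

    def test_derivative_control_requires_derivative(self):
        glm = TurnGlmParams.stimulus_derivative_control()
        with pytest.raises(ValueError, match="derivative"):
            lambda_of(glm, np.ones(5))
        out = lambda_of(glm, np.full(5, 50.0), derivative=np.zeros(5))
        assert np.all((0 < out) & (out < 1))

    def test_yaml_roundtrip(self, tmp_path):
        glm = TurnGlmParams.stimulus_derivative_control()
        glm.to_yaml(tmp_path / "glm.yaml")
        assert TurnGlmParams.from_yaml(tmp_path / "glm.yaml") == glm

    def test_table_defaults(self):
        c = TurnGlmParams.stimulus_control()
        assert (c.gamma0, c.gamma1) == (-0.8156, -0.0114)
        d = TurnGlmParams.stimulus_derivative_control()
        assert d.gamma2 == -0.0214

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(g0=st.floats(-5, 5), g1=st.floats(-1, 1),
           y=st.floats(0, 100))
    def test_logit_output_is_probability(self, g0, g1, y):
        lam = lambda_of(TurnGlmParams(gamma0=g0, gamma1=g1), y)
        assert 0.0 <= lam <= 1.0


class TestTurnProbabilityEstimator:
    def test_simple_fraction(self):
        runs = [Run(0, 0.8, True)] * 2 + [Run(0, 5.0, True)] * 8
        tp = estimate_turn_probability(runs)
        i = np.argmin(np.abs(tp.t - 0.6))
        assert tp.lam[i] == pytest.approx(0.2)

    def test_all_censored_gives_zero(self):
        runs = [Run(0, 10.0, False) for _ in range(20)]
        tp = estimate_turn_probability(runs)
        assert np.nansum(tp.lam) == 0.0

    def test_exponential_durations_flat_hazard(self):
        rate = 0.4
        tp = estimate_turn_probability(exponential_ensemble(rate, 4000))
        expected = 1.0 - np.exp(-rate)
        m = tp.reliable & (tp.t < 5.0)
        assert np.nanmean(tp.lam[m]) == pytest.approx(expected, abs=0.02)
        assert np.nanstd(tp.lam[m]) < 0.05

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            estimate_turn_probability([])

    def test_reliability_mask_drops_late_windows(self):
        tp = estimate_turn_probability(exponential_ensemble(0.5, 200))
        assert not tp.reliable[-1]
        assert tp.reliable[int(0.6 * 30)]


class TestResampling:
    def test_identical_runs_zero_std(self):
        runs = [Run(0, 3.0, True) for _ in range(40)]
        std = resample_errorbars(runs, n_resamples=20, seed=0)
        assert np.nanmax(std) == 0.0

    def test_reproducible_for_fixed_seed(self):
        ens = exponential_ensemble(0.4, 100)
        a = resample_errorbars(ens, seed=5)
        b = resample_errorbars(ens, seed=5)
        assert np.array_equal(a, b, equal_nan=True)

    def test_std_shrinks_with_ensemble_size(self):
        small = exponential_ensemble(0.4, 100, seed=1)
        large = exponential_ensemble(0.4, 400, seed=2)
        s_small = resample_errorbars(small, seed=0)
        s_large = resample_errorbars(large, seed=0)
        m = min((~np.isnan(s_small)).sum(), (~np.isnan(s_large)).sum(), 60)
        ratio = np.nanmean(s_small[:m]) / np.nanmean(s_large[:m])
        assert 1.4 < ratio < 2.9  # ~ sqrt(4) = 2


class TestGlmFit:
    def test_exact_inversion_of_known_glm(self):
        # logit(lambda) built exactly from the GLM is recovered to
        # machine precision by the regression
        glm = TurnGlmParams.test_model()
        t = np.arange(0, 10, 1 / 30)
        y_input = 10.0 * np.exp(-0.5 * ((t - 5) / 2.0) ** 2)
        lam = lambda_of(glm, y_input)
        from chemotax.turn_model import TurnProbability
        tp = TurnProbability(t, lam, np.full(len(t), 10**6),
                             np.ones(len(t), bool))
        rec = fit_glm([(tp, y_input)])
        assert rec.gamma0 == pytest.approx(glm.gamma0, abs=1e-4)
        assert rec.gamma1 == pytest.approx(glm.gamma1, abs=1e-5)

    def test_profile_regression_recovers_within_resampling_ci(self):
        # OLS on simulated turn-probability profiles recovers the
        # generating coefficients to within the resampling uncertainty
        from chemotax.synthetic import make_turn_ensemble
        from chemotax.transduction import RateTrace

        glm = TurnGlmParams.test_model()
        t = np.arange(0, 16, 1 / 30)
        traces = [RateTrace(t, 4.5 + a * np.sin(2 * np.pi * t / 8.0) ** 2)
                  for a in (6.0, 12.0, 16.0)]
        ensembles = [make_turn_ensemble(glm, [tr], 400, seed=50 + i)
                     for i, tr in enumerate(traces)]

        def estimate(subsample_seed=None):
            profiles = []
            for tr, ens in zip(traces, ensembles):
                runs = list(ens)
                if subsample_seed is not None:
                    rng = np.random.default_rng(subsample_seed)
                    pick = rng.choice(len(runs), len(runs) // 2, replace=False)
                    runs = [runs[j] for j in pick]
                tp = estimate_turn_probability(runs)
                y_sm = np.convolve(tr.y, np.ones(30) / 30.0, mode="same")
                profiles.append((tp, np.interp(tp.t, t, y_sm)))
            return fit_glm(profiles)

        point = estimate()
        reps = [estimate(subsample_seed=s) for s in range(12)]
        sd0 = np.std([r.gamma0 for r in reps])
        sd1 = np.std([r.gamma1 for r in reps])
        assert abs(point.gamma0 - glm.gamma0) < 3 * sd0
        assert abs(point.gamma1 - glm.gamma1) < 3 * sd1

    def test_mle_fit_recovers_generating_coefficients(self):
        from chemotax.synthetic import make_turn_ensemble
        from chemotax.turn_model import fit_glm_mle
        from chemotax.transduction import RateTrace

        glm = TurnGlmParams.test_model()
        t = np.arange(0, 20, 1 / 30)
        trace = RateTrace(t, 8.0 + 8.0 * np.sin(2 * np.pi * t / 10.0) ** 2)
        ens = make_turn_ensemble(glm, [trace], 3000, seed=12)
        rec = fit_glm_mle(ens)
        assert rec.gamma0 == pytest.approx(glm.gamma0, abs=0.06)
        assert rec.gamma1 == pytest.approx(glm.gamma1, rel=0.08)

    def test_constant_input_rejected(self):
        from chemotax.turn_model import TurnProbability
        t = np.arange(0, 5, 1 / 30)
        tp = TurnProbability(t, np.full(len(t), 0.3), np.full(len(t), 100),
                             np.ones(len(t), bool))
        with pytest.raises(ValueError, match="degenerate"):
            fit_glm([(tp, np.full(len(t), 2.0))])


class TestRunLikelihood:
    def test_eval_times_of_fractional_run(self):
        times = likelihood_eval_times(5.6)
        assert np.allclose(times, [0.6, 1.6, 2.6, 3.6, 4.6])
        assert len(times) == 5

    def test_integer_duration_anchored_at_zero(self):
        assert np.allclose(likelihood_eval_times(3.0), [0.0, 1.0, 2.0])

    def test_constant_half_probability(self):
        run = Run(0, 5.6, True, lam=np.full(200, 0.5), dt=0.033)
        assert run_likelihood(run) == pytest.approx(0.5**5)

    def test_censored_run_with_zero_hazard(self):
        run = Run(0, 7.3, False, lam=np.zeros(250), dt=0.033)
        assert run_likelihood(run) == 1.0

    def test_certain_turn_in_first_bin(self):
        run = Run(0, 1.4, True, lam=np.ones(60), dt=0.033)
        assert run_likelihood(run) == 1.0

    def test_subsecond_run_rejected(self):
        with pytest.raises(ValueError):
            likelihood_eval_times(0.7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dur=st.floats(1.0, 20.0), lam=st.floats(0.0, 1.0),
           terminal=st.booleans())
    def test_probability_bounds_and_factor_count(self, dur, lam, terminal):
        times = likelihood_eval_times(dur)
        assert len(times) == int(np.floor(dur / 1.0 + 1e-9))
        n = max(2, int(dur * 30) + 1)
        run = Run(0, dur, terminal, lam=np.full(n, lam), dt=dur / (n - 1))
        p = run_likelihood(run)
        assert 0.0 <= p <= 1.0


class TestEnsembleLoglik:
    def test_sum_of_logs(self):
        r1 = Run(0, 2.5, True, lam=np.full(80, 0.2), dt=0.033)
        r2 = Run(0, 3.5, False, lam=np.full(110, 0.2), dt=0.033)
        res = ensemble_loglik([r1, r2])
        assert res.logl == pytest.approx(np.log(run_likelihood(r1))
                                         + np.log(run_likelihood(r2)))

    def test_duplication_doubles_loglik(self):
        runs = [Run(0, 2.5, True, lam=np.full(80, 0.3), dt=0.033)] * 3
        once = ensemble_loglik(runs[:1]).logl
        assert ensemble_loglik(runs).logl == pytest.approx(3 * once)

    def test_zero_probability_reported(self):
        run = Run(0, 2.5, False, lam=np.ones(80), dt=0.033)  # certain turn
        res = ensemble_loglik([run])
        assert res.logl == -np.inf
        assert res.zero_runs == [0]


class TestBootstrap:
    @pytest.fixture(scope="class")
    def glm_ensemble(self):
        from chemotax.synthetic import make_turn_ensemble
        from chemotax.transduction import RateTrace

        glm = TurnGlmParams.test_model()
        t = np.arange(0, 20, 1 / 30)
        y = 8.0 + 6.0 * np.sin(2 * np.pi * t / 10.0)
        ens = make_turn_ensemble(glm, [RateTrace(t, y)], 500, seed=4)
        return glm, ens.filtered()  # likelihood defined on runs >= 1 s

    def test_self_comparison_is_degenerate(self, glm_ensemble):
        _, ens = glm_ensemble
        cmp = bootstrap_compare(ens, None, None, n=200, seed=0)
        assert np.allclose(cmp.deltas, 0.0)
        assert cmp.p_value == 0.0
        assert cmp.p_report == "< 0.005"

    def test_generating_model_beats_constant_control(self, glm_ensemble):
        glm, ens = glm_ensemble
        mean_lam = float(np.mean([r.lam.mean() for r in ens]))

        def control(run):
            return np.full(len(run.lam), mean_lam)

        cmp = bootstrap_compare(ens, None, control, n=2000, seed=1)
        assert cmp.p_value < 0.01

    def test_invariant_to_run_order(self, glm_ensemble):
        glm, ens = glm_ensemble
        mean_lam = float(np.mean([r.lam.mean() for r in ens]))

        def control(run):
            return np.full(len(run.lam), mean_lam)

        a = bootstrap_compare(ens, None, control, n=500, seed=7)
        shuffled = RunEnsemble(list(ens)[::-1])
        b = bootstrap_compare(shuffled, None, control, n=500, seed=7)
        assert a.p_value == b.p_value


class TestTurnTriggeredAverage:
    def test_identical_traces_average_to_trace(self):
        lam = np.linspace(0.1, 0.5, 90)
        runs = [Run(0, 3.0, True, lam=lam.copy(), dt=1 / 30) for _ in range(5)]
        tta = turn_triggered_average(runs, lookback=2.0)
        assert np.nanmax(tta.sem) == pytest.approx(0.0, abs=1e-12)
        expected_end = lam[-1]
        assert tta.mean[-1] == pytest.approx(expected_end, abs=1e-6)

    def test_short_runs_contribute_partial_lags(self):
        long = Run(0, 4.0, True, lam=np.full(121, 0.2), dt=1 / 30)
        short = Run(0, 1.5, True, lam=np.full(46, 0.4), dt=1 / 30)
        tta = turn_triggered_average([long, short], lookback=3.0)
        assert tta.n[0] == 1  # only the long run covers -3 s
        assert tta.n[-1] == 2
        assert tta.mean[-1] == pytest.approx(0.3)

    def test_requires_turn_terminated_runs(self):
        with pytest.raises(ValueError):
            turn_triggered_average([Run(0, 3.0, False,
                                        lam=np.full(91, 0.1), dt=1 / 30)])


class TestControlInputs:
    def test_palindromic_stimulus_invariant_under_reversal(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        assert np.allclose(control_inputs(x, "time_reversed"), x)

    def test_double_reversal_is_identity(self):
        x = np.arange(30.0)
        back = control_inputs(control_inputs(x, "time_reversed"),
                              "time_reversed")
        assert np.array_equal(back, x)

    def test_constant_stimulus_all_inputs_coincide(self):
        x = np.full(50, 3.3)
        assert np.allclose(control_inputs(x, "time_reversed"), x)
        assert np.allclose(control_inputs(x, "constant_mean"), x)

    def test_constant_mean_uses_rate_trace(self):
        x = np.arange(10.0)
        out = control_inputs(x, "constant_mean", rate_trace=np.full(10, 7.0))
        assert np.allclose(out, 7.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            control_inputs(np.arange(3.0), "shuffled")
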