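"""Stimulus-to-behavior GLMs and run-ensemble statistics.

The probability λ(t) that a surviving run terminates in a turn within a
1-s window is modelled as a logit-linear function of an input signal — the
ODE-predicted OSN firing rate for the test model, or the raw stimulus
(optionally with its single-frame derivative) for the control models:

    logit λ(t) = γ₀ + γ₁·input(t) [+ γ₂·dx/dt]

A rectified-linear link (λ = max(0, γ₀+γ₁·input), capped at 1) is kept for
the no-logit comparison.  The module also provides the nonparametric
turn-probability estimator over run ensembles, subsample resampling for
error bars, the per-run likelihood on 1-s bins, bootstrap model
comparison, turn-triggered averages and the time-reversed /
constant-activity control inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TurnGlmParams",
    "Run",
    "RunEnsemble",
    "TurnProbability",
    "lambda_of",
    "estimate_turn_probability",
    "resample_errorbars",
    "fit_glm",
    "fit_glm_mle",
    "likelihood_eval_times",
    "run_likelihood",
    "ensemble_loglik",
    "bootstrap_compare",
    "turn_triggered_average",
    "control_inputs",
]

DEFAULT_DT = 1.0 / 30.0


@dataclass
class TurnGlmParams:
    """Coefficients of a turn-probability GLM.

    ``input_kind`` declares what the linear predictor consumes: the
    predicted firing rate (test model), the stimulus intensity, or the
    stimulus plus its frame derivative; ``gamma2`` exists only for the
    latter.  ``link`` is ``"logit"`` or ``"rectified_linear"``.
    """

    gamma0: float
    gamma1: float
    gamma2: float | None = None
    input_kind: str = "rate"
    link: str = "logit"

    def __post_init__(self):
        if self.input_kind not in ("rate", "stimulus", "stimulus+derivative"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.link not in ("logit", "rectified_linear"):
            raise ValueError(f"unknown link {self.link!r}")
        if (self.gamma2 is not None) != (self.input_kind == "stimulus+derivative"):
            raise ValueError("gamma2 present iff input_kind is "
                             "'stimulus+derivative'")
        for g in (self.gamma0, self.gamma1):
            if not np.isfinite(g):
                raise ValueError("coefficients must be finite")

    # Fitted coefficient sets (training: open-loop light-ramp suite).
    @classmethod
    def test_model(cls) -> "TurnGlmParams":
        """Integrated stimulus-to-behavior model on the predicted rate."""
        return cls(gamma0=-0.3534, gamma1=-0.1523, input_kind="rate")

    @classmethod
    def stimulus_control(cls) -> "TurnGlmParams":
        return cls(gamma0=-0.8156, gamma1=-0.0114, input_kind="stimulus")

    @classmethod
    def stimulus_derivative_control(cls) -> "TurnGlmParams":
        return cls(gamma0=-0.8200, gamma1=-0.0013, gamma2=-0.0214,
                   input_kind="stimulus+derivative")

    @classmethod
    def rectified_test_model(cls) -> "TurnGlmParams":
        """No-logit variant fitted on the same ramps."""
        return cls(gamma0=0.3762, gamma1=-0.0198, input_kind="rate",
                   link="rectified_linear")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TurnGlmParams":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def lambda_of(params: TurnGlmParams, inputs, derivative=None) -> np.ndarray:
    """Turn probability per 1-s window from the GLM linear predictor."""
    inputs = np.asarray(inputs, float)
    z = params.gamma0 + params.gamma1 * inputs
    if params.input_kind == "stimulus+derivative":
        if derivative is None:
            raise ValueError("input_kind 'stimulus+derivative' requires the "
                             "derivative trace")
        z = z + params.gamma2 * np.asarray(derivative, float)
    elif derivative is not None:
        raise ValueError("derivative given but input_kind does not use it")
    if params.link == "logit":
        return 1.0 / (1.0 + np.exp(-z))
    return np.clip(z, 0.0, 1.0)


@dataclass
class Run:
    """A single run: forward crawl between two reorientation events.

    Times are seconds; ``turn_terminal`` is True when the run ended in a
    detected turn, False when censored (trajectory end, tracking loss).
    ``input`` optionally carries the per-frame model input over the run
    (rate or stimulus), ``lam`` the per-frame predicted turn probability;
    both sampled at ``dt``.
    """

    start: float
    end: float
    turn_terminal: bool
    input: np.ndarray | None = None
    lam: np.ndarray | None = None
    dt: float = DEFAULT_DT
    traj_id: int | None = None

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("run must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def times(self) -> np.ndarray:
        """Frame times relative to run onset."""
        n = len(self.lam if self.lam is not None else self.input)
        return np.arange(n) * self.dt


class RunEnsemble(list):
    """A collection of runs with the standard minimum-duration filter."""

    def __init__(self, runs=(), min_duration: float = 1.0):
        super().__init__(runs)
        self.min_duration = min_duration

    def filtered(self) -> "RunEnsemble":
        out = RunEnsemble([r for r in self if r.duration >= self.min_duration],
                          min_duration=self.min_duration)
        return out

    def durations(self) -> np.ndarray:
        return np.array([r.duration for r in self])


@dataclass
class TurnProbability:
    """Nonparametric turn-probability estimate aligned to run onset."""

    t: np.ndarray
    lam: np.ndarray
    n_alive: np.ndarray
    reliable: np.ndarray  # False once fewer than reliability_frac of runs remain


def estimate_turn_probability(
    ensemble,
    window: float = 1.0,
    dt: float = DEFAULT_DT,
    reliability_frac: float = 0.10,
) -> TurnProbability:
    """Sliding-window turn probability from a run ensemble.

    Runs are aligned to their onset.  At each time point the estimate is
    the fraction of the runs surviving at the start of the centred window
    that terminate in a turn within the window; censored runs leave the
    risk set without contributing an event.  Points where fewer than
    ``reliability_frac`` of all runs survive are flagged unreliable.
    """
    runs = list(ensemble)
    if not runs:
        raise ValueError("empty run ensemble")
    dur = np.array([r.duration for r in runs])
    is_turn = np.array([r.turn_terminal for r in runs])
    t = np.arange(0.0, dur.max() + dt / 2, dt)
    half = window / 2.0
    lo = t - half
    hi = t + half
    # alive at window start; events: turn-terminations inside the window
    alive = (dur[None, :] >= lo[:, None]).sum(axis=1)
    ends_in = (dur[None, :] >= lo[:, None]) & (dur[None, :] < hi[:, None])
    events = (ends_in & is_turn[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(alive > 0, events / np.maximum(alive, 1), np.nan)
    reliable = alive >= reliability_frac * len(runs)
    # windows clipped by the run onset cover only part of their nominal
    # 1-s exposure and would bias the estimate low
    reliable &= t >= half
    return TurnProbability(t, lam, alive, reliable)


def resample_errorbars(
    ensemble,
    n_resamples: int = 100,
    seed: int = 0,
    window: float = 1.0,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Per-time std of the turn-probability estimate from resampling.

    Half of the runs are drawn without replacement, ``n_resamples`` times;
    the std across the resampled estimates is returned on the grid of the
    full-ensemble estimate.
    """
    runs = list(ensemble)
    if len(runs) < 4:
        raise ValueError("need at least 4 runs to resample")
    ref = estimate_turn_probability(runs, window=window, dt=dt)
    rng = np.random.default_rng(seed)
    half_n = len(runs) // 2
    acc = np.empty((n_resamples, len(ref.t)))
    for i in range(n_resamples):
        pick = rng.choice(len(runs), size=half_n, replace=False)
        sub = [runs[j] for j in pick]
        tp = estimate_turn_probability(sub, window=window, dt=dt)
        acc[i] = np.interp(ref.t, tp.t, tp.lam,
                           right=np.nan) if len(tp.t) != len(ref.t) else tp.lam
    return np.nanstd(acc, axis=0)


def fit_glm(profiles, weighted: bool = False) -> "TurnGlmParams":
    """Fit GLM coefficients by OLS on the logit of estimated turn
    probabilities.

    ``profiles`` is a list of (TurnProbability, inputs) pairs, one per
    training ramp, where ``inputs`` is an array of shape (n,) or (n, k)
    aligned with the estimate's grid.  λ̂ is clipped to
    [1/(2N), 1 − 1/(2N)] with N the runs alive in each window; only
    reliable windows enter the regression.  ``weighted=True`` weights
    rows by the number of surviving runs.
    """
    import statsmodels.api as sm

    rows_X, rows_y, rows_w = [], [], []
    for tp, inputs in profiles:
        X = np.asarray(inputs, float)
        if X.ndim == 1:
            X = X[:, None]
        if len(X) != len(tp.t):
            raise ValueError("inputs must be aligned with the estimate grid")
        m = tp.reliable & (tp.n_alive > 0) & np.isfinite(tp.lam)
        if not m.any():
            continue
        N = tp.n_alive[m].astype(float)
        lam = np.clip(tp.lam[m], 1.0 / (2 * N), 1.0 - 1.0 / (2 * N))
        rows_X.append(X[m])
        rows_y.append(np.log(lam / (1.0 - lam)))
        rows_w.append(N)
    if not rows_X:
        raise ValueError("no reliable windows to fit")
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    if np.allclose(np.ptp(X, axis=0), 0):
        raise ValueError("degenerate design: constant input")
    exog = sm.add_constant(X)
    model = (sm.WLS(y, exog, weights=np.concatenate(rows_w)) if weighted
             else sm.OLS(y, exog))
    res = model.fit()
    coefs = res.params
    if X.shape[1] == 1:
        return TurnGlmParams(gamma0=float(coefs[0]), gamma1=float(coefs[1]),
                             input_kind="rate")
    return TurnGlmParams(gamma0=float(coefs[0]), gamma1=float(coefs[1]),
                         gamma2=float(coefs[2]),
                         input_kind="stimulus+derivative")


def fit_glm_mle(ensemble, x0=(-0.5, -0.1)) -> "TurnGlmParams":
    """Maximum-likelihood fit of the logit turn GLM from run ensembles.

    Treats every frame of every run as a Bernoulli trial with hazard
    p_f = 1 − (1−λ(input))^dt, the thinning the GLM defines; the last
    frame of a turn-terminated run is the event.  Statistically efficient
    where the windowed-profile regression (:func:`fit_glm`) is the
    estimator the open-loop experiments use.
    """
    from scipy import optimize

    ys, events, dts = [], [], []
    for run in ensemble:
        if run.input is None:
            raise ValueError("runs must carry their per-frame input traces")
        ys.append(np.asarray(run.input, float))
        k = np.zeros(len(run.input))
        if run.turn_terminal:
            k[-1] = 1.0
        events.append(k)
        dts.append(run.dt)
    y = np.concatenate(ys)
    k = np.concatenate(events) > 0
    dt = float(np.median(dts))

    def nll(g):
        lam = 1.0 / (1.0 + np.exp(-(g[0] + g[1] * y)))
        pf = np.clip(1.0 - (1.0 - lam) ** dt, 1e-12, 1.0 - 1e-12)
        return -(np.sum(np.log(pf[k])) + np.sum(np.log1p(-pf[~k])))

    res = optimize.minimize(nll, list(x0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    return TurnGlmParams(gamma0=float(res.x[0]), gamma1=float(res.x[1]),
                         input_kind="rate")


def likelihood_eval_times(duration: float, bin_s: float = 1.0) -> np.ndarray:
    """Evaluation times of the run likelihood: the residual (duration mod
    1 s) then every following second — ⌈duration⌉... i.e. ⌊duration⌋ points
    (5 for a 5.6-s run: 0.6, 1.6, 2.6, 3.6, 4.6 s)."""
    if duration < bin_s:
        raise ValueError("runs shorter than one bin are excluded upstream")
    k = int(np.floor(duration / bin_s + 1e-9))
    resid = duration - k * bin_s
    if resid < 1e-9:  # integer durations: bins anchored at 0
        resid, k = 0.0, k
    return resid + bin_s * np.arange(k)


def run_likelihood(run: Run, lam: np.ndarray | None = None,
                   lam_t: np.ndarray | None = None) -> float:
    """Probability of observing a run under a λ(t) profile (1-s bins).

    Survival factors (1−λ) at every evaluation time except the last, which
    contributes λ if the run ended in a turn and (1−λ) if censored.
    """
    if lam is None:
        lam = run.lam
        if lam is None:
            raise ValueError("run has no λ trace; pass one explicitly")
    lam = np.asarray(lam, float)
    if lam_t is None:
        lam_t = np.arange(len(lam)) * run.dt
    times = likelihood_eval_times(run.duration)
    lam_k = np.interp(times, lam_t, lam)
    p = float(np.prod(1.0 - lam_k[:-1]))
    p *= lam_k[-1] if run.turn_terminal else (1.0 - lam_k[-1])
    return p


@dataclass
class LoglikResult:
    logl: float
    per_run: np.ndarray
    zero_runs: list


def ensemble_loglik(ensemble, model=None) -> LoglikResult:
    """Log-likelihood of a run ensemble: Σ log p_i.

    ``model`` maps a run to its λ trace (callable); by default each run's
    stored λ trace is used.  Runs with p_i = 0 are reported and make the
    total −inf.
    """
    per = np.empty(len(ensemble))
    zeros = []
    for i, run in enumerate(ensemble):
        lam = model(run) if model is not None else None
        p = run_likelihood(run, lam=lam)
        per[i] = -np.inf if p == 0 else np.log(p)
        if p == 0:
            zeros.append(i)
    return LoglikResult(float(per.sum()), per, zeros)


@dataclass
class BootstrapComparison:
    deltas: np.ndarray  # (logL_test - logL_control)/logL_test per resample
    p_value: float
    n_resamples: int
    n_control_wins: int

    @property
    def p_report(self) -> str:
        if self.n_control_wins == 0:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.p_value:g}"


def bootstrap_compare(ensemble, test_model, control_model,
                      n: int = 10000, seed: int = 0) -> BootstrapComparison:
    """Bootstrap comparison of two turn-probability models on one ensemble.

    Runs are resampled with replacement ``n`` times; for each resample the
    relative likelihood difference (logL_test − logL_control)/logL_test is
    recorded, and the p-value is the fraction of resamples in which the
    control is the more likely model (raw log-likelihood comparison).
    Models are callables run → λ trace, or None to use stored traces.
    """
    lt = ensemble_loglik(ensemble, test_model).per_run
    lc = ensemble_loglik(ensemble, control_model).per_run
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(lt), size=(n, len(lt)))
    sum_t = lt[idx].sum(axis=1)
    sum_c = lc[idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        deltas = (sum_t - sum_c) / sum_t
    wins = int(np.sum(sum_c > sum_t))
    return BootstrapComparison(deltas, wins / n, n, wins)


@dataclass
class TurnTriggeredAverage:
    lags: np.ndarray  # negative: seconds before turn onset
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # runs contributing at each lag


def turn_triggered_average(ensemble, lookback: float = 5.0,
                           dt: float = DEFAULT_DT) -> TurnTriggeredAverage:
    """Average of per-run λ traces aligned to turn onset.

    Only turn-terminated runs contribute; shorter runs contribute only to
    the lags they cover.  The SEM is across runs at each lag.
    """
    runs = [r for r in ensemble if r.turn_terminal and r.lam is not None]
    if not runs:
        raise ValueError("no turn-terminated runs with λ traces")
    lags = -np.arange(0.0, lookback + dt / 2, dt)[::-1]
    acc = np.full((len(runs), len(lags)), np.nan)
    for i, run in enumerate(runs):
        tt = run.times()
        covered = lags >= -run.duration + 1e-9
        acc[i, covered] = np.interp(run.duration + lags[covered], tt, run.lam)
    n = np.sum(np.isfinite(acc), axis=0)
    mean = np.nanmean(acc, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(acc, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return TurnTriggeredAverage(lags, mean, sem, n)


def control_inputs(values: np.ndarray, mode: str,
                   rate_trace: np.ndarray | None = None) -> np.ndarray:
    """Uncoupled control inputs for the closed-loop model comparison.

    ``time_reversed``: the whole-trajectory stimulus (or rate) time course
    reversed before run segmentation.  ``constant_mean``: a constant trace
    at the per-trajectory mean of the predicted rate (pass it as
    ``rate_trace``; defaults to ``values``).
    """
    values = np.asarray(values, float)
    if mode == "time_reversed":
        return values[::-1].copy()
    if mode == "constant_mean":
        src = values if rate_trace is None else np.asarray(rate_trace, float)
        return np.full(len(values), float(src.mean()))
    raise ValueError(f"unknown control mode {mode!r}")
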