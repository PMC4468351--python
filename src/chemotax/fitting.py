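"""Parameter estimation of the transduction ODE against PSTHs.

The likelihood is Gaussian with per-bin standard deviations taken from the
PSTH trial spread (floored to avoid zero-variance bins), and each stimulus
protocol carries a free multiplicative scale factor absorbing
across-preparation variability.  Maximisation follows the reference
procedure: Nelder-Mead simplex from multiple seeded starts, each refined
by a Levenberg-Marquardt gradient search on the weighted residuals;
positivity is enforced by optimising log-parameters.  Goodness of fit is
reported as Pearson ρ and CV(RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .stimuli import StimulusTrace
from .transduction import (RateTrace, TransductionParams, integrate)

__all__ = [
    "FitEntry",
    "FitDataset",
    "FitResult",
    "fit",
    "pearson_rho",
    "cv_rmse",
    "psth_from_spikes",
]


def pearson_rho(a, b) -> float:
    """Product-moment correlation between two equal-length traces."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def cv_rmse(observed, predicted) -> float:
    """Root-mean-square error normalised by the mean of the observations."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("traces must have equal length")
    mean = observed.mean()
    if mean == 0:
        raise ValueError("CV(RMSE) undefined for zero-mean observations")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)) / mean)


def psth_from_spikes(
    spike_trains,
    t: np.ndarray,
    window: float = 0.05,
    smooth: bool = False,
    savgol_window: int = 9,
    polyorder: int = 3,
) -> RateTrace:
    """Peristimulus time histogram from per-trial spike times.

    Per time point, the rate of each trial is the spike count inside a
    centred sliding window divided by the window length; the PSTH is the
    across-trial mean, with the across-trial std attached.  Optionally the
    mean is mildly low-pass filtered (Savitzky-Golay).
    """
    trains = [np.sort(np.asarray(tr, float)) for tr in spike_trains]
    if len(trains) == 0:
        raise ValueError("need at least one trial")
    t = np.asarray(t, float)
    half = window / 2.0
    rates = np.empty((len(trains), len(t)))
    for i, tr in enumerate(trains):
        counts = np.searchsorted(tr, t + half, side="left") - np.searchsorted(
            tr, t - half, side="left")
        rates[i] = counts / window
    mean = rates.mean(axis=0)
    std = rates.std(axis=0, ddof=1) if len(trains) > 1 else np.zeros_like(mean)
    if smooth:
        from scipy.signal import savgol_filter
        w = min(savgol_window, len(t) - (1 - len(t) % 2))
        if w > polyorder:
            mean = savgol_filter(mean, w, polyorder)
    return RateTrace(t, mean, std)


@dataclass
class FitEntry:
    """One stimulation protocol: stimulus plus measured PSTH (mean, std)."""

    stimulus: StimulusTrace
    psth: RateTrace

    def __post_init__(self):
        if len(self.stimulus) != len(self.psth):
            raise ValueError("stimulus and PSTH must share a grid")


class FitDataset(list):
    """A list of :class:`FitEntry` with manifest-based text I/O."""

    @classmethod
    def from_manifest(cls, manifest_path) -> "FitDataset":
        """Manifest: delimited text with columns stimulus_file, psth_file
        (paths relative to the manifest)."""
        import pandas as pd
        from pathlib import Path
        from .stimuli import read_trace

        base = Path(manifest_path).parent
        table = pd.read_csv(manifest_path, sep=None, engine="python")
        entries = cls()
        for _, row in table.iterrows():
            stim = read_trace(base / row["stimulus_file"])
            arr = np.loadtxt(base / row["psth_file"])
            std = arr[:, 2] if arr.shape[1] > 2 else None
            entries.append(FitEntry(stim, RateTrace(arr[:, 0], arr[:, 1], std)))
        return entries


# Parameter names optimised per variant (n is held fixed; alpha1 is fixed
# for pure-IFF fits because the scale of u is absorbed by beta3).
_FREE = {
    "IFF": ("alpha2", "beta1", "beta2", "beta3", "beta4", "beta5", "theta"),
    "IFB": ("alpha2", "alpha3", "beta1", "beta2", "beta3", "beta4", "beta5",
            "theta"),
    "IFF_IFB": ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3",
                "beta4", "beta5", "theta"),
}


@dataclass
class FitResult:
    params: TransductionParams
    scales: np.ndarray
    objective: float  # negative log-likelihood (up to an additive constant)
    rho: list
    cvrmse: list
    n_starts: int
    objective_history: list
    degenerate: bool = False
    message: str = ""


def _objective_factory(variant, dataset, params0, free_names, fixed,
                       sigma_floor, scale_bounds, psth_window=None):
    sigmas = [np.maximum(e.psth.std if e.psth.std is not None else 0.0,
                         sigma_floor) for e in dataset]
    kernels = []
    for e in dataset:
        if psth_window is None:
            kernels.append(None)
        else:
            n = max(1, int(round(psth_window / e.stimulus.dt)))
            kernels.append(np.ones(n) / n)

    def model_psth(y, kern):
        # apply the same sliding window as the measured PSTH
        return y if kern is None else np.convolve(y, kern, mode="same")

    def build(logp):
        kw = params0.to_dict()
        kw.update(fixed)
        kw["variant"] = variant
        for name, v in zip(free_names, logp):
            kw[name] = float(np.exp(v))
        return TransductionParams(**kw)

    def evaluate(logp):
        try:
            params = build(logp)
        except ValueError:
            return np.inf, None, None
        nll = 0.0
        scales = np.empty(len(dataset))
        preds = []
        for i, (entry, sig) in enumerate(zip(dataset, sigmas)):
            try:
                sol = integrate(params, entry.stimulus)
            except RuntimeError:
                return np.inf, None, None
            yp = model_psth(sol.y, kernels[i])
            w = 1.0 / sig**2
            denom = np.sum(w * yp**2)
            s = np.sum(w * entry.psth.y * yp) / denom if denom > 0 else 1.0
            s = float(np.clip(s, *scale_bounds))
            scales[i] = s
            resid = (entry.psth.y - s * yp) / sig
            nll += 0.5 * float(np.sum(resid**2))
            preds.append(s * yp)
        if not np.isfinite(nll):
            return np.inf, None, None
        return nll, scales, preds

    def residuals(logp):
        """Stacked weighted residual vector (for the gradient refinement)."""
        try:
            params = build(logp)
        except ValueError:
            return np.full(sum(len(e.psth) for e in dataset), 1e6)
        out = []
        for i, (entry, sig) in enumerate(zip(dataset, sigmas)):
            try:
                sol = integrate(params, entry.stimulus)
            except RuntimeError:
                return np.full(sum(len(e.psth) for e in dataset), 1e6)
            yp = model_psth(sol.y, kernels[i])
            w = 1.0 / sig**2
            denom = np.sum(w * yp**2)
            s = np.sum(w * entry.psth.y * yp) / denom if denom > 0 else 1.0
            s = float(np.clip(s, *scale_bounds))
            out.append((entry.psth.y - s * yp) / sig)
        return np.concatenate(out)

    return build, evaluate, residuals


def fit(
    variant: str,
    dataset,
    params0: TransductionParams,
    fixed: dict | None = None,
    seed: int = 0,
    n_starts: int = 21,
    spread: float = 0.3,
    nm_maxiter: int | None = None,
    refine: bool = True,
    sigma_floor: float = 0.5,
    scale_bounds: tuple = (0.5, 2.0),
    psth_window: float | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a transduction model variant to PSTHs.

    ``params0`` provides the initial guess (and the values of fixed
    parameters); ``fixed`` pins parameters by name, defaulting to
    ``{"alpha1": 0.1}`` for the pure IFF variant.  ``n_starts`` controls the
    multi-start simplex (first start at ``params0``, the rest seeded
    log-normal perturbations); each simplex optimum is refined by a
    Levenberg-Marquardt pass on the weighted residuals.  ``psth_window``
    applies the measurement's sliding-window operator to the model rate
    before comparison (recommended when fitting windowed PSTHs).
    """
    if len(dataset) == 0:
        raise ValueError("dataset must contain at least one entry")
    if fixed is None:
        fixed = {"alpha1": 0.1} if variant == "IFF" else {}
    free_names = tuple(n for n in _FREE[variant] if n not in fixed)
    degenerate = all(np.ptp(e.stimulus.x) == 0 for e in dataset)

    build, evaluate, residuals = _objective_factory(variant, dataset, params0,
                                                    free_names, fixed,
                                                    sigma_floor, scale_bounds,
                                                    psth_window)
    p0 = np.log([max(getattr(params0, n), 1e-8) for n in free_names])
    rng = np.random.default_rng(seed)
    history: list = []
    best = (np.inf, None)

    def scalar(logp):
        return evaluate(logp)[0]

    for k in range(max(1, n_starts)):
        start = p0 if k == 0 else p0 + rng.normal(0.0, spread, size=len(p0))
        if not np.isfinite(scalar(start)):
            continue
        run_hist: list = []

        def cb(intermediate_result):
            # best-vertex objective at each simplex iteration
            run_hist.append(float(intermediate_result.fun))

        res = optimize.minimize(
            scalar, start, method="Nelder-Mead", callback=cb,
            options={"maxiter": nm_maxiter or 400 * len(p0),
                     "xatol": 1e-6, "fatol": 1e-8, "adaptive": True})
        history.append(run_hist)
        cand = (res.fun, res.x)
        if refine:
            lsq = optimize.least_squares(residuals, res.x, method="lm",
                                         xtol=1e-10, max_nfev=1000)
            refined = float(0.5 * np.sum(lsq.fun**2))
            if refined < cand[0]:
                cand = (refined, lsq.x)
        if cand[0] < best[0]:
            best = cand
    if best[1] is None:
        raise RuntimeError("objective non-finite at every start")

    nll, scales, preds = evaluate(best[1])
    params = build(best[1])
    rho, cv = [], []
    for entry, pred in zip(dataset, preds):
        try:
            rho.append(pearson_rho(entry.psth.y, pred))
        except ValueError:
            rho.append(np.nan)
        cv.append(cv_rmse(entry.psth.y, pred))
    return FitResult(params=params, scales=scales, objective=float(nll),
                     rho=rho, cvrmse=cv, n_starts=n_starts,
                     objective_history=history, degenerate=degenerate,
                     message="degenerate: constant stimulus, scale/beta "
                             "trade-off unidentifiable" if degenerate else "ok")
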