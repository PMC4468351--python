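"""Reverse-correlation linear-filter baseline for OSN identification.

Estimates a finite impulse response h from stimulus/rate pairs by
regularised spectral division on sliding windows, and predicts rates by
convolution.  The estimator is the standard systems-identification
baseline; on this neuron it succeeds for broadband (M-sequence) input but
fails on graded ramps, which is the point of carrying it alongside the
nonlinear ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusTrace
from .transduction import RateTrace

__all__ = ["LinearFilter", "estimate_filter", "predict_linear"]


@dataclass
class LinearFilter:
    """FIR filter: coefficient h[k] at lag ``lags[k]`` seconds (Hz per
    intensity unit per sample)."""

    lags: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.h = np.asarray(self.h, float)
        if not np.all(np.isfinite(self.h)):
            raise ValueError("filter coefficients must be finite")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def estimate_filter(
    x: StimulusTrace,
    y: RateTrace,
    window: float = 5.0,
    overlap: float = 0.5,
    eps_rel: float = 1e-6,
) -> LinearFilter:
    """Cross-spectral filter estimate averaged over sliding windows.

    Per window (mean-subtracted to cancel DC drifts):
    H = F(y)·conj(F(x)) / (|F(x)|² + ε) with ε = eps_rel·max|F(x)|²,
    then h = F⁻¹(H).  Window length sets the filter length; windows slide
    with the given fractional overlap.
    """
    if len(x) != len(y):
        raise ValueError("stimulus and rate must share a grid")
    dt = x.dt
    n_win = int(round(window / dt))
    if n_win < 2 or n_win > len(x):
        raise ValueError("window must be >= 2 samples and <= trace duration")
    if np.ptp(x.x) == 0:
        raise ValueError("stimulus is constant: zero spectrum, filter undefined")
    step = max(1, int(round(n_win * (1.0 - overlap))))
    cross = np.zeros(n_win, dtype=complex)
    power = np.zeros(n_win)
    count = 0
    for start in range(0, len(x) - n_win + 1, step):
        xs = x.x[start : start + n_win]
        ys = y.y[start : start + n_win]
        if np.ptp(xs) == 0:
            continue
        X = np.fft.fft(xs - xs.mean())
        Y = np.fft.fft(ys - ys.mean())
        cross += Y * np.conj(X)
        power += (X * np.conj(X)).real
        count += 1
    if count == 0:
        raise ValueError("no window with stimulus variance")
    h = np.fft.ifft(cross / (power + eps_rel * power.max())).real
    lags = np.arange(n_win) * dt
    return LinearFilter(lags, h)


def predict_linear(
    filt: LinearFilter,
    x: StimulusTrace,
    target_mean: float,
    rectify: bool = False,
) -> RateTrace:
    """Convolve the filter with a stimulus and shift the output to the
    target mean rate (the DC component is lost during estimation).

    ``rectify=True`` clamps negative rates to zero for downstream use; the
    raw values are what correlation scoring should see.
    """
    raw = np.convolve(x.x - x.x.mean(), filt.h, mode="full")[: len(x)]
    pred = raw - raw.mean() + target_mean
    if np.ptp(filt.h) == 0:
        # degenerate zero filter: constant trace at the target mean
        pred = np.full(len(x), float(target_mean))
    if rectify:
        pred = np.maximum(pred, 0.0)
    return RateTrace(x.t, pred)
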