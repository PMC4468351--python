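"""Quasi-steady-state theory of the pure incoherent feed-forward motif.

Because the firing rate y (timescale 1/β₅ ≈ 77 ms) and the intermediate
variable u (timescale 1/α₂ ≈ 1 s) both equilibrate much faster than the
~10-s stimulus ramps, the IFF ODE admits a closed-form input-output
relation ("transient normalization"):

    y_QSSA(t) = δ₁ · x / (δ₂ + x − δ₃·⟨dx/dt⟩) − δ₄

where ⟨dx/dt⟩ is the stimulus derivative convolved with the exponential
kernel e^(−α₂(t−t′)) — a short-term memory of intensity changes that
rescales the hyperbolic dose-response.  The derivation linearises the Hill
gate of the offset decay (valid above a firing-rate threshold ỹ) and
assumes y is slaved to the stimulus; both assumptions bound the domain of
validity quantified here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusTrace
from .transduction import TransductionParams

__all__ = [
    "QssaConstants",
    "QssaResult",
    "derived_constants",
    "scaling_term",
    "qssa_rate",
    "validity_threshold",
    "stimulus_timescale",
]

#: Hill-gate tolerance defining the validity threshold (gate > 1 - EPSILON).
EPSILON_DEFAULT = 0.05


@dataclass
class QssaConstants:
    """Constants of the closed-form solution.

    delta1: asymptotic rate scale (Hz); delta2: half-saturation intensity;
    delta3: weight of the derivative memory (dimensionless, < 1);
    delta4: offset rate (Hz).
    """

    delta1: float
    delta2: float
    delta3: float
    delta4: float

    def __post_init__(self):
        if min(self.delta1, self.delta2, self.delta3, self.delta4) < 0:
            raise ValueError("QSSA constants must be nonnegative")
        if not self.delta3 < 1:
            raise ValueError("delta3 must be < 1")


def _require_pure_iff(params: TransductionParams) -> None:
    if params.variant != "IFF" and params.alpha3_eff > 0:
        raise ValueError("the QSSA applies to the pure IFF motif only")


def derived_constants(params: TransductionParams) -> QssaConstants:
    """Map ODE parameters to the QSSA constants.

    δ₁ = (β₁/β₅)·α₂/(α₂+α₁β₃);  δ₂ = β₂·α₂/(α₂+α₁β₃);
    δ₃ = α₁β₃/(α₂+α₁β₃);        δ₄ = β₄/β₅.
    """
    _require_pure_iff(params)
    if params.beta5 == 0:
        raise ValueError("beta5 must be positive (rate decay)")
    denom = params.alpha2 + params.alpha1 * params.beta3
    return QssaConstants(
        delta1=params.beta1 / params.beta5 * params.alpha2 / denom,
        delta2=params.beta2 * params.alpha2 / denom,
        delta3=params.alpha1 * params.beta3 / denom,
        delta4=params.beta4 / params.beta5,
    )


def scaling_term(stimulus: StimulusTrace, alpha2: float) -> np.ndarray:
    """Exponentially weighted memory of the stimulus derivative,
    S(t) = ∫₀ᵗ e^(−α₂(t−t′)) dx/dt′ dt′.

    Discretised by the exact one-pole recursion for piecewise-linear
    stimuli: on each sample interval the slope is constant, so
    S_{k+1} = S_k·e^(−α₂Δt) + m_k·(1−e^(−α₂Δt))/α₂ exactly.  The kernel
    gives the term a memory of characteristic timescale 1/α₂ (~1 s).
    """
    x, dt = stimulus.x, stimulus.dt
    E = np.exp(-alpha2 * dt)
    gain = (1.0 - E) / alpha2
    m = np.diff(x) / dt
    S = np.empty_like(x)
    S[0] = 0.0
    for k in range(len(x) - 1):
        S[k + 1] = S[k] * E + m[k] * gain
    return S


@dataclass
class QssaResult:
    t: np.ndarray
    y: np.ndarray
    S: np.ndarray
    valid: np.ndarray  # True where the closed form is well-defined (denominator > 0)
    constants: QssaConstants


def qssa_rate(params: TransductionParams, stimulus: StimulusTrace) -> QssaResult:
    """Closed-form firing-rate prediction for a pure-IFF parameter set.

    Samples where the normalised denominator δ₂ + x − δ₃·S is not positive
    are flagged invalid (value set to NaN).  The returned rate may be
    negative near and below the validity threshold; rectify downstream if a
    physical rate is required.
    """
    c = derived_constants(params)
    S = scaling_term(stimulus, params.alpha2)
    den = c.delta2 + stimulus.x - c.delta3 * S
    valid = den > 0
    y = np.full(len(stimulus), np.nan)
    y[valid] = c.delta1 * stimulus.x[valid] / den[valid] - c.delta4
    return QssaResult(stimulus.t, y, S, valid, c)


def validity_threshold(theta: float, epsilon: float = EPSILON_DEFAULT) -> float:
    """Firing rate ỹ above which the Hill gate exceeds 1 − ε:
    ỹ = θ·√((1−ε)/ε).  With θ = 0.3 Hz and ε = 0.05 this is ≈ 1.3 Hz."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    return theta * np.sqrt((1.0 - epsilon) / epsilon)


def stimulus_timescale(stimulus: StimulusTrace) -> float:
    """Diagnostic timescale τ_x = (x_max − x_min)/max|dx/dt| used to judge
    the separation from the u and y kinetics."""
    dx = np.abs(np.diff(stimulus.x) / stimulus.dt)
    peak = dx.max()
    if peak == 0:
        return np.inf
    return float((stimulus.x.max() - stimulus.x.min()) / peak)
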