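"""Stimulus waveforms for optogenetic and olfactory drive of a single OSN.

Stimuli are uniformly sampled intensity time series (light in W/m², odor in
μM).  The module builds the ramp families used to characterise the neuron
(linear ramps of graded slope plus nonlinear rise profiles), pseudorandom
M-sequences for linear-system identification, and the open/closed-loop
protocols that couple stimulation to behaviour: replaying the intensity a
crawling larva experiences in a spatial light landscape, and run-gated ramp
presentation with reset to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "StimulusTrace",
    "RampSpec",
    "RHO_LIQUID_TO_GAS",
    "make_ramp",
    "make_msequence",
    "replay_from_trajectory",
    "stimulus_derivative",
    "open_loop_protocol",
    "gas_to_liquid",
    "read_trace",
    "write_trace",
]

#: Liquid-to-gas phase conversion for isoamyl acetate concentrations.
RHO_LIQUID_TO_GAS = 26.73

FRAME_RATE = 30.0  # Hz, tracker frame rate; default sampling everywhere
DEFAULT_DT = 1.0 / FRAME_RATE


@dataclass
class StimulusTrace:
    """Uniformly sampled intensity time series.

    Attributes
    ----------
    t : array of sample times (s), strictly increasing with constant step.
    x : intensity at each sample; W/m² for ``modality="light"``, μM for
        ``modality="odor"``.  Nonnegative everywhere.
    modality : ``"light"`` or ``"odor"``.
    baseline : intensity at and before t=0 (defaults to ``x[0]``).
    """

    t: np.ndarray
    x: np.ndarray
    modality: str = "light"
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.x.shape:
            raise ValueError("t and x must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("t must be strictly increasing with constant step")
        if np.any(self.x < 0):
            raise ValueError("stimulus intensity must be nonnegative")
        if self.modality not in ("light", "odor"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.baseline is None:
            self.baseline = float(self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation; constant baseline before t[0], last value after."""
        return np.interp(t, self.t, self.x, left=self.baseline, right=self.x[-1])

    def with_values(self, x: np.ndarray, **kw) -> "StimulusTrace":
        return replace(self, x=np.asarray(x, float), **kw)


@dataclass
class RampSpec:
    """Specification of a rise/fall intensity ramp.

    ``shape`` is one of linear, exponential, sigmoid, quadratic, asymptotic.
    The rise follows the named profile from ``min_intensity`` to
    ``max_intensity`` over ``rise_duration``; the fall mirrors the profile
    over ``fall_duration`` (0 for an abrupt drop to baseline).
    """

    shape: str
    rise_duration: float
    fall_duration: float
    min_intensity: float
    max_intensity: float
    modality: str = "light"

    def __post_init__(self) -> None:
        if self.shape not in _PROFILES:
            raise ValueError(
                f"unknown ramp shape {self.shape!r}; choose from {sorted(_PROFILES)}"
            )
        if self.rise_duration <= 0:
            raise ValueError("rise_duration must be > 0")
        if self.fall_duration < 0:
            raise ValueError("fall_duration must be >= 0")
        if not (self.max_intensity > self.min_intensity >= 0):
            raise ValueError("require max_intensity > min_intensity >= 0")


# Raw rise profiles p(t) on [0, T].  Each is normalised downstream so that
# p(T) maps to max_intensity; the printed forms (exp: e^-T (e^t - 1),
# sigmoid: t^3/(t^3 + (T/2)^3)) keep their shape under this normalisation.
def _p_linear(t, T):
    return t / T


def _p_quadratic(t, T):
    return (t / T) ** 2


def _p_exponential(t, T):
    return np.expm1(t) / np.expm1(T)


def _p_sigmoid(t, T):
    c = (T / 2.0) ** 3
    return (t**3 / (t**3 + c)) / (T**3 / (T**3 + c))


def _p_asymptotic(t, T):
    # Saturating rise 1 - e^(-t/tau) with tau = T/3 (surrogate form).
    tau = T / 3.0
    return -np.expm1(-t / tau) / -np.expm1(-3.0)


_PROFILES = {
    "linear": _p_linear,
    "quadratic": _p_quadratic,
    "exponential": _p_exponential,
    "sigmoid": _p_sigmoid,
    "asymptotic": _p_asymptotic,
}


def ramp_profile(shape: str, t: np.ndarray, rise_duration: float) -> np.ndarray:
    """Normalised rise profile: 0 at t=0, 1 at t=rise_duration."""
    if shape not in _PROFILES:
        raise ValueError(f"unknown ramp shape {shape!r}")
    return _PROFILES[shape](np.asarray(t, float), rise_duration)


def make_ramp(
    spec: RampSpec,
    dt: float = DEFAULT_DT,
    onset: float = 2.0,
    tail: float = 8.0,
) -> StimulusTrace:
    """Build a ramp stimulus trace padded with baseline before and after.

    The rise starts at ``onset`` seconds; the trace extends ``tail`` seconds
    past the end of the fall so offset responses are visible.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    T_r, T_f = spec.rise_duration, spec.fall_duration
    lo, hi = spec.min_intensity, spec.max_intensity
    t = np.arange(0.0, onset + T_r + T_f + tail + dt / 2, dt)
    x = np.full_like(t, lo)
    rising = (t >= onset) & (t < onset + T_r)
    x[rising] = lo + (hi - lo) * ramp_profile(spec.shape, t[rising] - onset, T_r)
    if T_f > 0:
        falling = (t >= onset + T_r) & (t < onset + T_r + T_f)
        # time-reversed rise profile, rescaled to the fall duration
        s = (onset + T_r + T_f - t[falling]) * (T_r / T_f)
        x[falling] = lo + (hi - lo) * ramp_profile(spec.shape, s, T_r)
    return StimulusTrace(t, x, modality=spec.modality, baseline=lo)


def _de_bruijn(k: int, n: int) -> list[int]:
    """de Bruijn sequence B(k, n) as symbol indices (Lyndon-word algorithm)."""
    a = [0] * (k * n)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > n:
            if n % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return seq


def make_msequence(
    levels,
    step: float,
    seed: int | None = None,
    order: int = 4,
    dt: float | None = None,
    modality: str = "light",
) -> StimulusTrace:
    """Pseudorandom intensity sequence covering every ordered ``order``-tuple
    of the given levels exactly once (cyclically, de Bruijn construction).

    Each symbol is held for ``step`` seconds; ``seed`` sets the starting
    rotation of the cyclic sequence.  ``dt`` defaults to one sample per
    symbol.
    """
    levels = np.asarray(list(levels), dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need at least 2 distinct intensity levels")
    if step <= 0:
        raise ValueError("step must be > 0")
    if np.any(levels < 0):
        raise ValueError("intensity levels must be nonnegative")
    idx = np.array(_de_bruijn(len(levels), order), dtype=int)
    if seed is not None:
        shift = int(np.random.default_rng(seed).integers(len(idx)))
        idx = np.roll(idx, -shift)
    if dt is None:
        dt = step
    n_samples = int(round(len(idx) * step / dt))
    t = np.arange(n_samples) * dt
    sym = np.minimum(np.floor(t / step + 1e-9).astype(int), len(idx) - 1)
    x = levels[idx[sym]]
    return StimulusTrace(t, x, modality=modality, baseline=float(x[0]))


def replay_from_trajectory(traj, landscape, point: str = "head") -> StimulusTrace:
    """Intensity experienced along a trajectory in a spatial landscape.

    ``point`` selects the body point whose position samples the landscape
    (``"head"`` or ``"midpoint"``).  Sampling is bilinear (see
    :meth:`chemotax.synthetic.Landscape.sample`); positions outside the grid
    raise an error naming the offending frame.
    """
    if point not in ("head", "midpoint"):
        raise ValueError("point must be 'head' or 'midpoint'")
    pos = getattr(traj, point)
    x = np.empty(len(pos))
    for i, (px, py) in enumerate(pos):
        try:
            x[i] = landscape.sample(px, py)
        except ValueError as err:
            raise ValueError(f"frame {i}: {err}") from err
    return StimulusTrace(np.asarray(traj.t, float), x,
                         modality=getattr(landscape, "modality", "light"))


def stimulus_derivative(
    trace: StimulusTrace,
    window: int = 11,
    polyorder: int = 3,
    frame_diff: bool = False,
) -> np.ndarray:
    """Time derivative of the stimulus, in intensity units per second.

    Default: Savitzky-Golay smoothing-differentiation (mild low-pass, window
    in samples).  ``frame_diff=True`` instead returns the single-frame
    backward difference (change during the preceding frame divided by dt),
    the form used by the stimulus+derivative control GLM.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if frame_diff:
        d = np.empty(len(trace))
        d[1:] = np.diff(trace.x) / trace.dt
        d[0] = 0.0
        return d
    window = min(window, len(trace) - (1 - len(trace) % 2))
    if window <= polyorder:
        return np.gradient(trace.x, trace.dt)
    return savgol_filter(trace.x, window, polyorder, deriv=1, delta=trace.dt)


def open_loop_protocol(
    run_events,
    ramp: StimulusTrace,
    baseline: float,
    assignment=None,
    dt: float = DEFAULT_DT,
    total_duration: float | None = None,
) -> StimulusTrace:
    """Run-gated stimulation: the ramp is replayed from each run's onset and
    the intensity resets to ``baseline`` the moment the run is interrupted.

    ``run_events`` is a sequence of (start, end) times; ``assignment`` marks
    each run as test (True, ramp) or control (False, constant baseline).
    Overlapping runs are rejected.
    """
    runs = sorted((float(a), float(b)) for a, b in run_events)
    for (a0, b0), (a1, _) in zip(runs, runs[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping runs: ({a0}, {b0}) and starting {a1}")
    if assignment is None:
        assignment = [True] * len(runs)
    if total_duration is None:
        total_duration = (runs[-1][1] if runs else 0.0) + 1.0
    t = np.arange(0.0, total_duration, dt)
    x = np.full_like(t, baseline)
    order = np.argsort([a for a, _ in run_events])
    flags = [assignment[i] for i in order]
    for (start, end), is_test in zip(runs, flags):
        if not is_test:
            continue
        m = (t >= start) & (t < end)
        x[m] = ramp.value_at(t[m] - start + ramp.t[0])
    return StimulusTrace(t, x, modality=ramp.modality, baseline=baseline)


def gas_to_liquid(x_gas):
    """Convert a gas-phase odor concentration (μM) to its liquid-phase
    equivalent via the calibration scalar ρ(liquid→gas) = 26.73."""
    x_gas = np.asarray(x_gas, dtype=float)
    if np.any(x_gas < 0):
        raise ValueError("gas-phase concentration must be nonnegative")
    out = RHO_LIQUID_TO_GAS * x_gas
    return float(out) if out.ndim == 0 else out


def write_trace(path, trace: StimulusTrace) -> None:
    """Write a trace as 2-column delimited text with a metadata header."""
    units = "W/m2" if trace.modality == "light" else "uM"
    header = (
        f"modality={trace.modality} units={units} baseline={trace.baseline!r}\n"
        "t_s\tx"
    )
    np.savetxt(path, np.column_stack([trace.t, trace.x]), header=header,
               delimiter="\t")


def read_trace(path) -> StimulusTrace:
    modality, baseline = "light", None
    with open(path) as fh:
        first = fh.readline()
    for tok in first.lstrip("# ").split():
        key, _, val = tok.partition("=")
        if key == "modality":
            modality = val
        elif key == "baseline":
            baseline = float(val)
    data = np.loadtxt(path)
    return StimulusTrace(data[:, 0], data[:, 1], modality=modality,
                         baseline=baseline)
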