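"""Synthetic-data generation: light landscapes, a closed-loop virtual
larva, Poisson PSTHs and open-loop run ensembles.

The simulator closes the sensorimotor loop that the analysis modules take
apart: a point agent crawls at constant speed, the intensity under its
head is sampled from a radially symmetric landscape by bilinear
interpolation (1×1 mm grid, as in the tracker), the transduction ODE is
advanced frame by frame, the turn GLM converts the predicted firing rate
into a 1-s turn probability, and run terminations are drawn from the
per-frame hazard.  Landscape geometry follows the virtual-reality
experiments: a common 8-s exponential rise (at 1 mm/s) from the foot to
the rim, continued inward as a mirrored fall ("volcano"), an abrupt drop
("well"), a plateau ("mesa") or a linear rise ("linear_hat"); a pure
"exponential" gradient rises all the way to a central peak.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .behavior import Trajectory
from .fitting import psth_from_spikes
from .stimuli import StimulusTrace, ramp_profile
from .transduction import RateTrace, TransductionParams, steady_state
from .turn_model import Run, RunEnsemble, TurnGlmParams, lambda_of

__all__ = [
    "Landscape",
    "AgentConfig",
    "SimulationResult",
    "make_landscape",
    "simulate_larva",
    "post_rim_run_durations",
    "synthetic_psth",
    "make_turn_ensemble",
]

PROFILES = ("exponential", "volcano", "well", "mesa", "linear_hat")


@dataclass
class Landscape:
    """Radially symmetric intensity field on a regular grid (W/m², mm)."""

    grid: np.ndarray  # [iy, ix]
    x0: float
    y0: float
    resolution: float
    profile: str
    rim_radius: float
    foot_radius: float
    i_min: float
    i_max: float
    modality: str = "light"
    decay_length: float = 8.0

    @property
    def center(self) -> tuple:
        return (0.0, 0.0)

    def sample(self, x: float, y: float) -> float:
        """Bilinear interpolation; exact on grid nodes."""
        gx = (x - self.x0) / self.resolution
        gy = (y - self.y0) / self.resolution
        ny, nx = self.grid.shape
        if not (0.0 <= gx <= nx - 1 and 0.0 <= gy <= ny - 1):
            raise ValueError(f"position ({x:.2f}, {y:.2f}) outside landscape grid")
        ix = min(int(gx), nx - 2)
        iy = min(int(gy), ny - 2)
        fx, fy = gx - ix, gy - iy
        g = self.grid
        return float((1 - fx) * (1 - fy) * g[iy, ix]
                     + fx * (1 - fy) * g[iy, ix + 1]
                     + (1 - fx) * fy * g[iy + 1, ix]
                     + fx * fy * g[iy + 1, ix + 1])

    def radial(self, r) -> np.ndarray:
        """Intensity along a radial transect (exact profile, not the grid)."""
        return _radial_intensity(np.asarray(r, float), self.profile,
                                 self.rim_radius, self.foot_radius,
                                 self.i_min, self.i_max, self._hat_slope,
                                 self.decay_length)

    _hat_slope: float = 12.0

    def save(self, path) -> None:
        np.savetxt(path, self.grid)
        meta = {k: v for k, v in asdict(self).items() if k != "grid"}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "Landscape":
        grid = np.loadtxt(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(grid=grid, **meta)


def _radial_intensity(r, profile, rim, foot, i_min, i_max, hat_slope,
                      decay_length=8.0):
    r = np.asarray(r, float)
    span = i_max - i_min
    rise = foot - rim

    def rise_value(tt, T):
        return i_min + span * ramp_profile("exponential", np.clip(tt, 0, T), T)

    if profile == "exponential":
        # point-source-like gradient: exponential decay from a central peak
        return i_min + span * np.exp(-r / decay_length)
    out = np.full_like(r, i_min)
    annulus = (r >= rim) & (r <= foot)
    out[annulus] = rise_value(foot - r[annulus], rise)
    inside = r < rim
    if profile == "volcano":
        # mirrored exponential fall over the rim extent, i_min at the center
        out[inside] = rise_value(r[inside] * (rise / rim), rise)
    elif profile == "well":
        out[inside] = i_min
    elif profile == "mesa":
        out[inside] = i_max
    elif profile == "linear_hat":
        out[inside] = i_max + hat_slope * (rim - r[inside])
    else:
        raise ValueError(f"unknown landscape profile {profile!r}")
    return out


def make_landscape(
    profile: str,
    rim_radius: float = 8.0,
    rise_extent: float = 8.0,
    i_min: float = 15.0,
    i_max: float = 207.0,
    half_size: float = 45.0,
    resolution: float = 1.0,
    hat_slope: float = 12.0,
    decay_length: float = 8.0,
) -> Landscape:
    """Build a radially symmetric light landscape.

    ``rise_extent`` is the width (mm) of the exponential rise outside the
    rim, so inward motion at 1 mm/s reproduces an ``rise_extent``-second
    exponential ramp; the foot of the gradient sits at rim + rise_extent.
    For the ``"exponential"`` profile the rise continues to a peak at the
    center (total extent rim + rise_extent).  ``hat_slope`` (W/m² per mm)
    sets the linear-hat apex.
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    if rise_extent <= 0:
        raise ValueError("rim must lie strictly inside the gradient foot")
    foot = rim_radius + rise_extent
    if foot > half_size:
        raise ValueError("gradient extends beyond the grid half-size")
    coords = np.arange(-half_size, half_size + resolution / 2, resolution)
    X, Y = np.meshgrid(coords, coords)
    R = np.hypot(X, Y)
    grid = _radial_intensity(R, profile, rim_radius, foot, i_min, i_max,
                             hat_slope, decay_length)
    ls = Landscape(grid=grid, x0=float(coords[0]), y0=float(coords[0]),
                   resolution=float(resolution), profile=profile,
                   rim_radius=float(rim_radius), foot_radius=float(foot),
                   i_min=float(i_min), i_max=float(i_max),
                   decay_length=float(decay_length))
    ls._hat_slope = hat_slope
    return ls


@dataclass
class AgentConfig:
    """Virtual-larva parameters.

    Crawl speed 1 mm/s at 30 Hz; turns last ``turn_duration`` s and redraw
    the heading by ±[30°, 120°]; the agent starts facing the center at
    ``start_distance`` (9.6 mm for the exponential gradient, 17.1 mm for
    the landscape family).  The transduction clock starts at
    ``clock_offset`` so that the slow β₄/θ′ drift corrections are in their
    adapted regime (the agent is treated as having rested under baseline
    illumination beforehand).
    """

    speed: float = 1.0
    dt: float = 1.0 / 30.0
    duration: float = 60.0
    turn_duration: float = 1.5
    turn_angle_min: float = 30.0  # degrees
    turn_angle_max: float = 120.0
    start_distance: float = 17.1
    head_offset: float = 1.5  # mm ahead of the midpoint
    tail_offset: float = 2.5  # mm behind the midpoint
    clock_offset: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.speed <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("speed, dt and duration must be positive")


@dataclass
class SimulationResult:
    trajectory: Trajectory
    stimulus: StimulusTrace
    u: np.ndarray
    y: np.ndarray
    lam: np.ndarray
    running: np.ndarray  # True on run frames
    runs: RunEnsemble
    run_frames: list  # (first_frame, last_frame) per run
    truncated: bool
    config: AgentConfig
    landscape: Landscape

    def rate_trace(self) -> RateTrace:
        return RateTrace(self.trajectory.t, self.y)


def _ode_stepper(params: TransductionParams, n_sub: int = 4):
    """Scalar exponential-Euler (Rosenbrock-1) stepper for the closed loop.

    u is updated exactly for frozen y; y uses the exponential integrator
    y += f·(1−e^(−Lh))/L with L the local decay stiffness, which remains
    stable through the steep Hill region of the offset decay.
    """
    a1, a3, a2 = params.alpha1_eff, params.alpha3_eff, params.alpha2
    b1, b2, b3 = params.beta1, params.beta2, params.beta3
    b4_0, b5, th0, n = params.beta4, params.beta5, params.theta, params.n
    corr = params.corrections_enabled

    def step(u, y, x, t0, h):
        hh = h / n_sub
        for k in range(n_sub):
            t = t0 + k * hh
            if corr:
                t4 = t**4
                b4 = 1.023 ** (t4 / (t4 + 810000.0)) * b4_0
                th = th0 if t <= 30.0 else th0 * (30.0 / t) ** 2
            else:
                b4, th = b4_0, th0
            prod = a1 * x + a3 * y
            Eu = math.exp(-a2 * hh)
            u_next = u * Eu + prod / a2 * (1.0 - Eu)
            yn = y**n
            thn = th**n
            hill = yn / (yn + thn) if yn + thn > 0 else 0.0
            f = b1 * x / (b2 + x + b3 * u) - b4 * hill - b5 * y
            dh = (n * y ** (n - 1) * thn / (yn + thn) ** 2) if y > 0 else 0.0
            L = b5 + b4 * dh
            y = max(y + f * (1.0 - math.exp(-L * hh)) / L, 0.0)
            u = u_next
        return u, y

    return step


def simulate_larva(
    landscape: Landscape,
    params: TransductionParams,
    glm: TurnGlmParams,
    config: AgentConfig | None = None,
) -> SimulationResult:
    """Closed-loop simulation of one virtual larva.

    Per frame: the intensity at the head position is sampled from the
    landscape, the transduction ODE is advanced, λ is computed from the
    GLM, and the 1-s window probability is thinned to a per-frame hazard
    p_f = 1 − (1−λ)^dt to draw run terminations.  Turns freeze the
    position for ``turn_duration`` and redraw the heading.  Leaving the
    grid truncates the trajectory (flagged).  Fully reproducible for a
    fixed seed.
    """
    cfg = config or AgentConfig()
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt
    n_frames = int(round(cfg.duration / dt))
    step = _ode_stepper(params)

    phi = rng.uniform(0.0, 2.0 * math.pi)
    pos = np.array([cfg.start_distance * math.cos(phi),
                    cfg.start_distance * math.sin(phi)])
    heading = math.atan2(-pos[1], -pos[0])  # facing the center

    head = np.empty((n_frames, 2))
    mid = np.empty((n_frames, 2))
    tail = np.empty((n_frames, 2))
    xs = np.empty(n_frames)
    us = np.empty(n_frames)
    ys = np.empty(n_frames)
    lams = np.empty(n_frames)
    running = np.empty(n_frames, dtype=bool)

    hx = pos[0] + cfg.head_offset * math.cos(heading)
    hy = pos[1] + cfg.head_offset * math.sin(heading)
    st = steady_state(params, landscape.sample(hx, hy), t_ref=cfg.clock_offset)
    u, y = st.u, st.y

    runs, run_frames = [], []
    run_start_frame = 0
    in_run = True
    turn_frames_left = 0
    truncated = False
    i = 0
    while i < n_frames:
        ux, uy = math.cos(heading), math.sin(heading)
        head_i = (pos[0] + cfg.head_offset * ux, pos[1] + cfg.head_offset * uy)
        tail_i = (pos[0] - cfg.tail_offset * ux, pos[1] - cfg.tail_offset * uy)
        try:
            x = landscape.sample(*head_i)
        except ValueError:
            truncated = True
            break
        t = i * dt
        u, y = step(u, y, x, t + cfg.clock_offset, dt)
        lam = float(lambda_of(glm, y))
        head[i], mid[i], tail[i] = head_i, pos, tail_i
        xs[i], us[i], ys[i], lams[i] = x, u, y, lam
        running[i] = in_run

        if in_run:
            p_frame = 1.0 - (1.0 - lam) ** dt
            if rng.random() < p_frame:
                end_t = (i + 1) * dt
                runs.append(Run(start=run_start_frame * dt, end=end_t,
                                turn_terminal=True,
                                input=ys[run_start_frame : i + 1].copy(),
                                lam=lams[run_start_frame : i + 1].copy(),
                                dt=dt))
                run_frames.append((run_start_frame, i))
                in_run = False
                turn_frames_left = int(round(cfg.turn_duration / dt))
            else:
                pos = pos + cfg.speed * dt * np.array([ux, uy])
        else:
            turn_frames_left -= 1
            if turn_frames_left <= 0:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                dphi = math.radians(rng.uniform(cfg.turn_angle_min,
                                                cfg.turn_angle_max))
                heading = (heading + sign * dphi) % (2.0 * math.pi)
                in_run = True
                run_start_frame = i + 1
        i += 1

    n = i
    if n == 0:
        raise ValueError("agent starts outside the landscape grid")
    if in_run and run_start_frame < n:
        runs.append(Run(start=run_start_frame * dt, end=n * dt,
                        turn_terminal=False,
                        input=ys[run_start_frame:n].copy(),
                        lam=lams[run_start_frame:n].copy(), dt=dt))
        run_frames.append((run_start_frame, n - 1))

    tgrid = np.arange(n) * dt
    traj = Trajectory(tgrid, head[:n], mid[:n], tail[:n])
    stim = StimulusTrace(tgrid, xs[:n], modality=landscape.modality,
                         baseline=float(xs[0]))
    return SimulationResult(trajectory=traj, stimulus=stim, u=us[:n],
                            y=ys[:n], lam=lams[:n], running=running[:n],
                            runs=RunEnsemble(runs), run_frames=run_frames,
                            truncated=truncated, config=cfg,
                            landscape=landscape)


def post_rim_run_durations(results, min_duration: float = 1.0) -> np.ndarray:
    """Time from inward rim crossing to run termination, per entering run.

    A run enters the landscape's central area when the radial distance of
    the head drops below the rim radius; only runs of at least
    ``min_duration`` that cross inward are scored.
    """
    durations = []
    for res in results:
        rim = res.landscape.rim_radius
        r = np.hypot(res.trajectory.head[:, 0], res.trajectory.head[:, 1])
        for run, (f0, f1) in zip(res.runs, res.run_frames):
            if run.duration < min_duration:
                continue
            seg = r[f0 : f1 + 1]
            crossing = np.nonzero((seg[:-1] >= rim) & (seg[1:] < rim))[0]
            if len(crossing) == 0:
                continue
            t_cross = (f0 + crossing[0] + 1) * run.dt
            durations.append(run.end - t_cross)
    if not durations:
        raise ValueError("no runs crossing the rim inward")
    return np.asarray(durations)


def synthetic_psth(rate: RateTrace, n_trials: int, seed: int = 0,
                   window: float = 0.05):
    """Inhomogeneous-Poisson spike trains from a rate trace, plus their
    PSTH (50-ms sliding window).

    Per trial and sample bin, counts are Poisson with mean rate·dt and
    spike times are placed uniformly in the bin.  Returns
    ``(spike_trains, psth)``.
    """
    rng = np.random.default_rng(seed)
    dt = rate.dt
    lam = np.maximum(rate.y, 0.0) * dt
    trains = []
    for _ in range(n_trials):
        counts = rng.poisson(lam)
        times = np.repeat(rate.t, counts) + rng.uniform(0.0, dt,
                                                        size=int(counts.sum()))
        trains.append(np.sort(times))
    return trains, psth_from_spikes(trains, rate.t, window=window)


def make_turn_ensemble(glm: TurnGlmParams, inputs, n_runs: int,
                       seed: int = 0) -> RunEnsemble:
    """Open-loop run ensemble: each run replays one input trace (predicted
    rate or stimulus) and terminates according to the GLM hazard.

    ``inputs`` is a list of :class:`RateTrace`-like objects; runs are
    distributed over the traces in round-robin order.  Runs surviving to
    the end of their trace are censored there.
    """
    inputs = list(inputs)
    rng = np.random.default_rng(seed)
    runs = RunEnsemble()
    per_trace = [n_runs // len(inputs) + (1 if k < n_runs % len(inputs) else 0)
                 for k in range(len(inputs))]
    for trace, k in zip(inputs, per_trace):
        if k == 0:
            continue
        yv = np.asarray(trace.y, float)
        dt = trace.dt
        lam = lambda_of(glm, yv)
        p_frame = 1.0 - (1.0 - lam) ** dt
        draws = rng.random((k, len(yv))) < p_frame[None, :]
        any_term = draws.any(axis=1)
        first = np.argmax(draws, axis=1)
        for j in range(k):
            if any_term[j]:
                end = (first[j] + 1) * dt
                sl = slice(0, first[j] + 1)
                runs.append(Run(0.0, end, True, input=yv[sl].copy(),
                                lam=lam[sl].copy(), dt=dt))
            else:
                runs.append(Run(0.0, len(yv) * dt, False, input=yv.copy(),
                                lam=lam.copy(), dt=dt))
    return runs
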