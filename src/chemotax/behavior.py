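"""Run/non-run classification and turn detection from larval trajectories.

Trajectories are 30-Hz tracks of three body points (head, midpoint —
a third of the skeleton from the head — and tail, in mm).  Two detectors
are provided: the online-style finite-state classifier used during
closed-loop tracking (head-angle and tail-velocity thresholds with
hysteresis) and an offline geometric detector that flags bends of the
arc-length-resampled midpoint path.  Runs are the maximal forward-crawl
segments between reorientation events; everything that is not a run
(stops, head casts, backward crawls) is a single non-run meta-state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .turn_model import Run, RunEnsemble

__all__ = [
    "Trajectory",
    "ClassifierThresholds",
    "KinematicFeatures",
    "kinematic_features",
    "classify_states",
    "detect_turns_geometric",
    "runs_from_states",
]

FRAME_RATE = 30.0


@dataclass
class Trajectory:
    """30-Hz track of head/midpoint/tail positions in mm."""

    t: np.ndarray
    head: np.ndarray  # (n, 2)
    midpoint: np.ndarray
    tail: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        for name in ("head", "midpoint", "tail"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (len(self.t), 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")
            setattr(self, name, arr)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": np.arange(len(self.t)), "t": self.t,
            "head_x": self.head[:, 0], "head_y": self.head[:, 1],
            "mid_x": self.midpoint[:, 0], "mid_y": self.midpoint[:, 1],
            "tail_x": self.tail[:, 0], "tail_y": self.tail[:, 1],
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["t"].to_numpy(),
                   df[["head_x", "head_y"]].to_numpy(),
                   df[["mid_x", "mid_y"]].to_numpy(),
                   df[["tail_x", "tail_y"]].to_numpy())


@dataclass
class ClassifierThresholds:
    """Run/non-run thresholds: tau1 (°) triggers non-run on large head
    angle, tau2 (dimensionless) on small/negative tail progression, tau3
    (°, < tau1) is the hysteretic re-entry angle."""

    tau1: float = 18.0
    tau2: float = 0.0065
    tau3: float = 13.0

    def __post_init__(self):
        if not self.tau3 < self.tau1:
            raise ValueError("hysteresis requires tau3 < tau1")


@dataclass
class KinematicFeatures:
    head_angle: np.ndarray  # degrees, unsigned
    v_tail: np.ndarray  # (n, 2), mm per frame
    dot_product: np.ndarray  # v_tail · unit body axis (mm/frame)


def _smooth(points: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    n = len(points)
    w = min(window, n - (1 - n % 2))
    if w <= polyorder:
        return points
    return savgol_filter(points, w, polyorder, axis=0)


def kinematic_features(traj: Trajectory, smooth: bool = True,
                       window: int = 15, polyorder: int = 3) -> KinematicFeatures:
    """Per-frame head angle, tail velocity and tail-progression dot product.

    The head angle is the unsigned angle between the neck axis
    (midpoint→head) and the body axis (tail→midpoint); tail velocity is a
    central difference in mm/frame; the dot product projects it on the unit
    body-axis vector (negative for backward motion).  Positions are
    Savitzky-Golay smoothed first (window 15 frames = 0.5 s, order 3).
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames")
    head = _smooth(traj.head, window, polyorder) if smooth else traj.head
    mid = _smooth(traj.midpoint, window, polyorder) if smooth else traj.midpoint
    tail = _smooth(traj.tail, window, polyorder) if smooth else traj.tail

    neck = head - mid
    body = mid - tail
    nn = np.linalg.norm(neck, axis=1)
    nb = np.linalg.norm(body, axis=1)
    bad = (nn == 0) | (nb == 0)
    if bad.any():
        raise ValueError(f"coincident body points at frame {int(np.where(bad)[0][0])}")
    cosang = np.clip(np.sum(neck * body, axis=1) / (nn * nb), -1.0, 1.0)
    head_angle = np.degrees(np.arccos(cosang))

    v_tail = np.empty_like(tail)
    v_tail[1:-1] = (tail[2:] - tail[:-2]) / 2.0
    v_tail[0] = tail[1] - tail[0]
    v_tail[-1] = tail[-1] - tail[-2]
    unit_body = body / nb[:, None]
    dot = np.sum(v_tail * unit_body, axis=1)
    return KinematicFeatures(head_angle, v_tail, dot)


def classify_states(traj: Trajectory,
                    thresholds: ClassifierThresholds | None = None,
                    features: KinematicFeatures | None = None) -> np.ndarray:
    """Two-state run/non-run machine with hysteresis.

    A run breaks as soon as the head angle exceeds tau1 (head cast) or the
    tail progression drops below tau2 (stop / backward crawl); it resumes
    only once the head angle is below tau3 and the progression is above
    tau2.  Returns a boolean array, True for run frames.
    """
    th = thresholds or ClassifierThresholds()
    f = features or kinematic_features(traj)
    run_break = (f.head_angle > th.tau1) | (f.dot_product < th.tau2)
    run_enter = (f.head_angle < th.tau3) & (f.dot_product > th.tau2)
    states = np.empty(len(f.head_angle), dtype=bool)
    state = bool(run_enter[0])
    for i in range(len(states)):
        if state and run_break[i]:
            state = False
        elif not state and run_enter[i]:
            state = True
        states[i] = state
    return states


def _resample_arclength(path: np.ndarray, spacing: float):
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_nodes = int(total // spacing) + 1  # trailing partial segment ignored
    s_nodes = np.arange(n_nodes) * spacing
    nodes = np.column_stack([np.interp(s_nodes, s, path[:, 0]),
                             np.interp(s_nodes, s, path[:, 1])])
    frame_of_node = np.searchsorted(s, s_nodes, side="left")
    return nodes, np.minimum(frame_of_node, len(path) - 1)


def detect_turns_geometric(path: np.ndarray, segment_length: float = 5.0,
                           angle_threshold: float = 20.0) -> list:
    """Offline turn detection on the midpoint path.

    The path is resampled into equal arc-length segments; a turn is a
    maximal block of consecutive super-threshold bends between successive
    segment vectors, reported at the frame of its largest bend.  Returns a
    list of frame indices (empty for paths shorter than two segments).
    """
    path = np.asarray(path, float)
    nodes, node_frames = _resample_arclength(path, segment_length)
    if len(nodes) < 3:
        return []
    v = np.diff(nodes, axis=0)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = np.sum(v[:-1] * v[1:], axis=1)
    ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    above = ang > angle_threshold
    turns = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            k = i + int(np.argmax(ang[i : j + 1]))
            turns.append(int(node_frames[k + 1]))  # vertex node of the bend
            i = j + 1
        else:
            i += 1
    return turns


def runs_from_states(states: np.ndarray, t: np.ndarray,
                     min_duration: float = 1.0) -> RunEnsemble:
    """Maximal run intervals from a boolean run/non-run frame sequence.

    A run is turn-terminated when followed by non-run frames and censored
    when the trajectory ends mid-run.  The ensemble carries the standard
    minimum-duration filter (applied downstream via ``filtered()``).
    """
    states = np.asarray(states, bool)
    t = np.asarray(t, float)
    runs = []
    i = 0
    n = len(states)
    while i < n:
        if states[i]:
            j = i
            while j + 1 < n and states[j + 1]:
                j += 1
            end_censored = j == n - 1
            dt = t[1] - t[0] if n > 1 else 1.0 / FRAME_RATE
            end_time = t[j] + (0.0 if end_censored else dt)
            if end_time > t[i]:
                runs.append(Run(start=float(t[i]), end=float(end_time),
                                turn_terminal=not end_censored))
            i = j + 1
        else:
            i += 1
    return RunEnsemble(runs, min_duration=min_duration)
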