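"""Behavioral parameter extraction from labeled centroid trajectories.

Fifteen per-subject parameters: activity budgets (lying / sitting /
out-of-room percentages, transition count), sit-stand transition times and
speeds, and spatio-temporal gait parameters derived from the local maxima of
the vertical centroid coordinate during walking (one step = the interval
between two consecutive local maxima).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .synthcohort import (ACTIVITIES, ACTIVITY_CODE, LYING, OUT_OF_ROOM,
                          SITTING, STANDING, UNKNOWN, WALKING,
                          DepthSequence, LabeledTrajectory)

log = logging.getLogger(__name__)

# step detector settings: reject sensor noise while passing cadences <= 5 steps/s
SMOOTH_WINDOW_S = 0.25
PEAK_PROMINENCE_M = 0.01
MIN_PEAK_SEPARATION_S = 0.2

# sit/stand transition window: vertical speed threshold and search span
TRANSITION_SPEED_MPS = 0.05
TRANSITION_MAX_SPAN_S = 10.0

PARAMETER_NAMES = [
    "total_lying_pct", "total_sitting_pct", "out_of_room_pct", "n_transitions",
    "time_to_sit_s", "speed_to_sit_mps", "time_to_get_up_s", "speed_to_get_up_mps",
    "mean_step_length_m", "cv_step_length", "mean_step_duration_s",
    "cv_step_duration", "mean_pace_steps_per_s", "cv_pace", "mean_gait_speed_mps",
]


@dataclass
class StepEvent:
    """One step: the interval between two consecutive vertical local maxima."""

    bout_id: int
    t_peak_prev: float
    t_peak: float
    length: float     # horizontal centroid displacement (m)
    duration: float   # t_peak - t_peak_prev (s)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("step duration must be > 0")
        if self.length < 0:
            raise ValueError("step length must be >= 0")


@dataclass
class TransitionEvent:
    kind: str        # "sit_down" | "get_up"
    t_start: float
    t_end: float
    vertical_excursion: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def speed(self) -> float:
        return self.vertical_excursion / self.duration


@dataclass
class ParameterSet:
    """The 15 per-subject behavioral parameters; NaN marks missing fields."""

    total_lying_pct: float = np.nan
    total_sitting_pct: float = np.nan
    out_of_room_pct: float = np.nan
    n_transitions: float = np.nan
    time_to_sit_s: float = np.nan
    speed_to_sit_mps: float = np.nan
    time_to_get_up_s: float = np.nan
    speed_to_get_up_mps: float = np.nan
    mean_step_length_m: float = np.nan
    cv_step_length: float = np.nan
    mean_step_duration_s: float = np.nan
    cv_step_duration: float = np.nan
    mean_pace_steps_per_s: float = np.nan
    cv_pace: float = np.nan
    mean_gait_speed_mps: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# centroid from depth frames
# ---------------------------------------------------------------------------

def extract_centroid_series(depth: DepthSequence, threshold_mm: float = 300.0,
                            min_pixels: int = 20) -> LabeledTrajectory:
    """Background-subtract each frame and back-project the foreground centroid.

    Foreground = pixels whose depth differs from the background by more than
    ``threshold_mm``. Frames with fewer than ``min_pixels`` foreground pixels
    are marked out_of_room; other frames carry the unknown activity code.
    When several disjoint blobs are present their joint centroid is returned
    (single-person assumption).
    """
    bg = depth.background
    n = len(depth.frames)
    if depth.frames.shape[1:] != bg.shape:
        raise ValueError("frame and background dimensions differ")
    cam = depth.camera
    V, U = np.meshgrid(np.arange(bg.shape[0]), np.arange(bg.shape[1]), indexing="ij")
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    z = np.full(n, np.nan)
    act = np.full(n, UNKNOWN, dtype=np.int8)
    for k in range(n):
        mask = np.abs(depth.frames[k] - bg) > threshold_mm
        if mask.sum() < min_pixels:
            act[k] = OUT_OF_ROOM
            continue
        pts = cam.backproject(U[mask], V[mask], depth.frames[k][mask] / 1000.0)
        x[k], y[k], z[k] = pts.mean(axis=0)
    return LabeledTrajectory(time=depth.timestamps.copy(), x=x, y=y, z=z,
                             activity=act)


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

def detect_steps(time: np.ndarray, x: np.ndarray, y: np.ndarray,
                 z: np.ndarray, bout_id: int = 0) -> list:
    """Detect steps in one contiguous walking bout.

    The vertical series is smoothed with a 0.25 s moving average; local
    maxima are retained with prominence >= 1 cm and separation >= 0.2 s.
    K retained maxima yield K-1 :class:`StepEvent`. Fewer than two maxima
    yield an empty list.
    """
    time = np.asarray(time, float)
    if len(time) < 3:
        raise ValueError("bout must contain at least 3 samples")
    fs = 1.0 / float(np.median(np.diff(time)))
    w = max(1, int(round(SMOOTH_WINDOW_S * fs)))
    zs = uniform_filter1d(np.asarray(z, float), size=w, mode="nearest")
    peaks, _ = find_peaks(zs, prominence=PEAK_PROMINENCE_M,
                          distance=max(1, int(round(MIN_PEAK_SEPARATION_S * fs))))
    events = []
    for i, j in zip(peaks[:-1], peaks[1:]):
        events.append(StepEvent(
            bout_id=bout_id,
            t_peak_prev=float(time[i]),
            t_peak=float(time[j]),
            length=float(math.hypot(x[j] - x[i], y[j] - y[i])),
            duration=float(time[j] - time[i]),
        ))
    return events


def walking_bouts(traj: LabeledTrajectory):
    """Yield (start, stop) index pairs of contiguous walking runs."""
    for i0, i1, code in _runs(traj.activity):
        if code == WALKING:
            yield i0, i1


def detect_all_steps(traj: LabeledTrajectory) -> list:
    events = []
    for bout_id, (i0, i1) in enumerate(walking_bouts(traj)):
        if i1 - i0 < 3:
            continue
        events.extend(detect_steps(traj.time[i0:i1], traj.x[i0:i1],
                                   traj.y[i0:i1], traj.z[i0:i1], bout_id=bout_id))
    return events


def gait_parameters(steps: list) -> dict:
    """Mean/CV of step length, duration and pace, plus mean gait speed.

    CV = sample standard deviation / mean. Pace is the per-step frequency
    1/duration. Gait speed is total length over total duration
    (bout-weighted), not the mean of per-step speeds. With fewer than two
    steps all fields are NaN (flagged missing).
    """
    keys = ["mean_step_length_m", "cv_step_length", "mean_step_duration_s",
            "cv_step_duration", "mean_pace_steps_per_s", "cv_pace",
            "mean_gait_speed_mps"]
    if len(steps) < 2:
        return {k: np.nan for k in keys}
    lengths = np.array([s.length for s in steps])
    durations = np.array([s.duration for s in steps])
    pace = 1.0 / durations

    def cv(a):
        return float(np.std(a, ddof=1) / np.mean(a))

    return {
        "mean_step_length_m": float(lengths.mean()),
        "cv_step_length": cv(lengths),
        "mean_step_duration_s": float(durations.mean()),
        "cv_step_duration": cv(durations),
        "mean_pace_steps_per_s": float(pace.mean()),
        "cv_pace": cv(pace),
        "mean_gait_speed_mps": float(lengths.sum() / durations.sum()),
    }


# ---------------------------------------------------------------------------
# activity budgets
# ---------------------------------------------------------------------------

def _runs(codes: np.ndarray):
    """Yield (start, stop, code) for each maximal run of identical labels."""
    codes = np.asarray(codes)
    if len(codes) == 0:
        return
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(codes)]])
    for i0, i1 in zip(starts, stops):
        yield int(i0), int(i1), int(codes[i0])


def activity_parameters(activity: np.ndarray, include_out_of_room: bool = True) -> dict:
    """Per-state time percentages and the number of activity changes.

    Percentages are fractions of the number of samples (uniform sampling
    assumed). ``include_out_of_room`` controls whether boundaries with the
    out-of-room state count toward ``n_transitions``.
    """
    activity = np.asarray(activity)
    n = len(activity)
    if n == 0:
        raise ValueError("empty label sequence")
    pct = {name: 100.0 * float(np.count_nonzero(activity == code)) / n
           for name, code in ACTIVITY_CODE.items()}
    run_codes = [c for _, _, c in _runs(activity)]
    if not include_out_of_room:
        run_codes = [c for c in run_codes if c != OUT_OF_ROOM]
        run_codes = [c for i, c in enumerate(run_codes)
                     if i == 0 or c != run_codes[i - 1]]
    n_trans = max(0, len(run_codes) - 1)
    return {
        "total_lying_pct": pct["lying"],
        "total_sitting_pct": pct["sitting"],
        "out_of_room_pct": pct["out_of_room"],
        "n_transitions": float(n_trans),
        "walking_standing_pct": pct["walking"] + pct["standing"],
    }


# ---------------------------------------------------------------------------
# sit/stand transitions
# ---------------------------------------------------------------------------

def detect_transitions(traj: LabeledTrajectory,
                       speed_threshold: float = TRANSITION_SPEED_MPS) -> list:
    """Find sit-down / get-up events at sitting<->standing/walking boundaries.

    The transition window is the maximal contiguous span around the label
    change where the absolute vertical velocity exceeds ``speed_threshold``
    (labels quantize the change instant, so the raw boundary is not used
    directly). Sitting<->lying posture changes are not scored.
    """
    t, z, act = traj.time, traj.z, traj.activity
    n = len(t)
    if n < 3:
        return []
    v = np.zeros(n)
    dz = np.diff(z)
    dt = np.diff(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        v[1:] = dz / dt
    v[0] = v[1]
    fast = np.abs(v) > speed_threshold
    fast &= np.isfinite(v)
    fs = 1.0 / float(np.median(dt))
    max_span = int(TRANSITION_MAX_SPAN_S * fs)

    events = []
    run_list = list(_runs(act))
    for (_, b0, c0), (b1, _, c1) in zip(run_list[:-1], run_list[1:]):
        pair = {c0, c1}
        if SITTING not in pair or not pair & {STANDING, WALKING}:
            continue
        kind = "sit_down" if c1 == SITTING else "get_up"
        k = b0  # first index of the new run
        if not fast[k]:  # anchor on the nearest fast sample around the change
            near = [k + d for d in range(1, max_span // 2)
                    for k_ in (1,) if 0 <= k + d < n and fast[k + d]] + \
                   [k - d for d in range(1, max_span // 2)
                    for k_ in (1,) if 0 <= k - d < n and fast[k - d]]
            if not near:
                continue
            k = min(near, key=lambda i: abs(i - k))
        lo = k
        while lo > max(1, k - max_span) and fast[lo - 1]:
            lo -= 1
        hi = k
        while hi < min(n - 1, k + max_span) and fast[hi + 1]:
            hi += 1
        i0 = max(lo - 1, 0)
        events.append(TransitionEvent(
            kind=kind, t_start=float(t[i0]), t_end=float(t[hi]),
            vertical_excursion=float(abs(z[hi] - z[i0])),
        ))
    return events


def transition_parameters(traj: LabeledTrajectory) -> dict:
    """Mean time and speed to sit down and to get up; NaN when no events."""
    events = detect_transitions(traj)
    out = {"time_to_sit_s": np.nan, "speed_to_sit_mps": np.nan,
           "time_to_get_up_s": np.nan, "speed_to_get_up_mps": np.nan}
    for kind, tkey, skey in (("sit_down", "time_to_sit_s", "speed_to_sit_mps"),
                             ("get_up", "time_to_get_up_s", "speed_to_get_up_mps")):
        sel = [e for e in events if e.kind == kind]
        if sel:
            out[tkey] = float(np.mean([e.duration for e in sel]))
            out[skey] = float(np.mean([e.speed for e in sel]))
    return out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def extract_parameters(traj: LabeledTrajectory,
                       include_out_of_room: bool = True) -> ParameterSet:
    """Compute all 15 behavioral parameters for one subject-day."""
    values = {}
    values.update(gait_parameters(detect_all_steps(traj)))
    budgets = activity_parameters(traj.activity, include_out_of_room)
    budgets.pop("walking_standing_pct")
    values.update(budgets)
    values.update(transition_parameters(traj))
    return ParameterSet(**values)


def extract_cohort(trajectories: dict, include_out_of_room: bool = True) -> pd.DataFrame:
    """Feature table: one row per subject, columns = the 15 parameter names."""
    rows = {}
    for subject_id, traj in trajectories.items():
        rows[subject_id] = extract_parameters(traj, include_out_of_room).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")[PARAMETER_NAMES]
    df.index.name = "subject_id"
    return df
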