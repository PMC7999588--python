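"""Synthetic cohort and monitoring-day generator.

Produces subject profiles with clinical scores (Tinetti, best-of-three TUG),
an eight-hour activity schedule over five states, a 3D body-centroid
trajectory with per-frame activity labels, and (optionally) rendered depth
frames — all with exhaustive ground truth so downstream extraction and
classification stages can be validated against known quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# activity vocabulary
# ---------------------------------------------------------------------------

ACTIVITIES = ("walking", "standing", "sitting", "lying", "out_of_room")
WALKING, STANDING, SITTING, LYING, OUT_OF_ROOM = range(5)
ACTIVITY_CODE = {name: code for code, name in enumerate(ACTIVITIES)}
UNKNOWN = -1  # activity not (yet) assigned, e.g. raw centroid series

# world frame: right-handed, z up, meters, seconds from day start
ROOM_SIZE = 5.0
ROOM_MARGIN = 0.4           # walkable interior is [margin, size - margin]^2
Z_STAND = 0.95              # standing centroid height
Z_LIE = 0.30                # lying centroid height
STEP_AMPLITUDE = 0.04       # vertical oscillation peak-to-trough per step (m)
LIE_RAMP_S = 2.0            # sit<->lie posture change duration (not scored)

CLINICAL_DEFAULTS = {
    # (mean, sd) per risk group for the two clinical instruments
    "tug_s": {"low": (11.82, 1.28), "high": (23.52, 5.11)},
    "tinetti": {"low": (26.25, 1.75), "high": (18.76, 4.02)},
}

# plausibility clip ranges for latent draws
_LATENT_CLIPS = {
    "step_length_m": (0.15, 0.90),
    "step_duration_s": (0.30, 0.90),
    "step_length_cv": (0.01, 0.30),
    "step_duration_cv": (0.01, 0.30),
    "get_up_speed_mps": (0.05, 0.60),
    "sit_down_speed_mps": (0.05, 0.60),
    "excursion_m": (0.25, 0.45),
    "sitting_fraction": (0.02, 0.80),
    "lying_fraction": (0.02, 0.60),
    "out_fraction": (0.02, 0.60),
}


def default_distributions(separation_mode: str) -> dict:
    """Per-parameter (mean, sd) pairs for each risk group.

    Magnitudes are calibration choices: in ``separable`` mode the group
    supports of mean step length and get-up speed are made disjoint with a
    margin; in ``overlap`` mode only step length carries a large effect,
    get-up speed and sitting budget carry small ones, and everything else is
    identical between groups.
    """
    dists = {
        "step_duration_s": {"low": (0.55, 0.05), "high": (0.55, 0.05)},
        "step_length_cv": {"low": (0.08, 0.02), "high": (0.08, 0.02)},
        "step_duration_cv": {"low": (0.08, 0.02), "high": (0.08, 0.02)},
        "sit_down_speed_mps": {"low": (0.25, 0.04), "high": (0.25, 0.04)},
        "excursion_m": {"low": (0.35, 0.03), "high": (0.35, 0.03)},
        "lying_fraction": {"low": (0.10, 0.03), "high": (0.10, 0.03)},
        "out_fraction": {"low": (0.10, 0.03), "high": (0.10, 0.03)},
    }
    if separation_mode == "separable":
        dists.update({
            "step_length_m": {"low": (0.52, 0.05), "high": (0.36, 0.06)},
            "get_up_speed_mps": {"low": (0.30, 0.05), "high": (0.17, 0.04)},
            "sitting_fraction": {"low": (0.35, 0.05), "high": (0.55, 0.05)},
        })
    elif separation_mode == "overlap":
        dists.update({
            "step_length_m": {"low": (0.51, 0.05), "high": (0.39, 0.05)},
            "get_up_speed_mps": {"low": (0.26, 0.05), "high": (0.24, 0.05)},
            "sitting_fraction": {"low": (0.42, 0.10), "high": (0.46, 0.10)},
            # wide between-subject cadence spread (and a slightly faster
            # high-group cadence, < 0.2 pooled sd) dilutes the gait-speed
            # effect inherited from step length
            "step_duration_s": {"low": (0.56, 0.15), "high": (0.54, 0.15)},
        })
    else:
        raise ValueError(f"unknown separation_mode: {separation_mode!r}")
    return dists


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Configuration of a synthetic monitored cohort."""

    n_subjects: int = 30
    n_low_risk: int = 9
    frame_rate: float = 30.0          # Hz (Kinect v2 nominal)
    day_duration: float = 28800.0     # seconds (8 h)
    separation_mode: str = "separable"
    n_incongruent: int = 0
    group_parameter_distributions: dict | None = None
    separation_margin_frac: float = 0.45   # fraction of |mu_low - mu_high|
    walk_active_fraction: float = 0.45
    min_dwell: float = 30.0
    max_dwell: float = 7200.0
    trajectory_noise_sd: float = 0.0       # additive z noise (m)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.n_low_risk <= self.n_subjects:
            raise ValueError("n_low_risk must satisfy 0 <= n_low_risk <= n_subjects")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.day_duration <= 0:
            raise ValueError("day_duration must be > 0")
        if self.n_incongruent < 0:
            raise ValueError("n_incongruent must be >= 0")
        if self.n_incongruent > self.n_subjects - self.n_low_risk:
            raise ValueError(
                "n_incongruent exceeds the number of high-risk subjects")
        for name, groups in self.distributions().items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"sd must be >= 0 for {name}/{g}")

    def distributions(self) -> dict:
        dists = default_distributions(self.separation_mode)
        if self.group_parameter_distributions:
            for name, groups in self.group_parameter_distributions.items():
                dists.setdefault(name, {}).update(
                    {g: tuple(v) for g, v in groups.items()})
        return dists


@dataclass
class SubjectProfile:
    subject_id: str
    true_group: str                   # "low" | "high"
    tinetti_score: int                # 0..28
    tug_trials: tuple                 # three durations, seconds
    fell_before: bool
    latent_gait: dict                 # step_length_m, step_duration_s, CVs
    latent_transition: dict           # sit_down_s, get_up_s, excursion_m, speeds
    latent_budget: dict               # sitting / lying / out_of_room fractions

    def validate(self) -> None:
        if not 0 <= self.tinetti_score <= 28:
            raise ValueError("tinetti_score out of range 0..28")
        if any(t <= 0 for t in self.tug_trials):
            raise ValueError("TUG trials must be > 0")
        if any(v <= 0 for k, v in self.latent_gait.items() if not k.endswith("cv")):
            raise ValueError("latent gait means must be > 0")
        if any(self.latent_gait[k] < 0 for k in ("step_length_cv", "step_duration_cv")):
            raise ValueError("CVs must be >= 0")
        total = sum(self.latent_budget.values())
        if not all(0 <= f <= 1 for f in self.latent_budget.values()) or total > 1:
            raise ValueError("budget fractions must each lie in [0,1] and sum <= 1")


@dataclass
class LabeledTrajectory:
    """Time-stamped 3D centroid samples with per-frame activity labels.

    Coordinates are NaN exactly where activity is ``out_of_room``; activity
    codes index :data:`ACTIVITIES` (-1 = unknown, for raw centroid series).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    activity: np.ndarray   # int8 codes

    def __len__(self) -> int:
        return len(self.time)

    @property
    def activity_names(self) -> np.ndarray:
        names = np.asarray(ACTIVITIES + ("unknown",), dtype=object)
        return names[self.activity]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "x_m": self.x, "y_m": self.y, "z_m": self.z,
            "activity": self.activity_names,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabeledTrajectory":
        act = np.full(len(df), UNKNOWN, dtype=np.int8)
        tokens = df["activity"].astype(str).to_numpy()
        for i, tok in enumerate(tokens):
            if tok in ACTIVITY_CODE:
                act[i] = ACTIVITY_CODE[tok]
            elif tok not in ("unknown", "nan", ""):
                raise ValueError(f"unknown activity token {tok!r} at row {i}")
        return cls(
            time=df["time_s"].to_numpy(float),
            x=df["x_m"].to_numpy(float),
            y=df["y_m"].to_numpy(float),
            z=df["z_m"].to_numpy(float),
            activity=act,
        )


@dataclass
class GroundTruth:
    """Everything the generator drew while simulating one day."""

    step_bout: np.ndarray          # bout index per drawn step
    step_length_m: np.ndarray
    step_duration_s: np.ndarray
    transitions: list              # dicts: kind, t_start, t_end, duration, speed
    totals: dict                   # exact seconds per activity
    budgets: dict                  # target fractions
    n_transitions: int             # schedule label changes

    def to_jsonable(self) -> dict:
        return {
            "steps": {
                "bout": self.step_bout.tolist(),
                "length_m": self.step_length_m.tolist(),
                "duration_s": self.step_duration_s.tolist(),
            },
            "transitions": self.transitions,
            "totals": self.totals,
            "budgets": self.budgets,
            "n_transitions": self.n_transitions,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruth":
        return cls(
            step_bout=np.asarray(d["steps"]["bout"]),
            step_length_m=np.asarray(d["steps"]["length_m"]),
            step_duration_s=np.asarray(d["steps"]["duration_s"]),
            transitions=d["transitions"],
            totals=d["totals"],
            budgets=d["budgets"],
            n_transitions=d["n_transitions"],
        )


@dataclass
class CameraModel:
    """Pinhole depth camera in a room corner, tilted below horizontal."""

    position: tuple = (0.15, 0.15, 2.2)
    yaw_deg: float = 45.0
    tilt_deg: float = 20.0
    width: int = 160
    height: int = 120
    focal_px: float = 130.0
    depth_min_mm: float = 400.0
    depth_max_mm: float = 9000.0
    room_size: float = ROOM_SIZE

    def validate(self) -> None:
        if not 0 < self.tilt_deg < 90:
            raise ValueError("tilt must lie in (0, 90) degrees")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be > 0")

    # camera frame: x right, y down, z forward (optical axis)
    def rotation(self) -> np.ndarray:
        cy, sy = math.cos(math.radians(self.yaw_deg)), math.sin(math.radians(self.yaw_deg))
        ct, st = math.cos(math.radians(self.tilt_deg)), math.sin(math.radians(self.tilt_deg))
        fwd = np.array([ct * cy, ct * sy, -st])
        right = np.array([sy, -cy, 0.0])
        down = np.cross(fwd, right)
        return np.stack([right, down, fwd])   # rows: world -> camera

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0

    def project(self, points: np.ndarray) -> tuple:
        """World points (N,3) -> pixel columns u, rows v, depth Z (m)."""
        pts = np.atleast_2d(points) - np.asarray(self.position)
        cam = pts @ self.rotation().T
        Z = cam[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.cx + self.focal_px * cam[:, 0] / Z
            v = self.cy + self.focal_px * cam[:, 1] / Z
        return u, v, Z

    def backproject(self, u: np.ndarray, v: np.ndarray, depth_m: np.ndarray) -> np.ndarray:
        """Pixel coordinates + perpendicular depth (m) -> world points (N,3)."""
        xn = (np.asarray(u, float) - self.cx) / self.focal_px
        yn = (np.asarray(v, float) - self.cy) / self.focal_px
        cam = np.stack([xn * depth_m, yn * depth_m, np.asarray(depth_m, float)], axis=-1)
        return cam @ self.rotation() + np.asarray(self.position)

    def _pixel_rays(self) -> np.ndarray:
        u, v = np.meshgrid(np.arange(self.width), np.arange(self.height))
        xn = (u - self.cx) / self.focal_px
        yn = (v - self.cy) / self.focal_px
        dirs_cam = np.stack([xn, yn, np.ones_like(xn)], axis=-1)
        return dirs_cam @ self.rotation()   # world directions, camera-z == 1

    def render_background(self) -> np.ndarray:
        """Depth image (mm) of the empty room: floor and far walls."""
        dirs = self._pixel_rays()
        px, py, pz = self.position
        s = np.full(dirs.shape[:2], np.inf)
        planes = [
            (2, 0.0, pz), (0, self.room_size, px), (1, self.room_size, py),
        ]
        for axis, level, origin in planes:
            d = dirs[..., axis]
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = (level - origin) / d
            s = np.where((cand > 0) & (cand < s), cand, s)
        depth = np.clip(s * 1000.0, None, self.depth_max_mm)
        return np.where(np.isfinite(depth), depth, self.depth_max_mm)


@dataclass
class DepthSequence:
    frames: np.ndarray       # (n, h, w) depth in mm
    timestamps: np.ndarray
    camera: CameraModel
    background: np.ndarray   # (h, w) depth in mm


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_latents(rng: np.random.Generator, dists: dict, group: str) -> tuple:
    """Draw one subject's latent parameters; return (values, z-scores)."""
    values, zscores = {}, {}
    for name, groups in dists.items():
        mu, sd = groups[group]
        raw = rng.normal(mu, sd) if sd > 0 else mu
        zscores[name] = (raw - mu) / sd if sd > 0 else 0.0
        lo, hi = _LATENT_CLIPS[name]
        values[name] = float(np.clip(raw, lo, hi))
    return values, zscores


def _separable_clip(values: dict, dists: dict, group: str, margin_frac: float) -> None:
    """Force disjoint group supports (with margin) for the discriminant latents."""
    for name in ("step_length_m", "get_up_speed_mps"):
        mu_lo = dists[name]["low"][0]
        mu_hi = dists[name]["high"][0]
        mid = 0.5 * (mu_lo + mu_hi)
        margin = margin_frac * abs(mu_lo - mu_hi)
        if mu_lo >= mu_hi:
            bound = mid + margin / 2 if group == "low" else mid - margin / 2
            values[name] = max(values[name], bound) if group == "low" else min(values[name], bound)
        else:
            values[name] = min(values[name], mid - margin / 2) if group == "low" \
                else max(values[name], mid + margin / 2)


def make_cohort(config: CohortConfig, seed: int) -> list:
    """Generate the cohort of :class:`SubjectProfile`.

    Clinical scores are drawn group-conditionally (low: TUG 11.82 +/- 1.28 s,
    Tinetti 26.25 +/- 1.75; high: 23.52 +/- 5.11 and 18.76 +/- 4.02) and
    co-vary with the latent gait through a shared slowness score, so the
    reference label is learnable from behavior. Scores are additionally kept
    on the label-consistent side of the clinical cutoffs so that true group
    and clinical label coincide.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    dists = config.distributions()
    profiles = []
    for i in range(config.n_subjects):
        group = "low" if i < config.n_low_risk else "high"
        values, zs = _draw_latents(rng, dists, group)
        if config.separation_mode == "separable":
            _separable_clip(values, dists, group, config.separation_margin_frac)

        budget = {
            "sitting": values["sitting_fraction"],
            "lying": values["lying_fraction"],
            "out_of_room": values["out_fraction"],
        }
        total = sum(budget.values())
        if total > 0.85:
            budget = {k: v * 0.85 / total for k, v in budget.items()}

        slowness = -(zs["step_length_m"] + zs["get_up_speed_mps"]) / math.sqrt(2)
        mu_tug, sd_tug = CLINICAL_DEFAULTS["tug_s"][group]
        trials = mu_tug + sd_tug * (0.8 * slowness + 0.6 * rng.normal(size=3))
        trials = np.clip(trials, 4.0, None)
        mu_tin, sd_tin = CLINICAL_DEFAULTS["tinetti"][group]
        tinetti = int(round(np.clip(
            mu_tin + sd_tin * (-0.8 * slowness + 0.6 * rng.normal()), 0, 28)))

        # keep scores on the label-consistent side of the clinical cutoffs
        if group == "low":
            trials = np.clip(trials, None, 13.0)
            tinetti = max(tinetti, 21)
        elif trials.min() < 13.5 and tinetti >= 21:
            trials = trials + (14.0 - trials.min())

        excursion = values["excursion_m"]
        latent_transition = {
            "excursion_m": excursion,
            "get_up_speed_mps": values["get_up_speed_mps"],
            "sit_down_speed_mps": values["sit_down_speed_mps"],
            "get_up_s": excursion / values["get_up_speed_mps"],
            "sit_down_s": excursion / values["sit_down_speed_mps"],
        }
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            true_group=group,
            tinetti_score=tinetti,
            tug_trials=tuple(round(float(t), 2) for t in trials),
            fell_before=bool(rng.random() < (0.5 if group == "high" else 0.15)),
            latent_gait={k: values[k] for k in (
                "step_length_m", "step_duration_s", "step_length_cv", "step_duration_cv")},
            latent_transition=latent_transition,
            latent_budget=budget,
        ))

    # test-incongruent subjects: near-perfect Tinetti, clearly slow TUG
    if config.n_incongruent:
        targets = range(config.n_subjects - config.n_incongruent, config.n_subjects)
        for j, idx in enumerate(targets):
            p = profiles[idx]
            if config.n_incongruent == 2:
                best = (17.0, 17.81)[j]
            else:
                best = 17.0 + 0.5 * j
            profiles[idx] = SubjectProfile(
                subject_id=p.subject_id, true_group="high", tinetti_score=27,
                tug_trials=(best, round(best + 0.9, 2), round(best + 1.6, 2)),
                fell_before=(j == 0), latent_gait=p.latent_gait,
                latent_transition=p.latent_transition, latent_budget=p.latent_budget,
            )
    for p in profiles:
        p.validate()
    return profiles


# ---------------------------------------------------------------------------
# day schedule
# ---------------------------------------------------------------------------

def _split(total: float, k: int, rng: np.random.Generator, min_part: float) -> list:
    """Split `total` into k random parts summing exactly to total."""
    if k <= 1 or total <= 0:
        return [total] if total > 0 else []
    min_part = min(min_part, 0.5 * total / k)
    w = rng.dirichlet(np.ones(k))
    return list(min_part + w * (total - k * min_part))


def _build_schedule(profile: SubjectProfile, config: CohortConfig,
                    rng: np.random.Generator) -> list:
    """Semi-Markov-style day plan: list of (state, duration) with exact budgets."""
    T = config.day_duration
    b = profile.latent_budget
    t_sit = b["sitting"] * T
    t_lie = b["lying"] * T
    t_out = b["out_of_room"] * T
    t_active = T - t_sit - t_lie - t_out
    if t_active < 30.0:
        raise ValueError("day too short to host the activity bouts")
    t_walk = config.walk_active_fraction * t_active
    t_stand = t_active - t_walk
    min_d = config.min_dwell

    def n_bouts(total, typical):
        if total < min(min_d, typical):
            return 0
        return max(1, int(round(total / typical)))

    sit_parts = _split(t_sit, n_bouts(t_sit, 1500.0), rng, min_d)
    lie_parts = _split(t_lie, n_bouts(t_lie, 2400.0), rng, min_d)
    out_parts = _split(t_out, n_bouts(t_out, 1200.0), rng, min_d)

    # each sitting bout becomes [sit] or [sit/2, lie, sit/2]
    sit_blocks = [[(SITTING, sp)] for sp in sit_parts]
    leftovers = []
    for j, lp in enumerate(lie_parts):
        if sit_blocks:
            blk = sit_blocks[j % len(sit_blocks)]
            state, dur = blk[0]
            blk[:1] = [(SITTING, dur / 2), (LYING, lp), (SITTING, dur / 2)]
        else:
            leftovers.append([(LYING, lp)])

    blocks = []
    if sit_blocks:
        stand_parts = _split(t_stand, 2 * len(sit_blocks), rng, min_d)
        for j, blk in enumerate(sit_blocks):
            blocks.append([(STANDING, stand_parts[2 * j]), *blk,
                           (STANDING, stand_parts[2 * j + 1])])
    else:
        blocks = [[(STANDING, p)] for p in _split(t_stand, max(1, n_bouts(t_stand, 1200.0)), rng, min_d)]
    blocks += leftovers
    blocks += [[(OUT_OF_ROOM, op)] for op in out_parts]
    rng.shuffle(blocks)

    walk_parts = _split(t_walk, len(blocks) + 1, rng, 8.0)
    if not walk_parts:
        walk_parts = [t_walk] * (1 if t_walk > 0 else 0)
    schedule = []
    if walk_parts:
        schedule.append((WALKING, walk_parts[0]))
    for j, blk in enumerate(blocks):
        schedule.extend(blk)
        if j + 1 < len(walk_parts):
            schedule.append((WALKING, walk_parts[j + 1]))
    # merge zero/negative and adjacent identical states defensively
    merged = []
    for state, dur in schedule:
        if dur <= 0:
            continue
        if merged and merged[-1][0] == state:
            merged[-1][1] += dur
        else:
            merged.append([state, dur])
    return [(s, d) for s, d in merged]


# ---------------------------------------------------------------------------
# trajectory realization
# ---------------------------------------------------------------------------

def _inside_room(xx: float, yy: float) -> bool:
    lo, hi = ROOM_MARGIN, ROOM_SIZE - ROOM_MARGIN
    return lo <= xx <= hi and lo <= yy <= hi


def _walk_bout(t: np.ndarray, i0: int, i1: int, t0: float, t1: float,
               pos: np.ndarray, heading: float, gait: dict,
               rng: np.random.Generator):
    """Realize one walking bout; returns (end_pos, end_heading, lengths, durations).

    Each drawn step is one vertical-oscillation cycle; consecutive retained
    maxima are spaced by the step durations and separated horizontally by the
    step lengths, so a reference peak finder recovers the drawn gait exactly.
    """
    L, D = gait["step_length_m"], gait["step_duration_s"]
    cvL, cvD = gait["step_length_cv"], gait["step_duration_cv"]
    bout = t1 - t0
    m = int(bout / 0.3) + 4
    d = np.clip(rng.normal(D, max(cvD * D, 1e-9), m), 0.30, 1.20)
    l = np.clip(rng.normal(L, max(cvL * L, 1e-9), m), 0.10, 1.00)
    c = np.cumsum(d)
    n = int(np.searchsorted(c, bout - 0.05, side="right"))
    # keep room for the declining half-cycle after the last peak, so the
    # last maximum is an interior local maximum of the bout
    while n > 3 and c[n - 1] + 0.5 * d[n - 1] > bout - 0.05:
        n -= 1
    if n < 3:
        n = min(3, m)
        total = c[n - 1] + 0.5 * d[n - 1]
        if total > bout - 0.05:       # squeeze to fit very short bouts
            d = d * (bout - 0.05) / total
            c = np.cumsum(d)
    d, l = d[:n], l[:n]
    peaks_t = t0 + np.cumsum(d)

    px = np.empty(n + 1)
    py = np.empty(n + 1)
    px[0], py[0] = pos
    h = heading
    center = ROOM_SIZE / 2
    for i in range(n):
        h += rng.normal(0.0, 0.2)
        ex, ey = px[i] + l[i] * math.cos(h), py[i] + l[i] * math.sin(h)
        if not _inside_room(ex, ey):
            h = math.atan2(center - py[i], center - px[i]) + rng.normal(0.0, 0.3)
            ex, ey = px[i] + l[i] * math.cos(h), py[i] + l[i] * math.sin(h)
            ex = min(max(ex, ROOM_MARGIN), ROOM_SIZE - ROOM_MARGIN)
            ey = min(max(ey, ROOM_MARGIN), ROOM_SIZE - ROOM_MARGIN)
        px[i + 1], py[i + 1] = ex, ey

    knot_t = np.concatenate([[t0], peaks_t])
    phase = np.concatenate([[-0.5], np.arange(n, dtype=float)])
    tail_t = peaks_t[-1] + 0.5 * d[-1]
    if tail_t < t1:
        knot_t = np.append(knot_t, tail_t)
        phase = np.append(phase, n - 0.5)
        px = np.append(px, px[-1])
        py = np.append(py, py[-1])

    ts = t[i0:i1]
    u = np.interp(ts, knot_t, phase)
    zseg = Z_STAND - 0.5 * STEP_AMPLITUDE * (1.0 - np.cos(2.0 * np.pi * u))
    xseg = np.interp(ts, knot_t, px)
    yseg = np.interp(ts, knot_t, py)
    return (np.array([px[-1], py[-1]]), h, l, d, xseg, yseg, zseg)


def simulate_day(profile: SubjectProfile, config: CohortConfig, seed: int):
    """Simulate one monitoring day.

    Returns ``(LabeledTrajectory, GroundTruth)``. Deterministic for a fixed
    (profile, config, seed).
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    schedule = _build_schedule(profile, config, rng)
    durs = np.array([d for _, d in schedule])
    states = np.array([s for s, _ in schedule], dtype=np.int8)
    edges = np.concatenate([[0.0], np.cumsum(durs)])
    edges[-1] = config.day_duration

    fs = config.frame_rate
    N = int(round(config.day_duration * fs))
    t = np.arange(N) / fs
    seg_of = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(schedule) - 1)
    act = states[seg_of]

    E = profile.latent_transition["excursion_m"]
    z_sit = Z_STAND - E
    base_z = {WALKING: Z_STAND - STEP_AMPLITUDE, STANDING: Z_STAND,
              SITTING: z_sit, LYING: Z_LIE}

    x = np.empty(N)
    y = np.empty(N)
    z = np.empty(N)
    pos = np.array([2.5, 2.0])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    step_bout, step_len, step_dur = [], [], []
    bout_counter = 0
    for j, (state, _) in enumerate(schedule):
        i0 = int(np.searchsorted(t, edges[j], side="left"))
        i1 = int(np.searchsorted(t, edges[j + 1], side="left")) if j + 1 < len(edges) else N
        if j == len(schedule) - 1:
            i1 = N
        if i1 <= i0:
            continue
        if state == OUT_OF_ROOM:
            x[i0:i1] = np.nan
            y[i0:i1] = np.nan
            z[i0:i1] = np.nan
        elif state == WALKING:
            pos, heading, l, d, xs, ys, zs = _walk_bout(
                t, i0, i1, edges[j], edges[j + 1], pos, heading,
                profile.latent_gait, rng)
            x[i0:i1], y[i0:i1], z[i0:i1] = xs, ys, zs
            step_bout.extend([bout_counter] * len(l))
            step_len.extend(l)
            step_dur.extend(d)
            bout_counter += 1
        else:
            x[i0:i1] = pos[0]
            y[i0:i1] = pos[1]
            z[i0:i1] = base_z[int(state)]

    # posture-change ramps at segment boundaries
    transitions = []
    for j in range(len(schedule) - 1):
        s0, s1 = int(states[j]), int(states[j + 1])
        tc = edges[j + 1]
        pair = {s0, s1}
        if SITTING in pair and pair & {STANDING, WALKING}:
            kind = "sit_down" if s1 == SITTING else "get_up"
            dur = profile.latent_transition[f"{kind}_s"]
            z_from = Z_STAND if s0 != SITTING else z_sit
            z_to = z_sit if s1 == SITTING else Z_STAND
            lo = int(np.searchsorted(t, tc - dur / 2, side="left"))
            hi = int(np.searchsorted(t, tc + dur / 2, side="left"))
            if hi > lo:
                z[lo:hi] = z_from + (z_to - z_from) * \
                    (t[lo:hi] - (tc - dur / 2)) / dur
            transitions.append({
                "kind": kind, "t_start": float(tc - dur / 2),
                "t_end": float(tc + dur / 2), "duration": float(dur),
                "vertical_excursion": float(E), "speed": float(E / dur),
            })
        elif pair == {SITTING, LYING}:
            z_from = base_z[s0]
            z_to = base_z[s1]
            lo = int(np.searchsorted(t, tc - LIE_RAMP_S / 2, side="left"))
            hi = int(np.searchsorted(t, tc + LIE_RAMP_S / 2, side="left"))
            if hi > lo:
                z[lo:hi] = z_from + (z_to - z_from) * \
                    (t[lo:hi] - (tc - LIE_RAMP_S / 2)) / LIE_RAMP_S

    if config.trajectory_noise_sd > 0:
        z += rng.normal(0.0, config.trajectory_noise_sd, N)

    totals = {name: 0.0 for name in ACTIVITIES}
    for (state, _), dur in zip(schedule, durs):
        totals[ACTIVITIES[state]] += float(dur)
    # absorb float drift into the largest bucket so totals sum exactly to T
    drift = config.day_duration - sum(totals.values())
    totals[max(totals, key=totals.get)] += drift

    traj = LabeledTrajectory(time=t, x=x, y=y, z=z, activity=act)
    truth = GroundTruth(
        step_bout=np.asarray(step_bout, dtype=int),
        step_length_m=np.asarray(step_len, dtype=float),
        step_duration_s=np.asarray(step_dur, dtype=float),
        transitions=transitions,
        totals=totals,
        budgets=dict(profile.latent_budget),
        n_transitions=len(schedule) - 1,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# depth rendering
# ---------------------------------------------------------------------------

def render_depth_sequence(trajectory: LabeledTrajectory, camera: CameraModel,
                          seed: int = 0, noise_sd_mm: float = 10.0,
                          person_rx: float = 0.18, person_rz: float = 0.45) -> DepthSequence:
    """Render the trajectory as depth frames over the empty-room background.

    The person is an elliptical blob centered on the projected centroid,
    rendered at the centroid's constant perpendicular depth so that the mean
    of back-projected foreground pixels recovers the centroid. Out-of-room
    samples (and centroids outside the frustum, with a warning) render as
    pure background.
    """
    camera.validate()
    rng = np.random.default_rng(seed)
    bg = camera.render_background()
    n = len(trajectory)
    frames = np.broadcast_to(bg, (n,) + bg.shape).copy()
    pts = np.stack([trajectory.x, trajectory.y, trajectory.z], axis=1)
    in_room = np.isfinite(pts).all(axis=1)
    if in_room.any():
        u, v, Z = camera.project(pts[in_room])
        idxs = np.nonzero(in_room)[0]
        for u0, v0, Z0, k in zip(u, v, Z, idxs):
            if Z0 <= camera.depth_min_mm / 1000.0 or not (
                    0 <= u0 < camera.width and 0 <= v0 < camera.height):
                warnings.warn(f"centroid outside camera frustum at frame {k}; "
                              "rendering background", stacklevel=2)
                continue
            a = camera.focal_px * person_rx / Z0
            b = camera.focal_px * person_rz / Z0
            uu = np.arange(max(0, int(u0 - a)), min(camera.width, int(u0 + a) + 2))
            vv = np.arange(max(0, int(v0 - b)), min(camera.height, int(v0 + b) + 2))
            if not len(uu) or not len(vv):
                continue
            U, V = np.meshgrid(uu, vv)
            mask = ((U - u0) / a) ** 2 + ((V - v0) / b) ** 2 <= 1.0
            depth_mm = Z0 * 1000.0
            sub = frames[k][np.ix_(vv, uu)]
            sub[mask & (depth_mm < sub)] = depth_mm
            frames[k][np.ix_(vv, uu)] = sub
    if noise_sd_mm > 0:
        frames = np.clip(frames + rng.normal(0.0, noise_sd_mm, frames.shape), 0.0, None)
    return DepthSequence(frames=frames, timestamps=trajectory.time.copy(),
                         camera=camera, background=bg)


# ---------------------------------------------------------------------------
# fast parameter-level sampling (no trajectory) for statistics calibration
# ---------------------------------------------------------------------------

def sample_parameter_sets(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw the 15 behavioral parameters directly from the group-conditional
    effect structure, bypassing trajectory simulation.

    Used for statistical power/calibration studies where only the parameter
    distributions matter. Columns match the extraction feature table.
    """
    profiles = make_cohort(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    rows = []
    for p in profiles:
        g = p.latent_gait
        tr = p.latent_transition
        b = p.latent_budget
        L = g["step_length_m"] + rng.normal(0, 0.005)
        D = g["step_duration_s"] + rng.normal(0, 0.005)
        rows.append({
            "subject_id": p.subject_id,
            "total_lying_pct": np.clip(b["lying"] * 100 + rng.normal(0, 1.5), 0, 100),
            "total_sitting_pct": np.clip(b["sitting"] * 100 + rng.normal(0, 2.0), 0, 100),
            "out_of_room_pct": np.clip(b["out_of_room"] * 100 + rng.normal(0, 1.5), 0, 100),
            "n_transitions": int(rng.poisson(40)),
            "time_to_sit_s": tr["sit_down_s"] + rng.normal(0, 0.05),
            "speed_to_sit_mps": tr["sit_down_speed_mps"] + rng.normal(0, 0.01),
            "time_to_get_up_s": tr["get_up_s"] + rng.normal(0, 0.05),
            "speed_to_get_up_mps": tr["get_up_speed_mps"] + rng.normal(0, 0.01),
            "mean_step_length_m": L,
            "cv_step_length": abs(g["step_length_cv"] + rng.normal(0, 0.01)),
            "mean_step_duration_s": D,
            "cv_step_duration": abs(g["step_duration_cv"] + rng.normal(0, 0.01)),
            "mean_pace_steps_per_s": 1.0 / D,
            "cv_pace": abs(g["step_duration_cv"] + rng.normal(0, 0.01)),
            "mean_gait_speed_mps": (L / D) * (1.0 + rng.normal(0, 0.08)),
        })
    return pd.DataFrame(rows).set_index("subject_id")
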