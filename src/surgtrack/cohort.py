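"""Synthetic skill cohorts: trajectory sets with class-conditional motion.

Surgeon groups (novice / skilled / expert) differ in how much their
instrument tips travel per unit time, how straight their movements are,
how often instruments leave the view or collide, and how the console is
used.  The generator emulates exactly these differences at the trajectory
level: each subject gets two instruments whose tips alternate between
pauses and wandering movement episodes, with out-of-view excursions,
collision approaches, arm swaps and camera-motion intervals injected at
class-conditional rates.  The nine motion metrics computed from a
subject's trajectories therefore recover the class parameters, and
cohorts of such subjects are the test bed for the skill classifier.

Effect sizes are free parameters of the simulation; the defaults make the
classes separable but overlapping, with the economy-of-motion rate as the
dominant separator (total path per unit time falls with skill as duty
cycle drops and paths straighten).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .indicators import IndicatorState, gate_trajectory
from .metrics import MetricVector, compute_metrics, METRIC_NAMES

CLASSES = ("novice", "skilled", "expert")


@dataclass(frozen=True)
class SkillClassParams:
    """Class-conditional motion statistics (means + between-subject s.d.)."""

    duration_s: float = 240.0
    duration_sd: float = 25.0
    speed_mm_s: float = 4.5  # tip speed while moving
    speed_sd: float = 0.4
    path_inefficiency: float = 1.45  # path length / net displacement while moving
    path_inefficiency_sd: float = 0.2
    duty_cycle: float = 0.45  # fraction of time in motion
    duty_cycle_sd: float = 0.05
    out_of_view_rate: float = 2.0  # expected excursions per video
    collision_rate: float = 1.5
    instrument_change_rate: float = 2.0
    camera_use_rate: float = 3.0


DEFAULT_CLASS_PARAMS: Dict[str, SkillClassParams] = {
    "novice": SkillClassParams(
        duration_s=300.0,
        speed_mm_s=4.0,
        path_inefficiency=1.7,
        duty_cycle=0.70,
        out_of_view_rate=4.0,
        collision_rate=3.0,
        instrument_change_rate=3.0,
        camera_use_rate=4.0,
    ),
    "skilled": SkillClassParams(
        duration_s=240.0,
        speed_mm_s=4.5,
        path_inefficiency=1.45,
        duty_cycle=0.45,
        out_of_view_rate=2.0,
        collision_rate=1.5,
        instrument_change_rate=2.0,
        camera_use_rate=3.0,
    ),
    "expert": SkillClassParams(
        duration_s=200.0,
        speed_mm_s=5.0,
        path_inefficiency=1.2,
        duty_cycle=0.30,
        out_of_view_rate=0.7,
        collision_rate=0.5,
        instrument_change_rate=1.0,
        camera_use_rate=2.0,
    ),
}


def economy_dominant_class_params() -> Dict[str, SkillClassParams]:
    """Class parameters injecting economy of motion as the dominant
    separator: the duty cycle (hence path length per unit time) differs
    strongly across classes while speed, straightness, duration and event
    rates stay mild or flat."""
    return {
        "novice": SkillClassParams(
            duration_s=240.0,
            speed_mm_s=4.5,
            path_inefficiency=1.45,
            duty_cycle=0.75,
            out_of_view_rate=2.5,
            collision_rate=2.0,
            instrument_change_rate=2.0,
            camera_use_rate=3.0,
        ),
        "skilled": SkillClassParams(
            duration_s=240.0,
            speed_mm_s=4.5,
            path_inefficiency=1.45,
            duty_cycle=0.50,
            out_of_view_rate=2.0,
            collision_rate=1.5,
            instrument_change_rate=2.0,
            camera_use_rate=3.0,
        ),
        "expert": SkillClassParams(
            duration_s=240.0,
            speed_mm_s=4.5,
            path_inefficiency=1.45,
            duty_cycle=0.28,
            out_of_view_rate=1.5,
            collision_rate=1.0,
            instrument_change_rate=2.0,
            camera_use_rate=3.0,
        ),
    }


@dataclass(frozen=True)
class SkillCohortConfig:
    n_per_class: int = 10
    class_params: Dict[str, SkillClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    counts: Dict[str, int] | None = None  # overrides n_per_class (imbalance)
    fps: float = 5.0
    seed: int = 0

    def validate(self):
        if self.counts is None and self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for key in CLASSES:
            if key not in self.class_params:
                raise ValueError(f"missing class parameters for {key!r}")
        n, s, e = (self.class_params[c] for c in CLASSES)
        for attr in ("path_inefficiency", "out_of_view_rate", "collision_rate"):
            if not (
                getattr(e, attr) <= getattr(s, attr) <= getattr(n, attr)
            ):
                raise ValueError(
                    f"class means must be ordered expert <= skilled <= novice in {attr}"
                )


@dataclass
class SkillSubject:
    """One simulated operation: trajectories + console states + label."""

    label: str
    trajectories: Dict[int, pd.DataFrame]  # gated, mm coordinates
    states: List[IndicatorState]
    active_sets: List[frozenset]
    arm_of: Dict[int, str]
    boxes_by_identity: Dict[int, Dict[int, Tuple]]
    fps: float

    def metrics(self) -> MetricVector:
        return compute_metrics(
            self.trajectories,
            self.states,
            self.fps,
            self.arm_of,
            active_sets=self.active_sets,
            boxes_by_identity=self.boxes_by_identity,
        )


_WORKSPACE = (120.0, 90.0)  # mm
_BOX_MM = 9.0  # nominal tip box side used for collision overlap


def _wandering_path(
    rng: np.random.Generator,
    n: int,
    fps: float,
    speed: float,
    inefficiency: float,
    duty: float,
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
):
    """Pause/move tip path; wander angle noise realizes the inefficiency.

    For an angular random walk with per-step s.d. ``sigma`` the expected
    straightness of an episode falls as sigma grows; sigma is driven by
    ``inefficiency - 1`` (zero gives perfectly straight episodes).
    """
    pos = np.array(
        [rng.uniform(*x_range), rng.uniform(*y_range)]
    )
    theta = rng.uniform(0, 2 * np.pi)
    sigma = 1.1 * np.sqrt(max(inefficiency - 1.0, 0.0)) / np.sqrt(fps / 5.0)
    xy = np.empty((n, 2))
    moving = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        move_len = max(int(rng.exponential(2.2 * fps)), int(fps * 0.4))
        pause_len = max(int(move_len * (1 - duty) / max(duty, 1e-6)), 0)
        for _ in range(min(move_len, n - i)):
            theta += rng.normal(0.0, sigma)
            step = speed / fps
            cand = pos + step * np.array([np.cos(theta), np.sin(theta)])
            # reflect at the workspace boundary
            if not x_range[0] <= cand[0] <= x_range[1]:
                theta = np.pi - theta
                cand = pos + step * np.array([np.cos(theta), np.sin(theta)])
            if not y_range[0] <= cand[1] <= y_range[1]:
                theta = -theta
                cand = pos + step * np.array([np.cos(theta), np.sin(theta)])
            pos = np.clip(cand, (x_range[0], y_range[0]), (x_range[1], y_range[1]))
            xy[i] = pos
            moving[i] = True
            i += 1
            if i >= n:
                break
        for _ in range(min(pause_len, n - i)):
            xy[i] = pos
            i += 1
            if i >= n:
                break
    return xy, moving


def _poisson_intervals(
    rng: np.random.Generator, rate: float, n: int, min_len: int, max_len: int, guard: int
):
    """Non-overlapping random intervals; count ~ Poisson(rate)."""
    k = rng.poisson(rate)
    out = []
    tries = 0
    while len(out) < k and tries < 200:
        tries += 1
        ln = int(rng.integers(min_len, max_len + 1))
        if n - ln - guard <= guard:
            break
        s = int(rng.integers(guard, n - ln - guard))
        if all(s + ln + guard <= a or s >= b + guard for a, b in out):
            out.append((s, s + ln))
    return sorted(out)


def generate_subject(
    label: str, params: SkillClassParams, fps: float, rng: np.random.Generator
) -> SkillSubject:
    dur = max(rng.normal(params.duration_s, params.duration_sd), 60.0)
    n = int(dur * fps)
    speed = max(rng.normal(params.speed_mm_s, params.speed_sd), 0.5)
    ineff = max(rng.normal(params.path_inefficiency, params.path_inefficiency_sd), 1.0)
    duty = float(np.clip(rng.normal(params.duty_cycle, params.duty_cycle_sd), 0.05, 0.95))

    W, H = _WORKSPACE
    # disjoint working halves (gap wider than the collision box), so box
    # overlap happens exactly at the steered collision events
    xy0, _ = _wandering_path(rng, n, fps, speed, ineff, duty, (5, 0.5 * W - 6), (5, H - 5))
    xy1, _ = _wandering_path(rng, n, fps, speed, ineff, duty, (0.5 * W + 6, W - 5), (5, H - 5))

    # collisions: steer the right instrument briefly onto the left one
    col_iv = _poisson_intervals(
        rng, params.collision_rate, n, int(0.8 * fps), int(1.5 * fps), int(3 * fps)
    )
    for s, e in col_iv:
        ramp = int(0.6 * fps)
        lo, hi = max(s - ramp, 0), min(e + ramp, n)
        r = np.zeros(n)
        r[s:e] = 1.0
        if s - lo:
            r[lo:s] = np.linspace(0, 1, s - lo, endpoint=False)
        if hi - e:
            r[e:hi] = np.linspace(1, 0, hi - e)
        target = xy0 + (0.6 * _BOX_MM, 0.0)
        xy1 = xy1 + r[:, None] * (target - xy1)

    # out-of-view excursions, split across the two instruments
    vis = np.ones((2, n), dtype=bool)
    oov_iv = _poisson_intervals(
        rng, params.out_of_view_rate, n, int(1.5 * fps), int(4 * fps), int(2 * fps)
    )
    for j, (s, e) in enumerate(oov_iv):
        vis[j % 2, s:e] = False

    # camera-motion intervals: view pans; both tips shift on screen
    cam_iv = _poisson_intervals(
        rng, params.camera_use_rate, n, int(1 * fps), int(3 * fps), int(2 * fps)
    )
    cam = np.zeros(n, dtype=bool)
    drift = np.zeros((n, 2))
    for s, e in cam_iv:
        cam[s:e] = True
        d = rng.uniform(-1.2, 1.2, 2) / fps
        drift[s:e] = d
    drift = np.cumsum(drift, axis=0)
    xy0 = xy0 + drift
    xy1 = xy1 + drift

    # arm swaps: the right arm alternates identity 1 <-> 2
    chg = _poisson_intervals(
        rng, params.instrument_change_rate, n, 1, 1, int(5 * fps)
    )
    swap_frames = [s for s, _ in chg]
    active_sets = []
    right_ident = 1
    nxt = 0
    right_ident_per_frame = np.empty(n, dtype=int)
    for f in range(n):
        if nxt < len(swap_frames) and f >= swap_frames[nxt]:
            right_ident = 3 - right_ident  # 1 <-> 2
            nxt += 1
        right_ident_per_frame[f] = right_ident
        active_sets.append(frozenset({0, right_ident}))

    states = [
        IndicatorState(f, bool(cam[f]), frozenset({"left", "right"}))
        for f in range(n)
    ]
    arm_of = {0: "left", 1: "right", 2: "right"}

    def _traj(ident: int, xy: np.ndarray, visible: np.ndarray, sel: np.ndarray):
        df = pd.DataFrame(
            {
                "frame": np.arange(n)[sel],
                "x_mm": xy[sel, 0],
                "y_mm": xy[sel, 1],
                "visible": visible[sel],
            }
        )
        g = gate_trajectory(df, states, arm=arm_of[ident])
        # an identity only moves while it is the one mounted on its arm
        g.loc[~g["visible"].astype(bool), "valid_motion"] = False
        return g

    all_f = np.ones(n, dtype=bool)
    trajectories = {
        0: _traj(0, xy0, vis[0], all_f),
        1: _traj(1, xy1, vis[1], right_ident_per_frame == 1),
        2: _traj(2, xy1, vis[1], right_ident_per_frame == 2),
    }
    if not (right_ident_per_frame == 2).any():
        del trajectories[2]

    boxes: Dict[int, Dict[int, Tuple]] = {0: {}, 1: {}}
    half = _BOX_MM / 2
    for f in range(n):
        if vis[0, f]:
            boxes[0][f] = (xy0[f, 0] - half, xy0[f, 1] - half, _BOX_MM, _BOX_MM)
        if vis[1, f]:
            ident = int(right_ident_per_frame[f])
            boxes.setdefault(ident, {})[f] = (
                xy1[f, 0] - half,
                xy1[f, 1] - half,
                _BOX_MM,
                _BOX_MM,
            )
    return SkillSubject(label, trajectories, states, active_sets, arm_of, boxes, fps)


def generate_skill_cohort(config: SkillCohortConfig) -> List[SkillSubject]:
    """Generate a cohort; balanced by default, imbalanced via ``counts``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts or {c: config.n_per_class for c in CLASSES}
    subjects = []
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            subjects.append(
                generate_subject(cls, config.class_params[cls], config.fps, rng)
            )
    return subjects


def cohort_metric_table(subjects: Sequence[SkillSubject]):
    """(metrics DataFrame, labels Series) for a cohort."""
    rows = [s.metrics().as_row() for s in subjects]
    table = pd.DataFrame(rows).reset_index(drop=True)
    labels = pd.Series([s.label for s in subjects], name="label")
    return table, labels
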