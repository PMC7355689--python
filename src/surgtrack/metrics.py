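"""The nine motion metrics and their two-stage normalization.

The metrics quantify the motion economy that structured rating rubrics
(OSATS/GEARS) score by eye: completion time, out-of-view excursions,
instrument collisions, economy of motion (total tip path length),
average speed, number of discrete movements, the movement straightness
ratio ("economic factor"), instrument changes, and laparoscope usage.

All functions consume *gated, calibrated* trajectories: per-identity
DataFrames with columns ``frame, x_mm, y_mm, visible, valid_motion,
active, camera_moving`` (see :func:`surgtrack.indicators.gate_trajectory`)
plus the per-frame indicator states.  Displacement is only ever summed
across consecutive frames on which motion is valid — screen motion and
inactive-arm drift never masquerade as hand motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .indicators import IndicatorState

METRIC_NAMES = [
    "time_to_completion",
    "instruments_out_of_view",
    "instrument_collisions",
    "economy_of_motion",
    "average_speed",
    "number_of_movements",
    "economic_factor",
    "instrument_changes",
    "laparoscopy_duration",
]

# metrics divided by completion time in normalization stage 1
_DURATION_DEPENDENT = [
    "instruments_out_of_view",
    "instrument_collisions",
    "economy_of_motion",
    "number_of_movements",
    "instrument_changes",
    "laparoscopy_duration",
]


@dataclass
class MetricVector:
    time_to_completion: float  # s
    instruments_out_of_view: float  # count
    instrument_collisions: float  # count
    economy_of_motion: float  # mm
    average_speed: float  # mm/s
    number_of_movements: float  # count
    economic_factor: float  # dimensionless, NaN when undefined
    instrument_changes: float  # count
    laparoscopy_duration: float  # s
    laparoscopy_count: float = 0.0  # companion to the duration

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)

    def as_row(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in METRIC_NAMES})


TrajectorySet = Dict[int, pd.DataFrame]


def _valid_steps(df: pd.DataFrame):
    """Consecutive-frame displacement vectors on valid-motion samples."""
    d = df.sort_values("frame")
    fr = d["frame"].to_numpy()
    xy = d[["x_mm", "y_mm"]].to_numpy(float)
    ok = d["valid_motion"].to_numpy(bool)
    consec = np.diff(fr) == 1
    both = ok[:-1] & ok[1:] & consec
    return xy[1:][both] - xy[:-1][both]


def economy_of_motion(trajectories: TrajectorySet) -> float:
    """Total tip path length (mm) over valid-motion samples, all instruments."""
    total = 0.0
    for df in trajectories.values():
        steps = _valid_steps(df)
        if len(steps):
            total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return total


def _valid_motion_duration(trajectories: TrajectorySet, fps: float) -> float:
    n = 0
    for df in trajectories.values():
        n += len(_valid_steps(df))
    return n / fps


def _moving_time(
    trajectories: TrajectorySet, fps: float, speed_threshold: float = 2.0
) -> float:
    """Total time (s) the tips spend in motion (smoothed speed above
    threshold) on valid-motion samples."""
    n = 0
    for df in trajectories.values():
        n += int((_speed_series(df, fps) > speed_threshold).sum())
    return n / fps


def average_speed(
    trajectories: TrajectorySet, fps: float, speed_threshold: float = 2.0
) -> float:
    """Mean tip speed while in motion: economy of motion over moving time.

    Pauses do not dilute the speed; a video with no valid motion at all
    has average speed 0 (there is nothing to divide).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if not any(len(df) for df in trajectories.values()):
        raise ValueError("zero valid-motion duration")
    eom = economy_of_motion(trajectories)
    mt = _moving_time(trajectories, fps, speed_threshold)
    if mt == 0:
        return 0.0
    return eom / mt


def _maximal_true_runs(flags: np.ndarray) -> List[Tuple[int, int]]:
    runs = []
    in_run = False
    for i, f in enumerate(flags):
        if f and not in_run:
            start, in_run = i, True
        elif not f and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(flags)))
    return runs


def count_out_of_view(
    trajectories: TrajectorySet,
    states: Sequence[IndicatorState],
    arm_of: Dict[int, str],
) -> int:
    """Maximal intervals during which an active arm has no instrument in view."""
    n = len(states)
    out = 0
    for arm in ("left", "right"):
        ids = [i for i, a in arm_of.items() if a == arm]
        if not ids:
            continue
        in_view = np.zeros(n, dtype=bool)
        present = np.zeros(n, dtype=bool)  # arm appears in the video at all
        for i in ids:
            df = trajectories.get(i)
            if df is None:
                continue
            vis = df.loc[df["visible"].astype(bool), "frame"].to_numpy(int)
            in_view[vis] = True
            present[df["frame"].to_numpy(int)] = True
        active = np.array([arm in s.active_arms for s in states])
        missing = active & present.any() & ~in_view
        out += len(_maximal_true_runs(missing))
    return out


def count_collisions(boxes_by_identity: Dict[int, Dict[int, Tuple]], n_frames: int) -> int:
    """Onset events where two distinct instruments' boxes/masks overlap.

    ``boxes_by_identity[identity][frame]`` is either an (x, y, w, h) box or
    a ``(box, local_mask)`` pair; a collision is counted when a pair goes
    from non-overlapping (or absent) to overlapping.
    """
    from .detection import box_iou

    ids = sorted(boxes_by_identity)
    count = 0
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            prev = False
            for f in range(n_frames):
                ra = boxes_by_identity[a].get(f)
                rb = boxes_by_identity[b].get(f)
                cur = False
                if ra is not None and rb is not None:
                    cur = _records_overlap(ra, rb)
                if cur and not prev:
                    count += 1
                prev = cur
    return count


def _records_overlap(ra, rb) -> bool:
    box_a, mask_a = (ra if isinstance(ra, tuple) and len(ra) == 2 and not np.isscalar(ra[0]) else (ra, None))
    box_b, mask_b = (rb if isinstance(rb, tuple) and len(rb) == 2 and not np.isscalar(rb[0]) else (rb, None))
    xa, ya, wa, ha = box_a
    xb, yb, wb, hb = box_b
    ix0, iy0 = max(xa, xb), max(ya, yb)
    ix1, iy1 = min(xa + wa, xb + wb), min(ya + ha, yb + hb)
    if ix0 >= ix1 or iy0 >= iy1:
        return False
    if mask_a is None or mask_b is None:
        return True
    sub_a = mask_a[iy0 - ya : iy1 - ya, ix0 - xa : ix1 - xa]
    sub_b = mask_b[iy0 - yb : iy1 - yb, ix0 - xb : ix1 - xb]
    return bool((sub_a & sub_b).any())


def _speed_series(df: pd.DataFrame, fps: float, smooth_window: int = 5):
    """Smoothed speed (mm/s) per frame interval; invalid steps are zero."""
    d = df.sort_values("frame")
    fr = d["frame"].to_numpy()
    xy = d[["x_mm", "y_mm"]].to_numpy(float)
    ok = d["valid_motion"].to_numpy(bool)
    if len(fr) < 2:
        return np.zeros(0)
    consec = np.diff(fr) == 1
    step = np.hypot(*(xy[1:] - xy[:-1]).T)
    speed = np.where(consec & ok[:-1] & ok[1:], step * fps, 0.0)
    if smooth_window > 1 and len(speed):
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def movement_episodes(
    df: pd.DataFrame,
    fps: float,
    speed_threshold: float = 2.0,
    min_duration: float = 0.2,
    smooth_window: int = 5,
) -> List[Tuple[int, int]]:
    """Maximal runs of smoothed speed above threshold lasting >= min_duration.

    Returned as (start, stop) indices into the frame-interval series.
    """
    speed = _speed_series(df, fps, smooth_window)
    min_len = max(int(np.ceil(min_duration * fps)), 1)
    return [r for r in _maximal_true_runs(speed > speed_threshold) if r[1] - r[0] >= min_len]


def count_movements(
    trajectories: TrajectorySet,
    fps: float,
    speed_threshold: float = 2.0,
    min_duration: float = 0.2,
) -> int:
    if fps <= 0:
        raise ValueError("fps must be positive")
    return sum(
        len(movement_episodes(df, fps, speed_threshold, min_duration))
        for df in trajectories.values()
    )


def economic_factor(
    trajectories: TrajectorySet,
    fps: float,
    speed_threshold: float = 2.0,
    min_duration: float = 0.2,
) -> float:
    """Mean straightness (net displacement / path length) over movement
    episodes; NaN when there are no episodes."""
    ratios = []
    for df in trajectories.values():
        d = df.sort_values("frame")
        xy = d[["x_mm", "y_mm"]].to_numpy(float)
        for start, stop in movement_episodes(d, fps, speed_threshold, min_duration):
            seg = xy[start : stop + 1]
            path = float(np.hypot(*np.diff(seg, axis=0).T).sum())
            if path <= 0:
                continue
            net = float(np.hypot(*(seg[-1] - seg[0])))
            ratios.append(net / path)
    return float(np.mean(ratios)) if ratios else float("nan")


def count_instrument_changes(active_sets: Sequence[frozenset]) -> int:
    """Membership changes of the active-instrument set (arm swaps)."""
    changes = 0
    for prev, cur in zip(active_sets[:-1], active_sets[1:]):
        if prev != cur:
            changes += 1
    return changes


def laparoscopy_usage(states: Sequence[IndicatorState], fps: float) -> Tuple[int, float]:
    """(count, total duration s) of maximal camera-motion intervals."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    flags = np.array([s.camera_moving for s in states], dtype=bool)
    runs = _maximal_true_runs(flags)
    dur = sum(b - a for a, b in runs) / fps
    return len(runs), float(dur)


def compute_metrics(
    trajectories: TrajectorySet,
    states: Sequence[IndicatorState],
    fps: float,
    arm_of: Dict[int, str],
    active_sets: Optional[Sequence[frozenset]] = None,
    boxes_by_identity: Optional[Dict[int, Dict[int, Tuple]]] = None,
    speed_threshold: float = 2.0,
    min_duration: float = 0.2,
) -> MetricVector:
    """All nine metrics for one video."""
    n_frames = len(states)
    ttc = n_frames / fps
    if active_sets is None:
        active_sets = [
            frozenset(i for i, a in arm_of.items() if a in s.active_arms)
            for s in states
        ]
    eom = economy_of_motion(trajectories)
    mt = _moving_time(trajectories, fps, speed_threshold)
    speed = eom / mt if mt > 0 else 0.0
    lap_n, lap_s = laparoscopy_usage(states, fps)
    collisions = (
        count_collisions(boxes_by_identity, n_frames) if boxes_by_identity else 0
    )
    return MetricVector(
        time_to_completion=ttc,
        instruments_out_of_view=count_out_of_view(trajectories, states, arm_of),
        instrument_collisions=collisions,
        economy_of_motion=eom,
        average_speed=speed,
        number_of_movements=count_movements(
            trajectories, fps, speed_threshold, min_duration
        ),
        economic_factor=economic_factor(
            trajectories, fps, speed_threshold, min_duration
        ),
        instrument_changes=count_instrument_changes(list(active_sets)),
        laparoscopy_duration=lap_s,
        laparoscopy_count=lap_n,
    )


# ---------------------------------------------------------------------------
# normalization: per-time rates, then per-metric z-scores


class MetricNormalizer:
    """Two-stage normalizer, sklearn-style (fit/transform).

    Stage 1 divides every duration-dependent metric by its video's
    completion time (counts become rates, path length becomes mm/s);
    completion time itself and the intensive metrics (average speed,
    economic factor) pass through.  Stage 2 standardizes each column to
    zero mean and unit variance across the fitted cohort; the stored
    transform is re-applicable to new subjects.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    @staticmethod
    def _stage1(table: pd.DataFrame) -> pd.DataFrame:
        out = table[METRIC_NAMES].copy().astype(float)
        t = out["time_to_completion"].to_numpy()
        for col in _DURATION_DEPENDENT:
            out[col] = out[col] / t
        return out

    def fit(self, table: pd.DataFrame) -> "MetricNormalizer":
        if len(table) < 2:
            raise ValueError("need a cohort of at least 2 videos to normalize")
        s1 = self._stage1(table).fillna(0.0)
        self.mean_ = s1.mean(axis=0)
        sd = s1.std(axis=0, ddof=0)
        zero = sd <= (self.mean_.abs() + 1.0) * 1e-12  # constant up to fp noise
        if zero.any():
            warnings.warn(
                f"zero-variance metric columns standardized to zeros: {list(sd.index[zero])}"
            )
        self.scale_ = sd.where(~zero, 1.0)
        self.zero_variance_ = list(sd.index[zero])
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise ValueError("normalizer is not fitted")
        s1 = self._stage1(table).fillna(0.0)
        z = (s1 - self.mean_) / self.scale_
        for col in getattr(self, "zero_variance_", []):
            z[col] = 0.0
        return z

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def get_params(self, deep: bool = True):
        return {}

    def set_params(self, **params):
        return self

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "mean": self.mean_.to_dict(),
                "scale": self.scale_.to_dict(),
                "zero_variance": getattr(self, "zero_variance_", []),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricNormalizer":
        import json

        doc = json.loads(text)
        obj = cls()
        obj.mean_ = pd.Series(doc["mean"])[METRIC_NAMES]
        obj.scale_ = pd.Series(doc["scale"])[METRIC_NAMES]
        obj.zero_variance_ = doc.get("zero_variance", [])
        return obj


def normalize_metrics(table: pd.DataFrame):
    """Fit-and-apply convenience wrapper; returns (normalized, normalizer)."""
    norm = MetricNormalizer()
    return norm.fit_transform(table), norm
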