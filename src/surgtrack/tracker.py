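"""SORT-style tracking-by-detection with a three-instrument cap.

A constant-velocity Kalman filter predicts each track's bounding box in
the measurement space ``(cx, cy, aspect, h)``; detections are associated
by a matching cascade (most recently updated tracks first) that combines
an appearance cosine distance with a Mahalanobis-gated motion distance,
followed by an IOU-only pass for fresh tracks, with the Hungarian
algorithm solving each assignment.  Tracks confirm after three
consecutive hits; at most three tracks may be confirmed at once — the
endoscopic view of a surgical robot shows at most three instruments — and
a confirmation blocked by the cap is granted as soon as a slot frees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection, box_iou

CHI2_GATE_4DOF = 9.4877  # chi-square 0.95 quantile, 4 dof
CHI2_GATE_2DOF = 5.9915  # chi-square 0.95 quantile, 2 dof (position gate)
GATED_COST = 1e5

iou = box_iou  # spatial affinity used for association


# ---------------------------------------------------------------------------
# Kalman filter (deep-SORT convention: noise scaled to box height)

_STD_WEIGHT_POS = 1.0 / 20
_STD_WEIGHT_VEL = 1.0 / 160


@dataclass
class KalmanState:
    mean: np.ndarray  # (cx, cy, aspect, h, v_cx, v_cy, v_aspect, v_h)
    covariance: np.ndarray  # 8x8 PSD

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValueError("state is 8-dimensional")


def box_to_measurement(box) -> np.ndarray:
    x, y, w, h = box
    return np.array([x + w / 2.0, y + h / 2.0, w / max(h, 1e-9), float(h)])


def measurement_to_box(z) -> Tuple[float, float, float, float]:
    cx, cy, a, h = z
    w = a * h
    return (cx - w / 2.0, cy - h / 2.0, w, h)


def _char_size(mean4) -> float:
    # sqrt(w*h): stable for elongated boxes whose h collapses when the
    # instrument lies horizontally (h alone is the pedestrian convention)
    a, h = max(mean4[2], 1e-3), max(mean4[3], 1e-3)
    return float(h * np.sqrt(a))


def kalman_initiate(measurement) -> KalmanState:
    z = np.asarray(measurement, dtype=float)
    mean = np.concatenate([z, np.zeros(4)])
    size = _char_size(z)
    std = np.array(
        [
            2 * _STD_WEIGHT_POS * size,
            2 * _STD_WEIGHT_POS * size,
            2e-1,
            2 * _STD_WEIGHT_POS * size,
            10 * _STD_WEIGHT_VEL * size,
            10 * _STD_WEIGHT_VEL * size,
            5e-2,
            10 * _STD_WEIGHT_VEL * size,
        ]
    )
    return KalmanState(mean, np.diag(std**2))


def kalman_predict(state: KalmanState, dt: int = 1) -> KalmanState:
    """Advance by the constant-velocity model; covariance grows."""
    if dt < 1:
        raise ValueError("dt must be >= 1")
    F = np.eye(8)
    for k in range(4):
        F[k, k + 4] = dt
    size = _char_size(state.mean)
    std = np.array(
        [
            _STD_WEIGHT_POS * size,
            _STD_WEIGHT_POS * size,
            2e-2,
            _STD_WEIGHT_POS * size,
            _STD_WEIGHT_VEL * size,
            _STD_WEIGHT_VEL * size,
            5e-3,
            _STD_WEIGHT_VEL * size,
        ]
    )
    Q = np.diag(std**2) * dt
    mean = F @ state.mean
    mean[2] = max(mean[2], 1e-3)  # extrapolation must keep a valid box
    mean[3] = max(mean[3], 1.0)
    cov = F @ state.covariance @ F.T + Q
    return KalmanState(mean, cov)


def _innovation_cov(state: KalmanState) -> np.ndarray:
    size = _char_size(state.mean)
    std = np.array(
        [_STD_WEIGHT_POS * size, _STD_WEIGHT_POS * size, 3e-1, _STD_WEIGHT_POS * size]
    )
    R = np.diag(std**2)
    H = np.eye(4, 8)
    return H @ state.covariance @ H.T + R


def kalman_update(state: KalmanState, measurement) -> KalmanState:
    """Standard linear Kalman correction in (cx, cy, aspect, h)."""
    z = np.asarray(measurement, dtype=float)
    if z[3] <= 0:
        raise ValueError("measured height must be positive")
    H = np.eye(4, 8)
    S = _innovation_cov(state)
    K = state.covariance @ H.T @ np.linalg.inv(S)
    innov = z - H @ state.mean
    mean = state.mean + K @ innov
    cov = (np.eye(8) - K @ H) @ state.covariance
    cov = (cov + cov.T) / 2.0
    return KalmanState(mean, cov)


def mahalanobis_sq(state: KalmanState, measurement) -> float:
    """Full 4-D squared Mahalanobis distance in measurement space."""
    z = np.asarray(measurement, dtype=float)
    S = _innovation_cov(state)
    d = z - state.mean[:4]
    return float(d @ np.linalg.solve(S, d))


def gate_distance_sq(state: KalmanState, measurement) -> float:
    """Position-only (cx, cy) squared Mahalanobis distance for gating.

    The box shape of a rigid elongated instrument pivoting about its entry
    port changes abruptly as the shaft passes through horizontal, so the
    aspect/height components carry no usable gating information; the
    predicted centre does.
    """
    z = np.asarray(measurement, dtype=float)[:2]
    S = _innovation_cov(state)[:2, :2]
    d = z - state.mean[:2]
    return float(d @ np.linalg.solve(S, d))


# ---------------------------------------------------------------------------
# tracks


TENTATIVE, CONFIRMED, LOST, DELETED = "tentative", "confirmed", "lost", "deleted"


@dataclass
class Track:
    track_id: int
    state: KalmanState
    status: str = TENTATIVE
    identity_label: Optional[int] = None
    hits: int = 0
    time_since_update: int = 0
    appearance_buffer: List[np.ndarray] = field(default_factory=list)
    history: List[Tuple[int, Detection]] = field(default_factory=list)
    appearance_buffer_size: int = 30

    @property
    def box(self):
        return measurement_to_box(self.state.mean[:4])

    def add_appearance(self, descriptor: Optional[np.ndarray]):
        if descriptor is not None:
            self.appearance_buffer.append(descriptor)
            if len(self.appearance_buffer) > self.appearance_buffer_size:
                self.appearance_buffer.pop(0)

    def appearance_distance(self, descriptor: Optional[np.ndarray]) -> float:
        if descriptor is None or not self.appearance_buffer:
            return 0.0
        sims = [float(d @ descriptor) for d in self.appearance_buffer]
        return 1.0 - max(sims)


# ---------------------------------------------------------------------------
# association


@dataclass
class AssociationResult:
    matches: List[Tuple[int, int]]  # (track index, detection index)
    unmatched_tracks: List[int]
    unmatched_detections: List[int]
    cost_matrix: np.ndarray


def associate(cost_matrix: np.ndarray, gate: float = GATED_COST) -> AssociationResult:
    """Minimum-total-cost assignment; matches at/above ``gate`` are dropped.

    Indices in the result refer to the rows (tracks) and columns
    (detections) of the cost matrix.
    """
    C = np.atleast_2d(np.asarray(cost_matrix, dtype=float))
    if C.size == 0:
        n_r = C.shape[0] if C.ndim == 2 else 0
        n_c = C.shape[1] if C.ndim == 2 else 0
        return AssociationResult([], list(range(n_r)), list(range(n_c)), C)
    rows, cols = linear_sum_assignment(C)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if C[r, c] < gate]
    mr = {r for r, _ in matches}
    mc = {c for _, c in matches}
    return AssociationResult(
        matches,
        [r for r in range(C.shape[0]) if r not in mr],
        [c for c in range(C.shape[1]) if c not in mc],
        C,
    )


@dataclass(frozen=True)
class TrackerConfig:
    max_confirmed: int = 3  # at most three instruments in view
    n_init: int = 3  # consecutive hits to confirm
    max_age: int = 30  # frames unmatched before a track is dropped
    appearance_lambda: float = 0.02  # motion weight in the combined cost
    iou_gate: float = 0.3  # IOU pass threshold
    appearance_gate: float = 0.4  # max cosine distance in the cascade


class Tracker:
    """Frame-by-frame multi-instrument tracker."""

    def __init__(self, config: TrackerConfig = TrackerConfig()):
        self.config = config
        self.tracks: List[Track] = []
        self._next_id = 1
        self.frame_index = -1

    @property
    def confirmed_tracks(self) -> List[Track]:
        return [t for t in self.tracks if t.status == CONFIRMED]

    def step(
        self,
        detections: Sequence[Detection],
        descriptors: Optional[Sequence[Optional[np.ndarray]]] = None,
    ) -> List[Track]:
        """Advance one frame with NMS-filtered detections.

        ``descriptors`` optionally carries one appearance vector per
        detection (unit L2 norm); without them association is motion/IOU
        only.  Returns the live track list.
        """
        self.frame_index += 1
        if descriptors is None:
            descriptors = [None] * len(detections)
        for t in self.tracks:
            t.state = kalman_predict(t.state)
            t.time_since_update += 1

        live = [t for t in self.tracks if t.status in (TENTATIVE, CONFIRMED, LOST)]
        confirmed = [t for t in live if t.status in (CONFIRMED, LOST)]
        fresh = [t for t in live if t.status == TENTATIVE]

        matches, um_tracks, um_dets = self._matching_cascade(
            confirmed, detections, descriptors
        )
        # IOU-only pass: first confirmed leftovers of age 1 (they keep
        # priority over fresh hypotheses), then tentative tracks
        recent = [t for t in um_tracks if t.time_since_update == 1]
        um_tracks = [t for t in um_tracks if t.time_since_update != 1]
        for iou_tracks in (recent, fresh):
            if iou_tracks and um_dets:
                C = np.full((len(iou_tracks), len(um_dets)), GATED_COST)
                for r, t in enumerate(iou_tracks):
                    for c, di in enumerate(um_dets):
                        ov = iou(t.box, detections[di].box)
                        if ov >= self.config.iou_gate:
                            C[r, c] = 1.0 - ov
                res = associate(C)
                matches += [(iou_tracks[r], um_dets[c]) for r, c in res.matches]
                um_tracks += [iou_tracks[r] for r in res.unmatched_tracks]
                um_dets = [um_dets[c] for c in res.unmatched_detections]
            else:
                um_tracks += iou_tracks

        for t, di in matches:
            d = detections[di]
            t.state = kalman_update(t.state, box_to_measurement(d.box))
            t.hits += 1
            t.time_since_update = 0
            t.add_appearance(descriptors[di])
            t.history.append((self.frame_index, d))
            if t.status == LOST:
                t.status = CONFIRMED  # re-association restores the track
            elif t.status == TENTATIVE and t.hits >= self.config.n_init:
                self._try_confirm(t)

        for t in um_tracks:
            if t.status == TENTATIVE:
                t.hits = 0
                if t.time_since_update > 1:
                    t.status = DELETED
            elif t.status == CONFIRMED and t.time_since_update > self.config.max_age:
                t.status = LOST
            elif t.status == LOST and t.time_since_update > 2 * self.config.max_age:
                t.status = DELETED

        for di in um_dets:
            d = detections[di]
            t = Track(self._next_id, kalman_initiate(box_to_measurement(d.box)))
            self._next_id += 1
            t.hits = 1
            t.history.append((self.frame_index, d))
            t.add_appearance(descriptors[di])
            self.tracks.append(t)

        # a blocked confirmation goes through as soon as a slot frees
        for t in self.tracks:
            if (
                t.status == TENTATIVE
                and t.hits >= self.config.n_init
                and t.time_since_update == 0
            ):
                self._try_confirm(t)

        self.tracks = [t for t in self.tracks if t.status != DELETED]
        return list(self.tracks)

    def _try_confirm(self, track: Track):
        if len(self.confirmed_tracks) < self.config.max_confirmed:
            track.status = CONFIRMED

    def _matching_cascade(self, tracks, detections, descriptors):
        matches: List[Tuple[Track, int]] = []
        um_dets = list(range(len(detections)))
        um_tracks: List[Track] = []
        lam = self.config.appearance_lambda
        for age in range(1, self.config.max_age + 1):
            bucket = [t for t in tracks if t.time_since_update == age]
            if not bucket:
                continue
            if not um_dets:
                um_tracks += bucket
                continue
            C = np.full((len(bucket), len(um_dets)), GATED_COST)
            for r, t in enumerate(bucket):
                for c, di in enumerate(um_dets):
                    z = box_to_measurement(detections[di].box)
                    m2 = gate_distance_sq(t.state, z)
                    if m2 > CHI2_GATE_2DOF:
                        continue
                    app = t.appearance_distance(descriptors[di])
                    if descriptors[di] is not None and app > self.config.appearance_gate:
                        continue
                    C[r, c] = lam * (m2 / CHI2_GATE_2DOF) + (1 - lam) * app
            res = associate(C)
            matches += [(bucket[r], um_dets[c]) for r, c in res.matches]
            um_tracks += [bucket[r] for r in res.unmatched_tracks]
            um_dets = [um_dets[c] for c in res.unmatched_detections]
        um_tracks += [t for t in tracks if t.time_since_update > self.config.max_age]
        return matches, um_tracks, um_dets


def tracks_to_jsonl(tracks_per_frame) -> str:
    """Per-frame dump: (frame, track_id, identity_label, box, status)."""
    import json

    lines = []
    for frame, tracks in enumerate(tracks_per_frame):
        for t in tracks:
            lines.append(
                json.dumps(
                    {
                        "frame": frame,
                        "track_id": t.track_id,
                        "identity_label": t.identity_label,
                        "box": [float(v) for v in t.box],
                        "status": t.status,
                    }
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")
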