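"""End-to-end pipeline: detect -> NMS -> track -> ReID -> indicators ->
tips -> gating -> metrics, plus evaluation against simulator ground truth.

The pipeline consumes a frame sequence and a detection provider (the
ground-truth-backed oracle with a noise model, or the classical colour
segmenter), maintains identity-labelled tracks, recovers calibrated tip
trajectories gated by the console indicators, and reduces them to the
nine motion metrics.  Confirmed tracks emit their trajectories
retrospectively over their full history, including the tentative phase,
so a stably tracked instrument has no warm-up gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import indicators as ind
from . import reid as reid_mod
from .detection import (
    Detection,
    NoiseConfig,
    ZERO_NOISE,
    box_iou,
    masks_overlap,
    nms,
    oracle_detect,
)
from .evaluation import EvalReport, count_identity_switches, evaluate_tracking
from .metrics import MetricVector, compute_metrics
from .scene import GroundTruth, Scene
from .tips import Calibration, calibrate_from_masks, detect_tip
from .tracker import CONFIRMED, Track, Tracker, TrackerConfig


@dataclass
class PipelineConfig:
    detector: str = "oracle"  # "oracle" | "color"
    noise: NoiseConfig = ZERO_NOISE
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    nms_iou: float = 0.5
    bovw_k: int = 32
    reentry_threshold: float = 0.25  # max gallery distance to reuse an identity
    gallery_capacity: int = 50
    calibration_override: Optional[Calibration] = None
    speed_threshold: float = 2.0  # mm/s, movement-episode detection
    min_move_duration: float = 0.2  # s
    seed: int = 0


@dataclass
class PipelineResult:
    rows: pd.DataFrame  # frame, track_id, identity, x_px, y_px, confidence
    trajectories: Dict[int, pd.DataFrame]  # gated + calibrated, per identity
    states: List[ind.IndicatorState]
    metrics: MetricVector
    calibration: Calibration
    arm_of: Dict[int, str]
    masks_by_identity: Dict[int, Dict[int, Tuple]]
    confidences: Dict[int, Dict[int, float]]


class _IdentityManager:
    """Gallery bookkeeping + cascade invocation for the tracker's events."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.gallery = reid_mod.Gallery(cfg.gallery_capacity)
        self._next_identity = 0
        self._frame_buffer: List[Tuple[np.ndarray, Dict[int, Tuple]]] = []

    def push_frame(self, frame: np.ndarray, boxes_by_track: Dict[int, Tuple]):
        self._frame_buffer.append((frame, boxes_by_track))
        if len(self._frame_buffer) > reid_mod.BOVW_WINDOW + 1:
            self._frame_buffer.pop(0)

    def _window_patches(self, identity_of_track: Dict[int, int]):
        out: Dict[int, List[np.ndarray]] = {}
        for frame, boxes in self._frame_buffer[:-1]:  # previous frames only
            for tid, box in boxes.items():
                ident = identity_of_track.get(tid)
                if ident is None:
                    continue
                p = reid_mod.patch_features(frame, box)
                if len(p):
                    out.setdefault(ident, []).append(p)
        return {i: np.vstack(ps) for i, ps in out.items() if ps}

    def decide(
        self,
        track: Track,
        descriptor: np.ndarray,
        frame: np.ndarray,
        box,
        live: Dict[int, float],
        identity_of_track: Dict[int, int],
    ) -> Optional[int]:
        """Identity for a track event; None means keep the incumbent."""
        if len(self.gallery) == 0:
            return self._new_identity()
        ranking = reid_mod.gallery_rank(descriptor, self.gallery)
        best_ident, best_d = ranking[0]
        if track.identity_label is None:
            # newly confirmed track: re-entry vs genuinely new instrument
            if best_d > self.cfg.reentry_threshold and len(self.gallery) < reid_mod.MAX_IDENTITIES:
                return self._new_identity()
        elif best_ident == track.identity_label:
            return track.identity_label
        event = reid_mod.ReIDEvent(
            incumbent=track.identity_label,
            query=descriptor,
            query_patches=reid_mod.patch_features(frame, box),
            window_patches=self._window_patches(identity_of_track),
        )
        decision = reid_mod.cascade_reid(
            event,
            self.gallery,
            k=self.cfg.bovw_k,
            seed=self.cfg.seed,
            live_identities=live,
        )
        return decision.identity

    def _new_identity(self) -> int:
        ident = self._next_identity
        self._next_identity += 1
        return ident

    def add_exemplar(self, identity: int, descriptor: np.ndarray, frame_index: int):
        self.gallery.add(identity, descriptor, frame_index)


def run_pipeline(
    scene: Scene,
    config: PipelineConfig = PipelineConfig(),
    detections_per_frame: Optional[Sequence[Sequence[Detection]]] = None,
) -> PipelineResult:
    """Run the full pipeline on a simulated scene.

    ``detections_per_frame`` overrides the detection stage (external
    detections in the documented JSON-lines format can be passed after
    :func:`surgtrack.detection.detections_from_jsonl`).
    """
    gt = scene.ground_truth
    c = scene.config
    frames = scene.frames
    tracker = Tracker(config.tracker)
    idman = _IdentityManager(config)
    identity_of_track: Dict[int, int] = {}
    rows: List[Dict] = []
    masks_by_identity: Dict[int, Dict[int, Tuple]] = {}
    confidences: Dict[int, Dict[int, float]] = {}
    states: List[ind.IndicatorState] = []
    first_masks: List[np.ndarray] = []

    for f in range(c.n_frames):
        frame = frames[f]
        st = ind.indicator_states([frame], scene.templates)[0]
        states.append(ind.IndicatorState(f, st.camera_moving, st.active_arms))
        if detections_per_frame is not None:
            dets = list(detections_per_frame[f])
        elif config.detector == "oracle":
            dets = oracle_detect(gt, f, config.noise)
        elif config.detector == "color":
            from .detection import color_segment

            dets = color_segment(frame, frame_index=f)
        else:
            raise ValueError(f"unknown detector {config.detector!r}")
        dets = nms(dets, config.nms_iou)
        descriptors = []
        for d in dets:
            try:
                descriptors.append(reid_mod.extract_descriptor(frame, d.box, d.mask))
            except ValueError:
                descriptors.append(None)
        tracker.step(dets, descriptors)

        # identity decisions for freshly updated confirmed tracks
        live: Dict[int, float] = {}
        for t in tracker.confirmed_tracks:
            if t.identity_label is not None:
                live[t.identity_label] = 0.0
        updated = [
            t
            for t in tracker.confirmed_tracks
            if t.time_since_update == 0 and t.history
        ]
        det_of_track = {t.track_id: t.history[-1][1] for t in updated}
        for t in updated:
            d = det_of_track[t.track_id]
            desc = None
            for di, dd in enumerate(dets):
                if dd is d:
                    desc = descriptors[di]
            if desc is None:
                continue
            others = {
                ident: 0.0
                for ident, _ in (
                    (identity_of_track.get(u.track_id), None)
                    for u in tracker.confirmed_tracks
                    if u.track_id != t.track_id
                )
                if ident is not None
            }
            decided = idman.decide(
                t, desc, frame, d.box, others, identity_of_track
            )
            if decided is not None and decided != t.identity_label:
                t.identity_label = decided
                identity_of_track[t.track_id] = decided
            elif t.identity_label is not None:
                identity_of_track[t.track_id] = t.identity_label
            # gallery exemplars only from unoccluded, high-confidence hits
            if (
                t.identity_label is not None
                and d.confidence >= 0.8
                and all(not masks_overlap(d, o) for o in dets if o is not d)
            ):
                idman.add_exemplar(t.identity_label, desc, f)

        idman.push_frame(
            frame,
            {
                t.track_id: t.history[-1][1].box
                for t in tracker.confirmed_tracks
                if t.time_since_update == 0 and t.history
            },
        )

        # emit rows: confirmed tracks emit their full history retroactively
        for t in tracker.confirmed_tracks:
            if t.identity_label is None:
                continue
            todo = [
                (fi, d)
                for fi, d in t.history
                if not _already_emitted(rows, t.track_id, fi)
            ]
            for fi, d in todo:
                full = d.full_mask(c.width_px, c.height_px)
                tx, ty = detect_tip(full, (c.height_px, c.width_px))
                rows.append(
                    {
                        "frame": fi,
                        "track_id": t.track_id,
                        "identity": t.identity_label,
                        "x_px": tx,
                        "y_px": ty,
                        "confidence": d.confidence,
                    }
                )
                masks_by_identity.setdefault(t.identity_label, {})[fi] = (
                    d.box,
                    d.mask,
                )
                confidences.setdefault(t.identity_label, {})[fi] = d.confidence
                if len(first_masks) < 50:
                    first_masks.append(full)

    rows_df = pd.DataFrame(
        rows,
        columns=["frame", "track_id", "identity", "x_px", "y_px", "confidence"],
    ).sort_values(["frame", "identity"]).reset_index(drop=True)

    calibration = config.calibration_override
    if calibration is None:
        calibration = calibrate_from_masks(first_masks, c.shaft_width_mm)

    arm_of = _infer_arms(rows_df, masks_by_identity, c.width_px)
    trajectories = _build_trajectories(rows_df, calibration, states, arm_of)
    active_sets = [
        frozenset(i for i, a in arm_of.items() if a in s.active_arms) for s in states
    ]
    mv = compute_metrics(
        trajectories,
        states,
        c.fps,
        arm_of,
        active_sets=active_sets,
        boxes_by_identity=masks_by_identity,
        speed_threshold=config.speed_threshold,
        min_duration=config.min_move_duration,
    )
    return PipelineResult(
        rows_df,
        trajectories,
        states,
        mv,
        calibration,
        arm_of,
        masks_by_identity,
        confidences,
    )


def _already_emitted(rows: List[Dict], track_id: int, frame: int) -> bool:
    # only the tail of a track's history can be new; scan backwards
    for r in reversed(rows):
        if r["track_id"] == track_id:
            return r["frame"] >= frame
    return False


def _infer_arms(rows_df, masks_by_identity, width_px) -> Dict[int, str]:
    arm_of = {}
    for ident, per_frame in masks_by_identity.items():
        f0 = min(per_frame)
        box = per_frame[f0][0]
        x, y, w, h = box
        if x <= 0:
            arm_of[ident] = "left"
        elif x + w >= width_px:
            arm_of[ident] = "right"
        else:
            arm_of[ident] = "left" if x + w / 2 < width_px / 2 else "right"
    return arm_of


def _build_trajectories(rows_df, calibration, states, arm_of):
    out: Dict[int, pd.DataFrame] = {}
    for ident, grp in rows_df.groupby("identity"):
        df = grp[["frame", "x_px", "y_px"]].copy()
        df["visible"] = True
        df["x_mm"] = df["x_px"] * calibration.mm_per_px
        df["y_mm"] = df["y_px"] * calibration.mm_per_px
        out[int(ident)] = ind.gate_trajectory(df, states, arm=arm_of.get(ident))
    return out


# ---------------------------------------------------------------------------
# ground-truth side and evaluation


def gt_trajectories(gt: GroundTruth, mm_per_px: Optional[float] = None):
    """Gated, calibrated tip trajectories straight from ground truth."""
    if mm_per_px is None:
        mm_per_px = gt.mm_per_px
    states = [
        ind.IndicatorState(f, bool(gt.camera_moving[f]), gt.active_arms(f))
        for f in range(gt.n_frames)
    ]
    out = {}
    for i in range(gt.config.n_instruments):
        fr, xy = gt.tip_trajectory(i)
        df = pd.DataFrame(
            {
                "frame": fr,
                "x_px": xy[:, 0],
                "y_px": xy[:, 1],
                "visible": True,
                "x_mm": xy[:, 0] * mm_per_px,
                "y_mm": xy[:, 1] * mm_per_px,
            }
        )
        out[i] = ind.gate_trajectory(df, states, arm=gt.arm_of[i])
    return out, states


def gt_metrics(gt: GroundTruth, speed_threshold=2.0, min_duration=0.2) -> MetricVector:
    """The nine metrics computed from ground truth alone."""
    trajs, states = gt_trajectories(gt)
    boxes = {}
    for f, inst in enumerate(gt.per_frame):
        for i, g in inst.items():
            if g.visible:
                boxes.setdefault(i, {})[f] = (g.box, g.mask)
    return compute_metrics(
        trajs,
        states,
        gt.config.fps,
        gt.arm_of,
        active_sets=gt.active,
        boxes_by_identity=boxes,
        speed_threshold=speed_threshold,
        min_duration=min_duration,
    )


def match_identities(result: PipelineResult, gt: GroundTruth) -> Dict[int, int]:
    """Map pipeline identity -> GT instrument by majority box overlap."""
    votes: Dict[Tuple[int, int], int] = {}
    for ident, per_frame in result.masks_by_identity.items():
        for f, (box, mask) in per_frame.items():
            best, best_iou = None, 0.3
            for i, g in gt.per_frame[f].items():
                if not g.visible:
                    continue
                ov = _pair_mask_iou(box, mask, g.box, g.mask)
                if ov > best_iou:
                    best, best_iou = i, ov
            if best is not None:
                votes[(ident, best)] = votes.get((ident, best), 0) + 1
    mapping: Dict[int, int] = {}
    used = set()
    for (ident, gt_i), n in sorted(votes.items(), key=lambda kv: -kv[1]):
        if ident not in mapping and gt_i not in used:
            mapping[ident] = gt_i
            used.add(gt_i)
    return mapping


def _pair_mask_iou(box_a, mask_a, box_b, mask_b) -> float:
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix0, iy0 = max(ax, bx), max(ay, by)
    ix1, iy1 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    inter = 0
    if ix0 < ix1 and iy0 < iy1:
        sa = mask_a[iy0 - ay : iy1 - ay, ix0 - ax : ix1 - ax]
        sb = mask_b[iy0 - by : iy1 - by, ix0 - bx : ix1 - bx]
        inter = int((sa & sb).sum())
    union = int(mask_a.sum()) + int(mask_b.sum()) - inter
    return inter / union if union > 0 else 0.0


def matched_identity_timeline(result: PipelineResult, gt: GroundTruth):
    """Per GT instrument, the pipeline identity matched at each frame.

    Matching is by best mask IOU: the hull boxes of crossing elongated
    instruments overlap heavily even when the instruments do not, so box
    IOU would produce spurious matches.
    """
    n = gt.n_frames
    timeline = {i: [None] * n for i in range(gt.config.n_instruments)}
    best_iou = {i: [0.0] * n for i in range(gt.config.n_instruments)}
    for ident, per_frame in result.masks_by_identity.items():
        for f, (box, mask) in per_frame.items():
            for i, g in gt.per_frame[f].items():
                if not g.visible:
                    continue
                ov = _pair_mask_iou(box, mask, g.box, g.mask)
                if ov > 0.5 and ov > best_iou[i][f]:
                    timeline[i][f] = ident
                    best_iou[i][f] = ov
    return timeline


def evaluate_against_gt(
    result: PipelineResult, gt: GroundTruth, rate_per_s: float = 2.0
) -> EvalReport:
    """Score pipeline trajectories against GT (shared GT calibration)."""
    mapping = match_identities(result, gt)
    mm = gt.mm_per_px
    gtrajs, _ = gt_trajectories(gt, mm)
    pred = {}
    confs = {}
    for ident, gt_i in mapping.items():
        df = result.trajectories[ident].copy()
        df["x_mm"] = df["x_px"] * mm
        df["y_mm"] = df["y_px"] * mm
        pred[gt_i] = df
        confs[gt_i] = result.confidences.get(ident, {})
    timeline = matched_identity_timeline(result, gt)
    return evaluate_tracking(
        pred,
        {i: t for i, t in gtrajs.items()},
        gt.config.fps,
        gt.n_frames,
        confidences=confs,
        matched_identity_per_frame=timeline,
        rate_per_s=rate_per_s,
    )
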