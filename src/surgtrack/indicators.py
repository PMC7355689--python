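"""Arm-indicator recognition and trajectory gating.

Robotic consoles overlay small fixed-position glyphs on the endoscopic
view: one per instrument arm while that arm is active, and a camera-arm
glyph while the surgeon is driving the laparoscope.  Because the glyph
shape and position are fixed per robot model, they are recognized by
normalized cross-correlation template matching inside a small anchor
region.  The resulting per-frame flags gate the tip trajectories: frames
with camera motion contribute no instrument displacement (screen motion is
not hand motion), and instruments whose arm is not active contribute no
displacement either.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template as _ncc

KIND_LEFT = "instrument_arm_left"
KIND_RIGHT = "instrument_arm_right"
KIND_CAMERA = "camera_arm"
KINDS = (KIND_LEFT, KIND_RIGHT, KIND_CAMERA)


@dataclass(frozen=True)
class IndicatorTemplate:
    """A stored overlay glyph with its fixed search region.

    ``anchor`` is the half-open box (x, y, w, h) in view coordinates that
    the template is searched in; it must contain the template.
    """

    image: np.ndarray  # uint8 RGB or grayscale
    anchor: tuple  # (x, y, w, h)
    kind: str
    threshold: float = 0.8

    def __post_init__(self):
        th, tw = self.image.shape[:2]
        x, y, w, h = self.anchor
        if tw > w or th > h:
            raise ValueError("template larger than its anchor region")
        if self.kind not in KINDS:
            raise ValueError(f"unknown indicator kind {self.kind!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class IndicatorState:
    """Per-frame console state recovered from the overlays."""

    frame_index: int
    camera_moving: bool
    active_arms: frozenset

    def __post_init__(self):
        if len(self.active_arms) > 2:
            raise ValueError("at most two instrument arms can be active")


def _as_gray(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=2)
    return a


def match_template(frame: np.ndarray, template: IndicatorTemplate):
    """Search the template inside its anchor region.

    Returns ``(score, present)`` where ``score`` is the maximum normalized
    cross-correlation clipped to [0, 1] (anti-correlation is as good as no
    match for overlay detection) and ``present`` is ``score >= threshold``.
    """
    x, y, w, h = template.anchor
    H, W = frame.shape[:2]
    if not (0 <= x and 0 <= y and x + w <= W and y + h <= H):
        raise ValueError("anchor region outside frame")
    region = _as_gray(frame[y : y + h, x : x + w])
    tmpl = _as_gray(template.image)
    if tmpl.shape[0] > region.shape[0] or tmpl.shape[1] > region.shape[1]:
        raise ValueError("template does not fit the anchor region")
    if tmpl.std() == 0 or region.std() == 0:
        return 0.0, False
    resp = _ncc(region, tmpl)
    score = float(np.nan_to_num(resp, nan=0.0).max())
    score = min(max(score, 0.0), 1.0)
    return score, score >= template.threshold


def indicator_states(
    frames: Iterable[np.ndarray], templates: Dict[str, IndicatorTemplate]
) -> List[IndicatorState]:
    """Classify every frame's console state by template matching."""
    missing = [k for k in KINDS if k not in templates]
    if missing:
        raise ValueError(f"missing indicator templates: {missing}")
    out = []
    for i, frame in enumerate(frames):
        arms = set()
        _, left = match_template(frame, templates[KIND_LEFT])
        _, right = match_template(frame, templates[KIND_RIGHT])
        if left:
            arms.add("left")
        if right:
            arms.add("right")
        _, cam = match_template(frame, templates[KIND_CAMERA])
        out.append(IndicatorState(i, cam, frozenset(arms)))
    return out


def gate_trajectory(
    trajectory: pd.DataFrame,
    states: Sequence[IndicatorState],
    arm: str | None = None,
) -> pd.DataFrame:
    """Attach validity flags to a tip trajectory.

    ``trajectory`` needs columns ``frame`` plus position columns; a row's
    displacement toward the next row counts only when ``valid_motion`` is
    set on both.  Positions are never altered.  ``arm`` names the console
    arm this instrument is mounted on; ``None`` means always active.
    """
    frames = trajectory["frame"].to_numpy()
    n = len(states)
    if len(frames) and (frames.min() < states[0].frame_index or frames.max() > states[-1].frame_index):
        raise ValueError("trajectory frames outside the indicator state range")
    by_frame = {s.frame_index: s for s in states}
    cam = np.array([by_frame[f].camera_moving for f in frames], dtype=bool)
    if arm is None:
        active = np.ones(len(frames), dtype=bool)
    else:
        active = np.array([arm in by_frame[f].active_arms for f in frames], dtype=bool)
    out = trajectory.copy()
    out["camera_moving"] = cam
    out["active"] = active
    visible = out["visible"].to_numpy(bool) if "visible" in out else np.ones(len(out), bool)
    out["valid_motion"] = active & ~cam & visible
    return out


# ---------------------------------------------------------------------------
# default template set (used by the scene simulator and the tests)

_TSIZE = 16


def _glyph(rng: np.random.Generator, color, pattern: str) -> np.ndarray:
    img = np.zeros((_TSIZE, _TSIZE, 3), dtype=np.uint8)
    img[:] = color
    yy, xx = np.mgrid[0:_TSIZE, 0:_TSIZE]
    if pattern == "diag":
        m = np.abs(yy - xx) <= 1
    elif pattern == "anti":
        m = np.abs(yy + xx - (_TSIZE - 1)) <= 1
    else:  # ring
        r = np.hypot(yy - _TSIZE / 2 + 0.5, xx - _TSIZE / 2 + 0.5)
        m = np.abs(r - 5) <= 1.2
    img[m] = (255, 255, 255)
    # fixed speckle so the template never degenerates to low variance
    speck = rng.random((_TSIZE, _TSIZE)) < 0.08
    img[speck] = (20, 20, 20)
    return img


def default_templates(
    width_px: int, height_px: int, threshold: float = 0.8, seed: int = 7
) -> Dict[str, IndicatorTemplate]:
    """Deterministic built-in glyph set for a given view size.

    Anchors follow the usual console layout: arm glyphs in the lower
    corners, camera glyph centred at the top.
    """
    rng = np.random.default_rng(seed)
    pad = 4
    region = _TSIZE + 2 * pad
    mk = lambda img, x, y, kind: IndicatorTemplate(
        img, (x, y, region, region), kind, threshold
    )
    left = _glyph(rng, (30, 160, 30), "diag")
    right = _glyph(rng, (30, 60, 200), "anti")
    cam = _glyph(rng, (150, 150, 150), "ring")
    return {
        KIND_LEFT: mk(left, 4, height_px - region - 4, KIND_LEFT),
        KIND_RIGHT: mk(right, width_px - region - 4, height_px - region - 4, KIND_RIGHT),
        KIND_CAMERA: mk(cam, width_px // 2 - region // 2, 4, KIND_CAMERA),
    }


def template_draw_position(template: IndicatorTemplate) -> tuple:
    """Top-left pixel where the glyph is painted (centred in its anchor)."""
    x, y, w, h = template.anchor
    th, tw = template.image.shape[:2]
    return x + (w - tw) // 2, y + (h - th) // 2
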