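"""Instrument-tip localization and pixel-to-millimetre calibration.

The tip — not the box centre — is the clinically meaningful point of an
instrument, so it is located geometrically from the segmentation mask.
Image displacements are converted to millimetres through the known 8 mm
shaft diameter: the shaft width is measured in pixels on the first
qualifying frame and held constant for the video (zoom changes during a
video are a documented error source of this scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

DEFAULT_SHAFT_MM = 8.0


@dataclass(frozen=True)
class Calibration:
    shaft_width_px: float
    shaft_width_mm: float = DEFAULT_SHAFT_MM

    def __post_init__(self):
        if self.shaft_width_px <= 0 or self.shaft_width_mm <= 0:
            raise ValueError("shaft widths must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.shaft_width_mm / self.shaft_width_px


def _mask_pixels(mask: np.ndarray) -> np.ndarray:
    pts = np.argwhere(np.asarray(mask, dtype=bool))  # (row, col)
    if len(pts) == 0:
        raise ValueError("empty mask")
    return pts


def _principal_axes(pts: np.ndarray):
    ctr = pts.mean(axis=0)
    d = pts - ctr
    cov = d.T @ d / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    # eigh returns ascending: column 1 = major axis
    return ctr, vecs[:, 1], vecs[:, 0], vals[::-1]


def detect_tip(
    mask: np.ndarray, frame_shape: Optional[Tuple[int, int]] = None
) -> Tuple[int, int]:
    """Locate the tip pixel of an instrument mask; returns ``(x, y)``.

    Instruments enter from an image border, so when the mask touches a
    border the tip is the mask pixel farthest from the centroid of the
    border-contact pixels.  For an interior mask the tip is the extreme
    pixel along the major principal axis on the side with the smaller
    perpendicular width.  Ties break deterministically (smallest y, then
    smallest x).
    """
    m = np.asarray(mask, dtype=bool)
    pts = _mask_pixels(m)
    H, W = frame_shape if frame_shape is not None else m.shape
    border = (
        (pts[:, 0] == 0) | (pts[:, 0] == H - 1) | (pts[:, 1] == 0) | (pts[:, 1] == W - 1)
    )
    if border.any():
        ctr = pts[border].mean(axis=0)
        d2 = ((pts - ctr) ** 2).sum(axis=1)
        best = d2.max()
        cand = pts[d2 >= best - 1e-9]
    else:
        ctr, major, minor, _ = _principal_axes(pts)
        t = (pts - ctr) @ major
        s = (pts - ctr) @ minor
        # pick the thinner end of the shaft; widths are compared inside
        # windows at the ends of the t-range (a tapered tip holds few
        # pixels, so pixel-quantile windows would dilute it with shaft)
        span = t.max() - t.min()
        win = max(0.15 * span, 2.0)
        hi_w = np.abs(s[t >= t.max() - win])
        lo_w = np.abs(s[t <= t.min() + win])
        hi_med = np.median(hi_w) if len(hi_w) else np.inf
        lo_med = np.median(lo_w) if len(lo_w) else np.inf
        tt = t if hi_med <= lo_med else -t
        best = tt.max()
        cand = pts[tt >= best - 1e-9]
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    r, c = cand[0]
    return int(c), int(r)


def measure_shaft_width(mask: np.ndarray, min_elongation: float = 2.0) -> float:
    """Median mask extent perpendicular to the major principal axis (px).

    Requires an elongated mask (major/minor spread ratio >= 2); the tip
    taper is excluded by sampling only the central part of the shaft.
    """
    pts = _mask_pixels(mask)
    ctr, major, minor, vals = _principal_axes(pts)
    if vals[1] <= 0 or np.sqrt(vals[0] / max(vals[1], 1e-12)) < min_elongation:
        raise ValueError("mask not elongated enough to measure shaft width")
    t = (pts - ctr) @ major
    s = (pts - ctr) @ minor
    lo, hi = np.quantile(t, [0.1, 0.6])  # central shaft, clear of the tip
    nbins = max(int(hi - lo), 1)
    widths = []
    edges = np.linspace(lo, hi, nbins + 1)
    for b in range(nbins):
        sel = (t >= edges[b]) & (t < edges[b + 1])
        if sel.sum() >= 2:
            widths.append(s[sel].max() - s[sel].min() + 1.0)
    if not widths:
        raise ValueError("too few shaft samples to measure width")
    return float(np.median(widths))


def calibrate_from_masks(masks, shaft_width_mm: float = DEFAULT_SHAFT_MM) -> Calibration:
    """Measure the calibration on the first qualifying mask of a video."""
    last_err = None
    for m in masks:
        try:
            w = measure_shaft_width(m)
            return Calibration(w, shaft_width_mm)
        except ValueError as e:  # insufficient elongation: try a later frame
            last_err = e
    raise ValueError(f"no qualifying frame for calibration: {last_err}")


def calibrate_and_convert(trajectory: pd.DataFrame, calibration: Calibration) -> pd.DataFrame:
    """Add millimetre coordinates to a pixel trajectory (linear scaling)."""
    out = trajectory.copy()
    out["x_mm"] = out["x_px"] * calibration.mm_per_px
    out["y_mm"] = out["y_px"] * calibration.mm_per_px
    return out
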