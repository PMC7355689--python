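"""Synthetic surgical-scene simulator with complete ground truth.

Scenes emulate a robotic endoscopic view: one to three rigid elongated
instruments pivot about fixed entry ports on the image border, their tips
following smooth interpolated trajectories; instruments can cross and
occlude each other, leave the view and re-enter, and the whole scene can
translate while the (simulated) laparoscope is moved.  Fixed-position
arm-status and camera-arm glyphs are overlaid exactly as a surgical
console would.  Every frame carries exact per-instrument masks, boxes and
tip positions, so each downstream stage can be validated without real
video.

Geometry: pixel grid, origin top-left, x rightward, y downward, 0-based;
boxes are half-open ``[x, x+w) x [y, y+h)``.  An instrument is a
flat-shaded capsule shaft ending in a tapered tip wedge; the ground-truth
tip is the distal-most rendered mask pixel along the shaft axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from . import indicators as _ind

DEFAULT_SHAFT_MM = 8.0  # standard da Vinci shaft diameter


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class InstrumentSpec:
    """One instrument: its entry port, tip waypoints and appearance."""

    waypoint_frames: Tuple[int, ...]
    waypoints: Tuple[Tuple[float, float], ...]  # tip positions, px
    entry_side: str  # "left" | "right"
    entry_y: float
    base_hue: float  # [0, 1)
    stripe_period: float = 16.0
    stripe_phase: float = 0.0

    def __post_init__(self):
        if self.entry_side not in ("left", "right"):
            raise ValueError("entry_side must be 'left' or 'right'")
        if len(self.waypoint_frames) != len(self.waypoints) or len(self.waypoints) < 2:
            raise ValueError("need >= 2 waypoints with matching frame stamps")


@dataclass(frozen=True)
class SceneConfig:
    width_px: int = 480
    height_px: int = 360
    fps: float = 23.0
    n_frames: int = 200
    n_instruments: int = 2
    shaft_width_px: int = 12
    shaft_width_mm: float = DEFAULT_SHAFT_MM
    instruments: Tuple[InstrumentSpec, ...] = ()
    occlusion_events: Tuple[Tuple[int, int, Tuple[int, int]], ...] = ()
    exit_events: Tuple[Tuple[int, int, int], ...] = ()
    camera_motion_events: Tuple[Tuple[int, int, Tuple[float, float]], ...] = ()
    # active-instrument schedule as (start_frame, ids) change points
    active_schedule: Tuple[Tuple[int, Tuple[int, ...]], ...] = ()
    noise_seed: int = 0
    background_noise: float = 6.0

    @property
    def mm_per_px(self) -> float:
        return self.shaft_width_mm / self.shaft_width_px

    def validate(self):
        if not 1 <= self.n_instruments <= 3:
            raise ValueError("n_instruments must be 1, 2 or 3")
        if len(self.instruments) != self.n_instruments:
            raise ValueError("instruments list must match n_instruments")
        ids = range(self.n_instruments)
        for f0, f1, pair in self.occlusion_events:
            if pair[0] not in ids or pair[1] not in ids or pair[0] == pair[1]:
                raise ValueError(f"occlusion event references unknown pair {pair}")
            self._check_interval(f0, f1)
        for f0, f1, i in self.exit_events:
            if i not in ids:
                raise ValueError(f"exit event references unknown instrument {i}")
            self._check_interval(f0, f1)
        for f0, f1, _ in self.camera_motion_events:
            self._check_interval(f0, f1)
        for _, act in self.active_schedule:
            if len(act) > 2:
                raise ValueError("at most two instruments can be active")
            if any(i not in ids for i in act):
                raise ValueError("active schedule references unknown instrument")

    def _check_interval(self, f0, f1):
        if not (0 <= f0 < f1 <= self.n_frames):
            raise ValueError(f"event interval [{f0}, {f1}) outside scene")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class InstrumentFrameGT:
    visible: bool
    box: Optional[Tuple[int, int, int, int]] = None  # (x, y, w, h)
    mask: Optional[np.ndarray] = None  # box-local boolean grid
    tip: Optional[Tuple[int, int]] = None  # (x, y) px

    def full_mask(self, width: int, height: int) -> np.ndarray:
        m = np.zeros((height, width), dtype=bool)
        if self.visible:
            x, y, w, h = self.box
            m[y : y + h, x : x + w] = self.mask
        return m


@dataclass
class GroundTruth:
    config: SceneConfig
    per_frame: List[Dict[int, InstrumentFrameGT]]
    camera_moving: np.ndarray  # (n_frames,) bool
    active: List[frozenset]  # active instrument ids per frame
    arm_of: Dict[int, str]  # instrument id -> "left" | "right"

    @property
    def mm_per_px(self) -> float:
        return self.config.mm_per_px

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def active_arms(self, frame_index: int) -> frozenset:
        return frozenset(self.arm_of[i] for i in self.active[frame_index])

    def tip_trajectory(self, instrument: int):
        """(frames, xy) arrays of the instrument's visible tip pixels."""
        fr, xy = [], []
        for t, inst in enumerate(self.per_frame):
            g = inst[instrument]
            if g.visible:
                fr.append(t)
                xy.append(g.tip)
        return np.asarray(fr, dtype=int), np.asarray(xy, dtype=float).reshape(-1, 2)

    def to_json(self) -> str:
        """Versioned JSON GT dump (masks as row-major binary RLE)."""
        from .detection import rle_encode

        recs = []
        for t, inst in enumerate(self.per_frame):
            for i, g in inst.items():
                if not g.visible:
                    continue
                recs.append(
                    {
                        "frame": t,
                        "instrument": i,
                        "box": list(g.box),
                        "tip": list(g.tip),
                        "mask_rle": rle_encode(g.mask),
                    }
                )
        doc = {
            "schema": "surgtrack-gt/1",
            "width_px": self.config.width_px,
            "height_px": self.config.height_px,
            "fps": self.config.fps,
            "n_frames": self.config.n_frames,
            "mm_per_px": self.mm_per_px,
            "seed": self.config.noise_seed,
            "arm_of": {str(k): v for k, v in self.arm_of.items()},
            "camera_moving": self.camera_moving.astype(int).tolist(),
            "active": [sorted(a) for a in self.active],
            "instruments": recs,
        }
        return json.dumps(doc)


# ---------------------------------------------------------------------------
# scene construction


class FrameSequence(Sequence):
    """Lazy, indexable sequence of rendered RGB frames."""

    def __init__(self, scene: "Scene"):
        self._scene = scene

    def __len__(self):
        return self._scene.config.n_frames

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return self._scene.render_frame(i)


class Scene:
    """A generated scene: lazy frames plus complete ground truth."""

    def __init__(self, config: SceneConfig):
        config.validate()
        self.config = config
        self._rng = np.random.default_rng(config.noise_seed)
        self.templates = _ind.default_templates(config.width_px, config.height_px)
        self._camera_offsets = self._cumulative_camera_offsets()
        self._background = self._make_background()
        self._tip_paths = self._tip_positions()
        self._visible = self._visibility()
        self.ground_truth = self._build_ground_truth()
        self.frames = FrameSequence(self)

    # -- kinematics ---------------------------------------------------------

    def _cumulative_camera_offsets(self) -> np.ndarray:
        c = self.config
        step = np.zeros((c.n_frames, 2))
        moving = np.zeros(c.n_frames, dtype=bool)
        for f0, f1, (dx, dy) in c.camera_motion_events:
            step[f0:f1] += (dx, dy)
            moving[f0:f1] = True
        self._camera_moving = moving
        return np.cumsum(step, axis=0)

    def _entry_point(self, spec: InstrumentSpec) -> np.ndarray:
        x = -2.0 if spec.entry_side == "left" else self.config.width_px + 1.0
        return np.array([x, spec.entry_y])

    def _tip_positions(self) -> np.ndarray:
        """(n_instruments, n_frames, 2) tip paths after event steering."""
        c = self.config
        t = np.arange(c.n_frames, dtype=float)
        paths = np.empty((c.n_instruments, c.n_frames, 2))
        for i, spec in enumerate(c.instruments):
            fr = np.asarray(spec.waypoint_frames, dtype=float)
            wp = np.asarray(spec.waypoints, dtype=float)
            for ax in range(2):
                paths[i, :, ax] = PchipInterpolator(fr, wp[:, ax])(
                    np.clip(t, fr[0], fr[-1])
                )
        # occlusion events steer the second instrument of the pair onto the
        # first with a smooth cosine ramp so motion stays continuous; the
        # approach takes ~1 s of video, like a deliberate hand movement
        ramp_len = 25
        w = c.shaft_width_px
        for f0, f1, (a, b) in c.occlusion_events:
            lo = max(f0 - ramp_len, 0)
            hi = min(f1 + ramp_len, c.n_frames)
            r = np.zeros(c.n_frames)
            r[f0:f1] = 1.0
            up = np.arange(lo, f0)
            if len(up):
                r[up] = 0.5 - 0.5 * np.cos(np.pi * (up - lo + 1) / (f0 - lo + 1))
            dn = np.arange(f1, hi)
            if len(dn):
                r[dn] = 0.5 + 0.5 * np.cos(np.pi * (dn - f1 + 1) / (hi - f1 + 1))
            # steer b's tip past a's tip so the full-width shaft bodies
            # cross (the tapered tips themselves are too thin to overlap)
            overshoot = 3.0 * w
            sign = -1.0 if c.instruments[b].entry_side == "right" else 1.0
            target = paths[a] + np.array([sign * overshoot, 0.0])
            paths[b] = paths[b] + r[:, None] * (target - paths[b])
        paths += self._camera_offsets[None, :, :]
        return paths

    def _visibility(self) -> np.ndarray:
        c = self.config
        vis = np.ones((c.n_instruments, c.n_frames), dtype=bool)
        for f0, f1, i in c.exit_events:
            vis[i, f0:f1] = False
        return vis

    # -- appearance ---------------------------------------------------------

    def _make_background(self) -> np.ndarray:
        c = self.config
        off = self._camera_offsets
        pad = int(np.ceil(np.abs(off).max())) + 2 if len(off) else 2
        self._bg_pad = pad
        h, w = c.height_px + 2 * pad, c.width_px + 2 * pad
        base = np.array([46.0, 24.0, 28.0])
        tex = gaussian_filter(self._rng.normal(0, 1, (h, w)), 6.0)
        tex = tex / (np.abs(tex).max() + 1e-12)
        img = base[None, None, :] * (1.0 + 0.35 * tex[:, :, None])
        img += self._rng.normal(0, c.background_noise * 0.15, img.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    # -- rasterization ------------------------------------------------------

    def _instrument_mask(self, i: int, frame_index: int):
        """Box-local mask, box, tip pixel for one instrument in one frame.

        Returns (box, local_mask, tip) or None when out of view.
        """
        c = self.config
        if not self._visible[i, frame_index]:
            return None
        tip = self._tip_paths[i, frame_index]
        anchor = self._entry_point(c.instruments[i]) + self._camera_offsets[frame_index]
        axis = tip - anchor
        T = float(np.hypot(*axis))
        if T < 1e-6:
            return None
        u = axis / T
        v = np.array([-u[1], u[0]])
        w2 = c.shaft_width_px / 2.0
        tip_len = 2.0 * c.shaft_width_px

        # ROI: capsule bounding box clipped to the frame
        corners = np.stack(
            [
                anchor + w2 * v,
                anchor - w2 * v,
                tip + w2 * v,
                tip - w2 * v,
            ]
        )
        x0 = max(int(np.floor(corners[:, 0].min())) - 1, 0)
        x1 = min(int(np.ceil(corners[:, 0].max())) + 2, c.width_px)
        y0 = max(int(np.floor(corners[:, 1].min())) - 1, 0)
        y1 = min(int(np.ceil(corners[:, 1].max())) + 2, c.height_px)
        if x0 >= x1 or y0 >= y1:
            return None
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx, gy = np.meshgrid(xs, ys)
        dx = gx - anchor[0]
        dy = gy - anchor[1]
        t = dx * u[0] + dy * u[1]
        s = np.abs(dx * v[0] + dy * v[1])
        shaft = (t >= 0) & (t <= T - tip_len) & (s <= w2)
        taper = (t > T - tip_len) & (t <= T)
        wedge = taper & (s <= w2 * (T - t) / tip_len)
        m = shaft | wedge
        if not m.any():
            return None
        # tight box + local mask
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        by0, by1 = rows[0], rows[-1] + 1
        bx0, bx1 = cols[0], cols[-1] + 1
        local = m[by0:by1, bx0:bx1]
        box = (int(x0 + bx0), int(y0 + by0), int(bx1 - bx0), int(by1 - by0))
        # GT tip = the rendered distal apex pixel: the mask pixel farthest
        # from the centroid of the border-contact pixels (the shaft always
        # enters through a border); ties -> smallest y, then x.  This pins
        # the label to the rasterized wedge apex (within a couple of px of
        # the continuous apex).
        tloc = np.where(m, t, -np.inf)
        tmax = tloc.max()
        rows_m, cols_m = np.nonzero(m)
        gx_m = x0 + cols_m
        gy_m = y0 + rows_m
        contact = (
            (gx_m == 0)
            | (gx_m == c.width_px - 1)
            | (gy_m == 0)
            | (gy_m == c.height_px - 1)
        )
        if contact.any():
            cx = gx_m[contact].mean()
            cy = gy_m[contact].mean()
            d2 = (gx_m - cx) ** 2 + (gy_m - cy) ** 2
            best = d2.max()
            sel = d2 >= best - 1e-9
        else:  # fully interior (should not happen): distal along the axis
            sel = tloc[rows_m, cols_m] >= tmax - 1e-9
        cand = np.stack([gy_m[sel], gx_m[sel]], axis=1)
        cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
        tip_px = (int(cand[0][1]), int(cand[0][0]))
        # require the true apex to be in view (not clipped at a border);
        # the rasterized apex pixel sits within a few px of the geometric
        # apex, so only genuine clipping trips this
        if tmax < T - 4.0:
            return None
        return box, local, tip_px

    def _instrument_color(self, i: int, t: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Flat-shaded HSV shading with longitudinal stripes (t, s in px)."""
        spec = self.config.instruments[i]
        h = spec.base_hue
        sat = 0.75
        val = 0.72 + 0.18 * np.sin(
            2 * np.pi * t / spec.stripe_period + spec.stripe_phase
        )
        import colorsys

        # vectorized hsv->rgb for constant h, s
        r, g, b = colorsys.hsv_to_rgb(h, sat, 1.0)
        rgb = np.stack([r * val, g * val, b * val], axis=-1)
        return np.clip(rgb * 255, 0, 255).astype(np.uint8)

    def render_frame(self, frame_index: int) -> np.ndarray:
        """Render one RGB frame (uint8, H x W x 3). Deterministic."""
        c = self.config
        if not 0 <= frame_index < c.n_frames:
            raise IndexError("frame index out of range")
        pad = self._bg_pad
        off = self._camera_offsets[frame_index]
        # camera pans the view window across the background
        ox = int(round(pad - off[0]))
        oy = int(round(pad - off[1]))
        img = self._background[oy : oy + c.height_px, ox : ox + c.width_px].copy()
        gt = self.ground_truth.per_frame[frame_index]
        for i in range(c.n_instruments):
            g = gt[i]
            if not g.visible:
                continue
            x, y, w, h = g.box
            m = g.mask
            anchor = self._entry_point(c.instruments[i]) + off
            xs = np.arange(x, x + w)
            ys = np.arange(y, y + h)
            gx, gy = np.meshgrid(xs, ys)
            tip = self._tip_paths[i, frame_index]
            axis = tip - anchor
            u = axis / np.hypot(*axis)
            v = np.array([-u[1], u[0]])
            t = (gx - anchor[0]) * u[0] + (gy - anchor[1]) * u[1]
            s = (gx - anchor[0]) * v[0] + (gy - anchor[1]) * v[1]
            col = self._instrument_color(i, t, s)
            roi = img[y : y + h, x : x + w]
            roi[m] = col[m]
        # console overlays
        state_arms = self.ground_truth.active_arms(frame_index)
        draw = []
        if "left" in state_arms:
            draw.append(self.templates[_ind.KIND_LEFT])
        if "right" in state_arms:
            draw.append(self.templates[_ind.KIND_RIGHT])
        if self.ground_truth.camera_moving[frame_index]:
            draw.append(self.templates[_ind.KIND_CAMERA])
        for tm in draw:
            tx, ty = _ind.template_draw_position(tm)
            th, tw = tm.image.shape[:2]
            img[ty : ty + th, tx : tx + tw] = tm.image
        return img

    # -- ground truth -------------------------------------------------------

    def _build_ground_truth(self) -> GroundTruth:
        c = self.config
        per_frame: List[Dict[int, InstrumentFrameGT]] = []
        for f in range(c.n_frames):
            entry = {}
            for i in range(c.n_instruments):
                res = self._instrument_mask(i, f)
                if res is None:
                    entry[i] = InstrumentFrameGT(visible=False)
                else:
                    box, local, tip = res
                    entry[i] = InstrumentFrameGT(True, box, local, tip)
            per_frame.append(entry)
        active = self._active_per_frame()
        arm_of = {i: c.instruments[i].entry_side for i in range(c.n_instruments)}
        return GroundTruth(c, per_frame, self._camera_moving.copy(), active, arm_of)

    def _active_per_frame(self) -> List[frozenset]:
        c = self.config
        sched = sorted(self.config.active_schedule)
        if not sched:
            sched = [(0, tuple(range(min(2, c.n_instruments))))]
        if sched[0][0] != 0:
            sched = [(0, sched[0][1])] + sched
        out = []
        k = 0
        cur = frozenset(sched[0][1])
        for f in range(c.n_frames):
            while k + 1 < len(sched) and sched[k + 1][0] <= f:
                k += 1
                cur = frozenset(sched[k][1])
            out.append(cur)
        return out


def generate_scene(config: SceneConfig):
    """Build a scene; returns ``(frames, ground_truth)``.

    ``frames`` is a lazy indexable sequence of rendered RGB frames; the
    underlying :class:`Scene` is reachable as ``frames._scene``.
    """
    scene = Scene(config)
    return scene.frames, scene.ground_truth


# ---------------------------------------------------------------------------
# ready-made scene layout


def default_scene_config(
    n_frames: int = 200,
    n_instruments: int = 2,
    seed: int = 0,
    width_px: int = 480,
    height_px: int = 360,
    fps: float = 23.0,
    shaft_width_px: int = 12,
    with_occlusions: bool = True,
    with_exits: bool = True,
    with_camera_motion: bool = True,
    n_waypoints: int = 6,
) -> SceneConfig:
    """A realistic default layout: instruments pivot about lateral ports,
    wander smoothly inside the view, cross once per ~150 frames, take one
    exit/re-entry excursion each and the camera pans twice."""
    rng = np.random.default_rng(seed)
    hues = [0.02, 0.58, 0.33]  # red-ish, blue-ish, green-ish
    margin_x, margin_y = 70, 60
    specs = []
    # instruments sharing an entry side keep disjoint working bands (and
    # separated ports), as hands do; otherwise two same-side shafts can
    # drift into near-coincident lines that no detector could separate
    side_of = ["left" if i % 2 == 0 else "right" for i in range(n_instruments)]
    for i in range(n_instruments):
        side = side_of[i]
        same_side = [j for j in range(n_instruments) if side_of[j] == side]
        fr = tuple(np.linspace(0, n_frames - 1, n_waypoints).astype(int))
        if side == "left":
            xs = rng.uniform(margin_x, width_px * 0.55, n_waypoints)
        else:
            xs = rng.uniform(width_px * 0.45, width_px - margin_x, n_waypoints)
        y_lo, y_hi = margin_y, height_px - margin_y
        if len(same_side) > 1:
            k = same_side.index(i)
            band = (y_hi - y_lo) / len(same_side)
            y_lo, y_hi = y_lo + k * band, y_lo + (k + 1) * band
            entry_y = (0.25 + 0.5 * k) * height_px
        else:
            entry_y = float(rng.uniform(height_px * 0.3, height_px * 0.7))
        ys = rng.uniform(y_lo, y_hi, n_waypoints)
        specs.append(
            InstrumentSpec(
                waypoint_frames=fr,
                waypoints=tuple(zip(xs, ys)),
                entry_side=side,
                entry_y=float(entry_y),
                base_hue=hues[i],
                stripe_period=float(rng.uniform(12, 22)),
                stripe_phase=float(rng.uniform(0, 2 * np.pi)),
            )
        )
    occl, exits, cam = (), (), ()
    if with_occlusions and n_instruments >= 2:
        k = max(1, n_frames // 150)
        starts = np.linspace(0.15, 0.45, k) * n_frames
        occl = tuple(
            (int(s), int(s) + 12, (0, 1)) for s in starts
        )
    if with_exits:
        exits = tuple(
            (int(n_frames * (0.55 + 0.12 * i)), int(n_frames * (0.55 + 0.12 * i)) + max(8, n_frames // 25), i)
            for i in range(n_instruments)
        )
    if with_camera_motion:
        f0 = int(n_frames * 0.85)
        cam = ((f0, min(f0 + max(10, n_frames // 20), n_frames), (0.8, 0.3)),)
    active = ((0, tuple(range(min(2, n_instruments)))),)
    cfg = SceneConfig(
        width_px=width_px,
        height_px=height_px,
        fps=fps,
        n_frames=n_frames,
        n_instruments=n_instruments,
        shaft_width_px=shaft_width_px,
        instruments=tuple(specs),
        occlusion_events=occl,
        exit_events=exits,
        camera_motion_events=cam,
        active_schedule=active,
        noise_seed=seed,
    )
    cfg.validate()
    return cfg


def write_scene(frames, gt: GroundTruth, out_dir) -> None:
    """Persist frames as zero-padded PNGs, masks as 0/255 PNGs and GT JSON."""
    from PIL import Image

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i in range(len(frames)):
        Image.fromarray(frames[i]).save(out / "frames" / f"frame_{i:06d}.png")
        for j, g in gt.per_frame[i].items():
            if g.visible:
                m = (g.full_mask(gt.config.width_px, gt.config.height_px) * 255).astype(
                    np.uint8
                )
                Image.fromarray(m).save(out / "masks" / f"mask_{i:06d}_{j}.png")
    (out / "ground_truth.json").write_text(gt.to_json())
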