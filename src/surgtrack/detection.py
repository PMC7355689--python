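"""Per-frame instrument detection providers and non-maximum suppression.

Detections are class-free: a detector reports *instrument foreground*
(box + mask + confidence) only, and instrument identity is assigned
downstream by the tracker and the re-identification cascade.  Two
providers are included: an oracle backed by simulator ground truth with a
configurable corruption model (jitter, misses, false positives, merged
detections under occlusion), and a classical colour/shape segmenter for
rendered frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .scene import GroundTruth


@dataclass(eq=False)
class Detection:
    """One instrument candidate in one frame.

    ``mask`` is box-local (``mask.shape == (h, w)`` of ``box``); use
    :meth:`full_mask` for the frame-sized grid.
    """

    frame_index: int
    box: Tuple[int, int, int, int]  # (x, y, w, h), half-open
    mask: np.ndarray
    confidence: float

    def __post_init__(self):
        x, y, w, h = self.box
        if self.mask is not None:
            if self.mask.shape != (h, w):
                raise ValueError("mask shape must match box (h, w)")
            if not self.mask.any():
                raise ValueError("mask must be nonempty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    def full_mask(self, width: int, height: int) -> np.ndarray:
        m = np.zeros((height, width), dtype=bool)
        x, y, w, h = self.box
        m[y : y + h, x : x + w] = self.mask
        return m

    @property
    def center(self) -> Tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Corruption model for the ground-truth-backed oracle detector."""

    box_jitter_sd: float = 0.0  # px, per axis
    miss_rate: float = 0.0
    false_positive_rate: float = 0.0  # expected spurious detections / frame
    merge_on_occlusion: bool = False
    confidence_base: float = 1.0
    confidence_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.box_jitter_sd < 0 or self.false_positive_rate < 0:
            raise ValueError("noise magnitudes must be non-negative")


ZERO_NOISE = NoiseConfig()


def _rng_for_frame(noise: NoiseConfig, frame_index: int) -> np.random.Generator:
    # per-frame stream: reproducible regardless of evaluation order
    return np.random.default_rng((noise.seed, frame_index))


def _shift_box_mask(box, mask, dx, dy, width, height):
    """Translate a box-local mask by integer offsets, clipping to the frame."""
    x, y, w, h = box
    x += dx
    y += dy
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + w, width), min(y + h, height)
    if x0 >= x1 or y0 >= y1:
        return None
    local = mask[y0 - y : y1 - y, x0 - x : x1 - x]
    if not local.any():
        return None
    return (x0, y0, x1 - x0, y1 - y0), local


def oracle_detect(
    gt: GroundTruth, frame_index: int, noise: NoiseConfig = ZERO_NOISE
) -> List[Detection]:
    """Ground-truth-backed detector with a configurable corruption model.

    At zero noise the detections equal the GT boxes and masks with
    confidence 1.  With ``merge_on_occlusion`` set, instruments whose GT
    masks overlap are emitted as a single fused detection (union mask,
    hull box) — the classic occlusion failure mode of segmentation-only
    pipelines.
    """
    if not 0 <= frame_index < gt.n_frames:
        raise IndexError("frame index outside scene")
    c = gt.config
    rng = _rng_for_frame(noise, frame_index)
    visible = [(i, g) for i, g in gt.per_frame[frame_index].items() if g.visible]

    groups: List[List[Tuple[int, object]]] = []
    if noise.merge_on_occlusion and len(visible) > 1:
        # union-find over pairwise mask overlap
        parent = {i: i for i, _ in visible}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        full = {i: g.full_mask(c.width_px, c.height_px) for i, g in visible}
        idx = [i for i, _ in visible]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if (full[idx[a]] & full[idx[b]]).any():
                    parent[find(idx[a])] = find(idx[b])
        roots = {}
        for i, g in visible:
            roots.setdefault(find(i), []).append((i, g))
        groups = list(roots.values())
    else:
        groups = [[(i, g)] for i, g in visible]

    dets: List[Detection] = []
    for grp in groups:
        if rng.random() < noise.miss_rate:
            continue
        if len(grp) == 1:
            _, g = grp[0]
            box, mask = g.box, g.mask
        else:
            full = np.zeros((c.height_px, c.width_px), dtype=bool)
            for _, g in grp:
                full |= g.full_mask(c.width_px, c.height_px)
            rows = np.flatnonzero(full.any(axis=1))
            cols = np.flatnonzero(full.any(axis=0))
            box = (cols[0], rows[0], cols[-1] + 1 - cols[0], rows[-1] + 1 - rows[0])
            mask = full[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        if noise.box_jitter_sd > 0:
            dx, dy = np.round(rng.normal(0, noise.box_jitter_sd, 2)).astype(int)
            shifted = _shift_box_mask(box, mask, dx, dy, c.width_px, c.height_px)
            if shifted is None:
                continue
            box, mask = shifted
        conf = noise.confidence_base
        if noise.confidence_jitter > 0:
            conf += rng.normal(0, noise.confidence_jitter)
        dets.append(Detection(frame_index, tuple(int(v) for v in box), mask.copy(), float(np.clip(conf, 0, 1))))

    n_fp = rng.poisson(noise.false_positive_rate)
    for _ in range(n_fp):
        w = int(rng.integers(20, 60))
        h = int(rng.integers(20, 60))
        x = int(rng.integers(0, max(c.width_px - w, 1)))
        y = int(rng.integers(0, max(c.height_px - h, 1)))
        m = np.zeros((h, w), dtype=bool)
        yy, xx = np.mgrid[0:h, 0:w]
        m[((xx - w / 2) / (w / 2)) ** 2 + ((yy - h / 2) / (h / 2)) ** 2 <= 1] = True
        conf = float(np.clip(rng.uniform(0.3, 0.8), 0, 1))
        dets.append(Detection(frame_index, (x, y, w, h), m, conf))
    return dets


@dataclass(frozen=True)
class ColorSegmenterParams:
    """HSV thresholds for the classical foreground segmenter.

    Defaults target the simulator's saturated metallic-hued instruments on
    the darker, low-saturation tissue background.
    """

    min_value: float = 0.35
    min_saturation: float = 0.45
    min_area: int = 150


def color_segment(
    frame: np.ndarray,
    params: ColorSegmenterParams = ColorSegmenterParams(),
    frame_index: int = 0,
) -> List[Detection]:
    """Threshold + connected components segmenter for rendered frames."""
    hsv = rgb2hsv(frame)
    fg = (hsv[:, :, 2] >= params.min_value) & (hsv[:, :, 1] >= params.min_saturation)
    lab = cc_label(fg, connectivity=2)
    dets = []
    for rp in regionprops(lab):
        if rp.area < params.min_area:
            continue
        y0, x0, y1, x1 = rp.bbox
        mask = rp.image
        conf = float(rp.area / ((y1 - y0) * (x1 - x0)))
        dets.append(
            Detection(frame_index, (x0, y0, x1 - x0, y1 - y0), mask, min(conf, 1.0))
        )
    dets.sort(key=lambda d: -d.confidence)
    return dets


def box_iou(a, b) -> float:
    """IOU of two half-open (x, y, w, h) boxes; 0 when both degenerate."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw < 0 or ah < 0 or bw < 0 or bh < 0:
        raise ValueError("box sides must be non-negative")
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    if union <= 0:
        return 0.0
    return inter / union


def masks_overlap(a: Detection, b: Detection) -> bool:
    """Whether two detections' masks share any pixel (box-local test)."""
    ax, ay, aw, ah = a.box
    bx, by, bw, bh = b.box
    ix0, iy0 = max(ax, bx), max(ay, by)
    ix1, iy1 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    if ix0 >= ix1 or iy0 >= iy1:
        return False
    sub_a = a.mask[iy0 - ay : iy1 - ay, ix0 - ax : ix1 - ax]
    sub_b = b.mask[iy0 - by : iy1 - by, ix0 - bx : ix1 - bx]
    return bool((sub_a & sub_b).any())


def mask_iou(a: Detection, b: Detection) -> float:
    """IOU of two detections' masks (box IOU when either mask is absent).

    Crossing elongated instruments can share most of their hull boxes
    while sharing almost no pixels, so duplicate suppression must compare
    masks when it has them.
    """
    if a.mask is None or b.mask is None:
        return box_iou(a.box, b.box)
    ax, ay, aw, ah = a.box
    bx, by, bw, bh = b.box
    ix0, iy0 = max(ax, bx), max(ay, by)
    ix1, iy1 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    inter = 0
    if ix0 < ix1 and iy0 < iy1:
        sub_a = a.mask[iy0 - ay : iy1 - ay, ix0 - ax : ix1 - ax]
        sub_b = b.mask[iy0 - by : iy1 - by, ix0 - bx : ix1 - bx]
        inter = int((sub_a & sub_b).sum())
    union = int(a.mask.sum()) + int(b.mask.sum()) - inter
    return inter / union if union > 0 else 0.0


def nms(candidates: Sequence[Detection], iou_threshold: float = 0.5) -> List[Detection]:
    """Greedy non-maximum suppression in descending confidence.

    Overlap uses the mask IOU (falling back to box IOU for mask-less
    candidates).  Ties in confidence are broken by the smaller input index
    so the result is deterministic; the output is sorted by confidence
    descending and any surviving pair has IOU strictly below the
    threshold.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in [0, 1]")
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].confidence, i))
    keep: List[int] = []
    for i in order:
        if all(mask_iou(candidates[i], candidates[j]) < iou_threshold for j in keep):
            keep.append(i)
    return [candidates[i] for i in keep]


# ---------------------------------------------------------------------------
# serialization: JSON-lines with a documented run-length mask encoding
#
# RLE scheme: the box-local mask is flattened row-major; the encoding is a
# list of run lengths alternating value 0 then 1, starting with the length
# of the initial 0-run (possibly zero).  Sum of runs equals h * w.


def rle_encode(mask: np.ndarray) -> List[int]:
    flat = np.asarray(mask, dtype=np.uint8).ravel()
    if flat.size == 0:
        return []
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: Sequence[int], shape: Tuple[int, int]) -> np.ndarray:
    total = int(np.prod(shape))
    flat = np.zeros(total, dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    if pos != total:
        raise ValueError("RLE runs do not cover the mask")
    return flat.reshape(shape)


def detections_to_jsonl(dets: Iterable[Detection]) -> str:
    lines = []
    for d in dets:
        x, y, w, h = d.box
        lines.append(
            json.dumps(
                {
                    "frame": d.frame_index,
                    "box": [int(x), int(y), int(w), int(h)],
                    "confidence": d.confidence,
                    "mask_rle": rle_encode(d.mask),
                }
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def detections_from_jsonl(text: str) -> List[Detection]:
    dets = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        x, y, w, h = rec["box"]
        mask = rle_decode(rec["mask_rle"], (h, w))
        dets.append(Detection(rec["frame"], (x, y, w, h), mask, rec["confidence"]))
    return dets
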