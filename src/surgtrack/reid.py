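"""Cascaded appearance re-identification for instrument identity.

Tracking alone loses instrument identity when an instrument leaves the
view or crosses close to another.  The cascade re-assigns identity in two
stages: first an *offline* gallery of appearance exemplars accumulated
per identity is ranked against the query (at most three identities appear
in a robotic view); when that stage predicts an identity *change*, an
*online* bag-of-visual-words model fitted on the previous ten frames
casts a second vote, and the final label follows the online vote only if
it agrees with one of the candidates, otherwise the incumbent is kept.

The appearance descriptor is classical (grid HSV colour histograms plus
gradient-orientation histograms) behind a pluggable interface; any
stronger embedding with unit-norm output drops in unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.color import rgb2hsv
from sklearn.cluster import KMeans

MAX_IDENTITIES = 3
TIE_EPSILON = 0.02  # cosine distance below which appearances are "identical"

_GRID = 3
_HUE_BINS = 8
_SAT_BINS = 4
_ORI_BINS = 9
DESCRIPTOR_DIM = _GRID * _GRID * (_HUE_BINS * _SAT_BINS + _ORI_BINS)


def extract_descriptor(frame: np.ndarray, box, mask: np.ndarray | None = None) -> np.ndarray:
    """L2-normalized appearance descriptor of a box patch.

    Concatenates, over a 3x3 grid of the box, an 8 hue x 4 saturation
    colour histogram and a 9-bin gradient-orientation histogram per cell.
    When the detection's box-local ``mask`` is given, the histograms are
    restricted to foreground pixels — a thin instrument occupies a small
    fraction of its hull box, and background would otherwise dominate.
    """
    x, y, w, h = (int(v) for v in box)
    H, W = frame.shape[:2]
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + w, W), min(y + h, H)
    if x1 - x0 < _GRID or y1 - y0 < _GRID:
        raise ValueError("degenerate box for descriptor extraction")
    patch = np.asarray(frame[y0:y1, x0:x1], dtype=float) / 255.0
    hsv = rgb2hsv(patch)
    gray = patch.mean(axis=2)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation
    if mask is not None:
        fg = np.asarray(mask[y0 - y : y1 - y, x0 - x : x1 - x], dtype=float)
        if fg.shape != gray.shape or fg.sum() == 0:
            fg = np.ones_like(gray)
    else:
        fg = np.ones_like(gray)

    ph, pw = gray.shape
    ys = np.linspace(0, ph, _GRID + 1).astype(int)
    xs = np.linspace(0, pw, _GRID + 1).astype(int)
    feats = []
    for r in range(_GRID):
        for c in range(_GRID):
            sl = (slice(ys[r], ys[r + 1]), slice(xs[c], xs[c + 1]))
            wgt = fg[sl].ravel()
            hh = hsv[sl][..., 0].ravel()
            ss = hsv[sl][..., 1].ravel()
            col, _, _ = np.histogram2d(
                hh, ss, bins=(_HUE_BINS, _SAT_BINS), range=((0, 1), (0, 1)),
                weights=wgt,
            )
            oo = ori[sl].ravel()
            mm = mag[sl].ravel() * wgt
            oh, _ = np.histogram(oo, bins=_ORI_BINS, range=(0, np.pi), weights=mm)
            cell = np.concatenate([col.ravel(), oh])
            n = np.linalg.norm(cell)
            if n > 0:
                cell = cell / n
            feats.append(cell)
    vec = np.concatenate(feats)
    n = np.linalg.norm(vec)
    if n == 0:
        raise ValueError("descriptor degenerate (empty patch)")
    return vec / n


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(1.0 - a @ b)


# ---------------------------------------------------------------------------
# offline stage: exemplar gallery


class Gallery:
    """Per-identity appearance exemplars with FIFO-capped capacity."""

    def __init__(self, capacity: int = 50):
        self.capacity = capacity
        self._store: Dict[int, List[Tuple[int, np.ndarray]]] = {}

    @property
    def identities(self) -> List[int]:
        return sorted(self._store)

    def __len__(self):
        return len(self._store)

    def add(self, identity: int, descriptor: np.ndarray, frame_index: int = -1):
        if identity not in self._store and len(self._store) >= MAX_IDENTITIES:
            raise ValueError(f"gallery holds at most {MAX_IDENTITIES} identities")
        lst = self._store.setdefault(identity, [])
        lst.append((frame_index, descriptor))
        if len(lst) > self.capacity:
            lst.pop(0)

    def min_distance(self, identity: int, query: np.ndarray) -> float:
        return min(cosine_distance(d, query) for _, d in self._store[identity])

    def to_json(self) -> str:
        return json.dumps(
            {
                "capacity": self.capacity,
                "identities": {
                    str(i): [[f, d.tolist()] for f, d in lst]
                    for i, lst in self._store.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Gallery":
        doc = json.loads(text)
        g = cls(doc["capacity"])
        for i, lst in doc["identities"].items():
            for f, d in lst:
                g.add(int(i), np.asarray(d, dtype=float), f)
        return g


def gallery_rank(query: np.ndarray, gallery: Gallery) -> List[Tuple[int, float]]:
    """Identities sorted by min cosine distance to the query (<= 3 entries)."""
    if len(gallery) == 0:
        raise ValueError("empty gallery")
    ranked = sorted(
        ((i, gallery.min_distance(i, query)) for i in gallery.identities),
        key=lambda t: (t[1], t[0]),
    )
    return ranked[:MAX_IDENTITIES]


# ---------------------------------------------------------------------------
# online stage: bag of visual words over the previous ten frames

BOVW_WINDOW = 10  # frames of appearance history the online stage trains on


def patch_features(frame: np.ndarray, box, patch: int = 8, stride: int = 4) -> np.ndarray:
    """Dense local patch descriptors inside a box (colour + gradient)."""
    x, y, w, h = (int(v) for v in box)
    H, W = frame.shape[:2]
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + w, W), min(y + h, H)
    img = np.asarray(frame[y0:y1, x0:x1], dtype=float) / 255.0
    if img.shape[0] < patch or img.shape[1] < patch:
        return np.empty((0, 5))
    hsv = rgb2hsv(img)
    gray = img.mean(axis=2)
    gy, gx = np.gradient(gray)
    feats = []
    for r in range(0, img.shape[0] - patch + 1, stride):
        for c in range(0, img.shape[1] - patch + 1, stride):
            hs = hsv[r : r + patch, c : c + patch]
            feats.append(
                [
                    hs[..., 0].mean(),
                    hs[..., 1].mean(),
                    hs[..., 2].mean(),
                    np.abs(gx[r : r + patch, c : c + patch]).mean(),
                    np.abs(gy[r : r + patch, c : c + patch]).mean(),
                ]
            )
    return np.asarray(feats)


@dataclass
class BovwModel:
    vocabulary: np.ndarray  # (k, d) cluster centers
    histograms: Dict[int, np.ndarray]  # identity -> normalized word histogram
    k: int

    def quantize(self, feats: np.ndarray) -> np.ndarray:
        d = ((feats[:, None, :] - self.vocabulary[None, :, :]) ** 2).sum(axis=2)
        words = d.argmin(axis=1)
        hist = np.bincount(words, minlength=self.k).astype(float)
        s = hist.sum()
        return hist / s if s > 0 else hist

    def classify(self, feats: np.ndarray) -> Tuple[Optional[int], Dict[int, float]]:
        """Histogram-cosine argmax identity for a query patch set."""
        if len(feats) == 0 or not self.histograms:
            return None, {}
        q = self.quantize(feats)
        sims = {}
        for ident, hh in self.histograms.items():
            na, nb = np.linalg.norm(q), np.linalg.norm(hh)
            sims[ident] = float(q @ hh / (na * nb)) if na > 0 and nb > 0 else 0.0
        best = max(sorted(sims), key=lambda i: sims[i])
        return best, sims


def bovw_fit(
    patches_by_identity: Dict[int, np.ndarray], k: int = 32, seed: int = 0
) -> BovwModel:
    """Fit a k-means vocabulary on pooled window patches.

    ``patches_by_identity`` maps each identity to its stacked patch
    features from the previous ten frames.  Raises when fewer than ``k``
    patch descriptors are available in total (caller should shrink k).
    """
    if k < 2:
        raise ValueError("vocabulary size k must be >= 2")
    pools = [p for p in patches_by_identity.values() if len(p)]
    if not pools:
        raise ValueError("no patch descriptors to train on")
    allp = np.vstack(pools)
    if len(allp) < k:
        raise ValueError(
            f"only {len(allp)} patch descriptors for k={k}; shrink k to at most {len(allp)}"
        )
    km = KMeans(n_clusters=k, n_init=4, max_iter=100, random_state=seed)
    km.fit(allp)
    model = BovwModel(km.cluster_centers_, {}, k)
    for ident, p in patches_by_identity.items():
        if len(p):
            model.histograms[ident] = model.quantize(p)
    return model


# ---------------------------------------------------------------------------
# cascade


@dataclass
class ReIDEvent:
    """A moment the cascade must decide an identity.

    ``incumbent`` is the track's current identity label (None for a newly
    confirmed track); ``query`` its appearance descriptor now;
    ``window_patches`` maps identities to patch features gathered from the
    previous ten frames; ``query_patches`` are the query's own local
    patches for the online stage.
    """

    incumbent: Optional[int]
    query: np.ndarray
    query_patches: np.ndarray
    window_patches: Dict[int, np.ndarray]


@dataclass
class ReIDDecision:
    identity: int
    stage: str  # "offline" | "online" | "incumbent"
    ranking: List[Tuple[int, float]]


def cascade_reid(
    event: ReIDEvent,
    gallery: Gallery,
    k: int = 32,
    seed: int = 0,
    live_identities: Optional[Dict[int, float]] = None,
) -> ReIDDecision:
    """Two-stage identity decision.

    Stage 1 ranks the gallery; if the proposal matches the incumbent (or
    the ranking is an appearance tie within ``TIE_EPSILON`` and an
    incumbent exists — motion continuity wins when appearance is
    uninformative) the decision is made there.  Otherwise stage 2 fits a
    BOVW model on the ten-frame window and votes; the vote is accepted
    only when it names one of the two candidates.  ``live_identities``
    maps identities already carried by other confirmed tracks to their
    own match distances; the decision avoids duplicating those unless the
    query is strictly closer (the other track then needs relabelling,
    which the caller handles).
    """
    ranking = gallery_rank(event.query, gallery)
    proposal, best_d = ranking[0]
    # appearance tie -> retain the incumbent (motion continuity)
    if (
        event.incumbent is not None
        and len(ranking) > 1
        and abs(ranking[1][1] - best_d) <= TIE_EPSILON
        and any(i == event.incumbent for i, _ in ranking)
    ):
        return ReIDDecision(event.incumbent, "incumbent", ranking)
    if event.incumbent is None or proposal == event.incumbent:
        decision = proposal
        stage = "offline"
    else:
        # offline predicts an identity change: online verification
        decision, stage = _online_verdict(event, ranking, k, seed)
    if live_identities and decision in live_identities:
        if best_d >= live_identities[decision] - 1e-12:
            for ident, d in ranking:
                if ident not in live_identities:
                    return ReIDDecision(ident, stage, ranking)
            # every identity taken: keep incumbent if any
            if event.incumbent is not None:
                return ReIDDecision(event.incumbent, "incumbent", ranking)
    return ReIDDecision(decision, stage, ranking)


def _online_verdict(event: ReIDEvent, ranking, k: int, seed: int):
    candidates = {ranking[0][0], event.incumbent}
    usable = {i: p for i, p in event.window_patches.items() if len(p)}
    total = sum(len(p) for p in usable.values())
    if total < 2 or len(event.query_patches) == 0:
        return ranking[0][0], "offline"  # degenerate window: stage-1 decision
    k_eff = min(k, total)
    try:
        model = bovw_fit(usable, k=max(2, k_eff), seed=seed)
    except ValueError:
        return ranking[0][0], "offline"
    vote, _ = model.classify(event.query_patches)
    if vote in candidates:
        return vote, "online"
    return event.incumbent, "incumbent"


# ---------------------------------------------------------------------------
# evaluation


def cmc_accuracy(
    rank_lists: Sequence[Sequence[int]], true_identities: Sequence[int], k: int = 1
) -> float:
    """Cumulative matching characteristic at rank ``k``.

    The fraction of queries whose true identity appears within the top-k
    entries of its ranked identity list; rank-1 is the headline number.
    """
    if len(rank_lists) != len(true_identities):
        raise ValueError("rank lists and identities must have equal length")
    if len(rank_lists) == 0:
        raise ValueError("no queries")
    hits = sum(
        1 for rl, t in zip(rank_lists, true_identities) if t in list(rl)[:k]
    )
    return hits / len(rank_lists)
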