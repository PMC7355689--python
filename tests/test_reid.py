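"""Appearance descriptors, gallery ranking, BOVW and the cascade."""

import numpy as np
import pytest

from surgtrack import reid
from surgtrack.reid import (
    BovwModel,
    Gallery,
    ReIDEvent,
    bovw_fit,
    cascade_reid,
    cmc_accuracy,
    cosine_distance,
    extract_descriptor,
    gallery_rank,
    patch_features,
)


def uniform_patch(color, size=48):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[:] = color
    # mild texture so gradients are defined
    img[::4] = np.clip(np.array(color) * 0.8, 0, 255).astype(np.uint8)
    return img


FULL = lambda img: (0, 0, img.shape[1], img.shape[0])


# -- descriptor ------------------------------------------------------------


def test_descriptor_deterministic_and_unit_norm():
    img = uniform_patch((200, 30, 30))
    d1 = extract_descriptor(img, FULL(img))
    d2 = extract_descriptor(img, FULL(img))
    np.testing.assert_array_equal(d1, d2)
    assert np.linalg.norm(d1) == pytest.approx(1.0, abs=1e-9)


def test_descriptor_separates_red_from_blue():
    red = extract_descriptor(uniform_patch((220, 20, 20)), FULL(uniform_patch((220, 20, 20))))
    blue = extract_descriptor(uniform_patch((20, 20, 220)), FULL(uniform_patch((20, 20, 220))))
    assert cosine_distance(red, blue) > 0.5


def test_descriptor_rejects_degenerate_box():
    img = uniform_patch((100, 100, 100))
    with pytest.raises(ValueError):
        extract_descriptor(img, (0, 0, 1, 1))


def test_descriptor_mask_weighting_focuses_on_foreground():
    """With mask weighting, a thin stripe dominates its busy background."""
    rng = np.random.default_rng(0)
    bg = rng.integers(0, 255, (48, 48, 3)).astype(np.uint8)
    a, b = bg.copy(), bg.copy()
    a[:, 20:24] = (220, 20, 20)
    b[:, 20:24] = (20, 220, 20)
    mask = np.zeros((48, 48), bool)
    mask[:, 20:24] = True
    plain = cosine_distance(
        extract_descriptor(a, FULL(a)), extract_descriptor(b, FULL(b))
    )
    masked = cosine_distance(
        extract_descriptor(a, FULL(a), mask), extract_descriptor(b, FULL(b), mask)
    )
    assert masked > plain


# -- gallery ---------------------------------------------------------------


def _three_color_gallery():
    g = Gallery(capacity=5)
    colors = {0: (220, 30, 30), 1: (30, 220, 30), 2: (30, 30, 220)}
    for ident, col in colors.items():
        img = uniform_patch(col)
        g.add(ident, extract_descriptor(img, FULL(img)), 0)
    return g, colors


def test_gallery_rank_exact_exemplar_is_rank_one():
    g, colors = _three_color_gallery()
    img = uniform_patch(colors[1])
    ranked = gallery_rank(extract_descriptor(img, FULL(img)), g)
    assert ranked[0][0] == 1
    assert ranked[0][1] == pytest.approx(0.0, abs=1e-9)


def test_gallery_single_identity_always_rank_one():
    g = Gallery()
    img = uniform_patch((10, 200, 10))
    g.add(2, extract_descriptor(img, FULL(img)))
    q = extract_descriptor(uniform_patch((200, 10, 10)), FULL(uniform_patch((200, 10, 10))))
    assert gallery_rank(q, g)[0][0] == 2


def test_gallery_rank_accuracy_on_noisy_queries():
    g, colors = _three_color_gallery()
    rng = np.random.default_rng(1)
    hits = 0
    for k in range(30):
        ident = k % 3
        img = uniform_patch(colors[ident]).astype(float)
        img = np.clip(img + rng.normal(0, 12, img.shape), 0, 255).astype(np.uint8)
        ranked = gallery_rank(extract_descriptor(img, FULL(img)), g)
        hits += ranked[0][0] == ident
    assert hits == 30


def test_gallery_capacity_fifo_and_identity_cap():
    g = Gallery(capacity=3)
    img = uniform_patch((100, 100, 100))
    d = extract_descriptor(img, FULL(img))
    for f in range(5):
        g.add(0, d, f)
    assert [f for f, _ in g._store[0]] == [2, 3, 4]
    g.add(1, d)
    g.add(2, d)
    with pytest.raises(ValueError):
        g.add(3, d)


def test_gallery_rank_empty_gallery_errors():
    with pytest.raises(ValueError):
        gallery_rank(np.ones(reid.DESCRIPTOR_DIM), Gallery())


def test_gallery_json_roundtrip():
    g, _ = _three_color_gallery()
    g2 = Gallery.from_json(g.to_json())
    assert g2.identities == g.identities
    for i in g.identities:
        assert g2.min_distance(i, g._store[i][0][1]) == pytest.approx(0.0, abs=1e-12)


# -- BOVW ------------------------------------------------------------------


def test_bovw_vocabulary_matches_direct_kmeans_on_toy_clusters():
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.05, (40, 5))
    b = rng.normal(1.0, 0.05, (40, 5))
    model = bovw_fit({0: a, 1: b}, k=2, seed=3)
    direct = KMeans(n_clusters=2, n_init=4, max_iter=100, random_state=3).fit(
        np.vstack([a, b])
    )
    got = model.vocabulary[np.argsort(model.vocabulary[:, 0])]
    want = direct.cluster_centers_[np.argsort(direct.cluster_centers_[:, 0])]
    np.testing.assert_allclose(got, want, atol=1e-9)
    # each centre lies inside one cluster's bounding range
    assert got[0][0] < 0.5 < got[1][0]


def test_bovw_histograms_normalized_and_deterministic():
    rng = np.random.default_rng(2)
    patches = {i: rng.random((30, 5)) for i in range(3)}
    m1 = bovw_fit(patches, k=4, seed=9)
    m2 = bovw_fit(patches, k=4, seed=9)
    for i in range(3):
        assert m1.histograms[i].sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(m1.histograms[i], m2.histograms[i])
    np.testing.assert_array_equal(m1.vocabulary, m2.vocabulary)


def test_bovw_requires_enough_patches():
    with pytest.raises(ValueError, match="shrink k"):
        bovw_fit({0: np.random.default_rng(0).random((3, 5))}, k=8)
    with pytest.raises(ValueError):
        bovw_fit({0: np.empty((0, 5))}, k=2)


# -- cascade ---------------------------------------------------------------


def _window_patches(colors, rng):
    out = {}
    for ident, col in colors.items():
        frames = []
        for _ in range(10):
            img = uniform_patch(col).astype(float)
            img = np.clip(img + rng.normal(0, 6, img.shape), 0, 255).astype(np.uint8)
            frames.append(patch_features(img, FULL(img)))
        out[ident] = np.vstack(frames)
    return out


def test_cascade_restores_identity_on_reentry():
    g, colors = _three_color_gallery()
    rng = np.random.default_rng(4)
    img = uniform_patch(colors[2]).astype(float)
    img = np.clip(img + rng.normal(0, 10, img.shape), 0, 255).astype(np.uint8)
    event = ReIDEvent(
        incumbent=None,
        query=extract_descriptor(img, FULL(img)),
        query_patches=patch_features(img, FULL(img)),
        window_patches=_window_patches(colors, rng),
    )
    assert cascade_reid(event, g, k=8, seed=0).identity == 2


def test_cascade_tie_retains_incumbent():
    """Identical appearances: motion continuity (the incumbent) wins."""
    g = Gallery()
    img = uniform_patch((128, 128, 128))
    d = extract_descriptor(img, FULL(img))
    g.add(0, d)
    g.add(1, d)
    event = ReIDEvent(
        incumbent=1,
        query=d,
        query_patches=patch_features(img, FULL(img)),
        window_patches={},
    )
    decision = cascade_reid(event, g, k=4, seed=0)
    assert decision.identity == 1
    assert decision.stage == "incumbent"


def test_cascade_never_duplicates_live_identity():
    g, colors = _three_color_gallery()
    img = uniform_patch(colors[0])
    event = ReIDEvent(
        incumbent=None,
        query=extract_descriptor(img, FULL(img)),
        query_patches=patch_features(img, FULL(img)),
        window_patches={},
    )
    # identity 0 already carried by another live track at distance 0
    decision = cascade_reid(event, g, live_identities={0: 0.0})
    assert decision.identity != 0


def test_cascade_corrects_offline_error_via_online_stage():
    """A wrong offline proposal is overruled when BOVW backs the incumbent."""
    g, colors = _three_color_gallery()
    rng = np.random.default_rng(0)
    # query is identity 1, but poison the gallery so offline ranks 0 first
    img = uniform_patch(colors[1])
    d1 = extract_descriptor(img, FULL(img))
    g._store[0].insert(0, (99, d1))
    event = ReIDEvent(
        incumbent=1,
        query=d1,
        query_patches=patch_features(img, FULL(img)),
        window_patches=_window_patches(colors, rng),
    )
    decision = cascade_reid(event, g, k=8, seed=0)
    assert decision.identity == 1


# -- CMC -------------------------------------------------------------------


def test_cmc_worked_example():
    ranks = [[0, 1, 2], [1, 0, 2], [2, 1, 0]]
    truth = [0, 0, 0]
    assert cmc_accuracy(ranks, truth, 1) == pytest.approx(1 / 3)
    assert cmc_accuracy(ranks, truth, 2) == pytest.approx(2 / 3)
    assert cmc_accuracy(ranks, truth, 3) == pytest.approx(1.0)


def test_cmc_limits_and_monotonicity():
    ranks = [[0, 1], [1, 0], [0, 1]]
    truth = [0, 1, 0]
    assert cmc_accuracy(ranks, truth, 1) == 1.0
    assert cmc_accuracy([[1, 0]] * 3, [0] * 3, 1) == 0.0
    accs = [cmc_accuracy([[2, 1, 0], [0, 2, 1]], [0, 1], k) for k in (1, 2, 3)]
    assert accs == sorted(accs)


def test_cmc_errors():
    with pytest.raises(ValueError):
        cmc_accuracy([], [])
    with pytest.raises(ValueError):
        cmc_accuracy([[0]], [0, 1])
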