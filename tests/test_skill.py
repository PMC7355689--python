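"""SMOTE, skill classifiers, cross-validated tuning and importance."""

import numpy as np
import pandas as pd
import pytest

from surgtrack.skill import (
    CLASS_ORDER,
    ModelSpec,
    SkillClassifier,
    confusion_matrix_table,
    feature_importance,
    load_model,
    predict_skill,
    save_model,
    smote,
    train_skill_model,
)


def blobs(n_per_class, sep=6.0, d=4, seed=0):
    """Well-separated 3-class Gaussian clouds."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, cls in enumerate(CLASS_ORDER):
        mu = np.zeros(d)
        mu[k % d] = sep * (k + 1)
        X.append(rng.normal(mu, 1.0, (n_per_class, d)))
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


# -- SMOTE -----------------------------------------------------------------


def test_smote_balanced_input_unchanged():
    X, y = blobs(10)
    Xb, yb = smote(X, y, seed=1)
    np.testing.assert_array_equal(Xb, X)
    np.testing.assert_array_equal(yb, y)


def _on_some_segment(s, Xc, k=5):
    """Is s on a segment between a class point and one of its k-NN?"""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
    _, idx = nn.kneighbors(Xc)
    for i in range(len(Xc)):
        for j in idx[i][1:]:
            a, b = Xc[i], Xc[j]
            ab = b - a
            denom = ab @ ab
            if denom == 0:
                continue
            u = (s - a) @ ab / denom
            if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(a + u * ab - s) < 1e-9:
                return True
    return False


def test_smote_balances_and_interpolates_within_class():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (10, 3))])
    y = np.array(["a"] * 20 + ["b"] * 10)
    Xb, yb = smote(X, y, k_neighbors=5, seed=4)
    assert (yb == "a").sum() == 20 and (yb == "b").sum() == 20
    np.testing.assert_array_equal(Xb[:30], X)  # originals untouched
    minority = X[y == "b"]
    for s in Xb[30:]:
        assert _on_some_segment(s, minority)


def test_smote_deterministic_for_fixed_seed():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(5, 1, (5, 2))])
    y = np.array([0] * 12 + [1] * 5)
    a = smote(X, y, seed=9)
    b = smote(X, y, seed=9)
    np.testing.assert_array_equal(a[0], b[0])


def test_smote_shrinks_k_with_warning_and_rejects_singletons():
    X = np.vstack([np.random.default_rng(0).normal(0, 1, (10, 2)), [[5, 5]], [[5.5, 5]]])
    y = np.array([0] * 10 + [1] * 2)
    with pytest.warns(UserWarning, match="shrinking"):
        smote(X, y, k_neighbors=5, seed=0)
    y1 = np.array([0] * 11 + [1])
    with pytest.raises(ValueError, match="single member"):
        smote(X, y1, k_neighbors=5, seed=0)


# -- classifiers -----------------------------------------------------------


@pytest.mark.parametrize("kind", ["linear", "svm_rbf", "random_forest"])
def test_separable_cohort_reaches_perfect_cv_accuracy(kind):
    X, y = blobs(10, sep=8.0)
    clf, report = train_skill_model(
        X, y, ModelSpec(kind=kind, grid=None if kind != "random_forest" else
                        [{"n_estimators": 50, "max_depth": None}], seed=0)
    )
    assert report["cv_accuracy"] == 1.0
    assert clf.score(X, y) == 1.0


def test_permuted_labels_score_at_chance():
    X, y = blobs(12, sep=8.0, seed=5)
    rng = np.random.default_rng(0)
    yp = rng.permutation(y)
    _, report = train_skill_model(
        X, yp, ModelSpec(kind="random_forest", grid=[{"n_estimators": 100, "max_depth": None}])
    )
    se = np.sqrt((1 / 3) * (2 / 3) / len(y))
    assert abs(report["cv_accuracy"] - 1 / 3) < 4 * se


def test_forest_interpolates_training_data():
    X, y = blobs(8, sep=2.0, seed=2)  # overlapping classes
    clf = SkillClassifier(
        "random_forest", grid=[{"n_estimators": 100, "max_depth": None}], cv_folds=2
    ).fit(X, y)
    assert clf.score(X, y) == 1.0


def test_predict_single_row_and_confusion_layout():
    X, y = blobs(10, sep=8.0)
    clf = SkillClassifier(
        "random_forest", grid=[{"n_estimators": 50, "max_depth": None}]
    ).fit(X, y)
    labels, proba = predict_skill(clf, X[0])
    assert len(labels) == 1 and proba.shape == (1, 3)
    Xt, yt = blobs(4, sep=8.0, seed=9)
    cm = confusion_matrix_table(yt, clf.predict(Xt))
    assert list(cm.index) == list(CLASS_ORDER)
    assert (cm.sum(axis=1) == 4).all()


def test_fit_input_validation():
    X, y = blobs(10)
    with pytest.raises(ValueError):
        SkillClassifier().fit(X, np.array(["a"] * len(X)))  # one class
    with pytest.raises(ValueError):
        SkillClassifier(cv_folds=5).fit(X[:6], y[:6])  # too few per class
    clf = SkillClassifier("random_forest", grid=[{"n_estimators": 20, "max_depth": None}]).fit(X, y)
    with pytest.raises(ValueError):
        clf.predict(np.zeros((2, 17)))  # dimension mismatch


def test_tuning_is_no_harm():
    """The selected config's CV accuracy >= the first grid entry's."""
    X, y = blobs(10, sep=2.5, seed=7)
    clf = SkillClassifier(
        "svm_rbf", grid=[{"C": 0.001}, {"C": 1.0}, {"C": 10.0}], random_state=0
    ).fit(X, y)
    accs = [r["mean_accuracy"] for r in clf.cv_report_["results"]]
    assert clf.cv_report_["cv_accuracy"] == max(accs)
    assert clf.cv_report_["cv_accuracy"] >= accs[0]


# -- importance ------------------------------------------------------------


def test_importance_normalized_and_requires_forest():
    X, y = blobs(10, sep=8.0)
    clf = SkillClassifier(
        "random_forest", grid=[{"n_estimators": 100, "max_depth": None}]
    ).fit(X, y)
    imp = feature_importance(clf, [f"f{i}" for i in range(X.shape[1])])
    assert sum(v for _, v in imp) == pytest.approx(1.0, abs=1e-9)
    assert sorted((v for _, v in imp), reverse=True) == [v for _, v in imp]
    lin = SkillClassifier("linear").fit(X, y)
    with pytest.raises(ValueError):
        feature_importance(lin, ["a", "b", "c", "d"])


def test_pure_noise_feature_ranks_last():
    ranks = []
    for seed in range(20):
        # d=3 with one axis per class: every base feature is informative
        X, y = blobs(10, sep=8.0, d=3, seed=seed)
        rng = np.random.default_rng(seed + 100)
        Xn = np.hstack([X, rng.normal(0, 1, (len(X), 1))])
        clf = SkillClassifier(
            "random_forest",
            grid=[{"n_estimators": 50, "max_depth": None}],
            random_state=seed,
        ).fit(Xn, y)
        imp = feature_importance(clf, [f"f{i}" for i in range(4)])
        ranks.append([name for name, _ in imp].index("f3"))
    assert np.median(ranks) == 3  # the appended noise column ranks last


def test_model_archive_roundtrip(tmp_path):
    from surgtrack.metrics import METRIC_NAMES, MetricNormalizer

    rng = np.random.default_rng(0)
    table = pd.DataFrame(np.abs(rng.normal(5, 2, (30, 9))), columns=METRIC_NAMES)
    norm = MetricNormalizer().fit(table)
    X = norm.transform(table).to_numpy()
    y = np.array((["novice"] * 10 + ["skilled"] * 10 + ["expert"] * 10))
    clf = SkillClassifier(
        "random_forest", grid=[{"n_estimators": 20, "max_depth": None}]
    ).fit(X, y)
    path = tmp_path / "model.bin"
    save_model(clf, norm, path)
    clf2, norm2 = load_model(path)
    np.testing.assert_array_equal(clf2.predict(X), clf.predict(X))
    np.testing.assert_allclose(
        norm2.transform(table).to_numpy(), X, atol=1e-12
    )
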