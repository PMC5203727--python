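"""EDDA discriminant analysis: parameter recovery, Bayes-rate oracle,
split construction and evaluation."""

import numpy as np
import pandas as pd
import pytest

from tremorkit import (
    edda_fit,
    edda_predict,
    evaluate_splits,
    make_splits,
)
from tremorkit.classify import canonical_classes, success_table_row


def _two_gaussians(rng, n, mu0, mu1, cov0, cov1):
    X = np.vstack(
        [
            rng.multivariate_normal(mu0, cov0, size=n),
            rng.multivariate_normal(mu1, cov1, size=n),
        ]
    )
    y = np.repeat(["a", "b"], n)
    return X, y


MU0, MU1 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
COV0 = np.array([[1.0, 0.3], [0.3, 0.5]])
COV1 = np.array([[0.6, -0.2], [-0.2, 1.2]])


def test_parameter_recovery_at_large_n(rng):
    X, y = _two_gaussians(rng, 2000, MU0, MU1, COV0, COV1)
    model = edda_fit(X, y, constraint="full-varying")
    np.testing.assert_allclose(model.means[0], MU0, atol=0.1)
    np.testing.assert_allclose(model.means[1], MU1, atol=0.1)
    assert np.linalg.norm(model.covariances[0] - COV0) < 0.1
    assert np.linalg.norm(model.covariances[1] - COV1) < 0.1


def _bayes_rate(mu0, mu1, cov0, cov1, half=12.0, n_grid=801):
    """Bayes-optimal accuracy of the equal-prior two-Gaussian problem by
    numerical integration on a grid."""
    from scipy.stats import multivariate_normal

    xs = np.linspace(-half, half, n_grid)
    dx = xs[1] - xs[0]
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    p0 = multivariate_normal(mu0, cov0).pdf(pts)
    p1 = multivariate_normal(mu1, cov1).pdf(pts)
    return 0.5 * np.sum(np.maximum(p0, p1)) * dx * dx


def test_prediction_accuracy_approaches_bayes_rate(rng):
    X, y = _two_gaussians(rng, 2000, MU0, MU1, COV0, COV1)
    model = edda_fit(X, y, constraint="full-varying")
    Xt, yt = _two_gaussians(np.random.default_rng(99), 5000, MU0, MU1, COV0, COV1)
    pred, _ = edda_predict(model, Xt)
    acc = np.mean(pred == yt)
    bayes = _bayes_rate(MU0, MU1, COV0, COV1)
    assert abs(acc - bayes) < 0.01


def test_separable_classes_reach_perfect_cv(rng):
    X = np.vstack(
        [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 100.0]
    )
    y = np.repeat(["a", "b"], 30)
    model = edda_fit(X, y, constraint="auto", cv_seed=0)
    assert model.selection_score == 0.0
    pred, post = edda_predict(model, X)
    assert np.all(pred == y)


def test_point_at_class_mean_gets_high_posterior(rng):
    X = np.vstack(
        [rng.standard_normal((50, 2)), rng.standard_normal((50, 2)) + 50.0]
    )
    y = np.repeat(["a", "b"], 50)
    model = edda_fit(X, y, constraint="full-varying")
    pred, post = edda_predict(model, model.means[0])
    assert pred[0] == "a"
    assert post[0, 0] > 0.99


def test_equidistant_point_has_symmetric_posterior():
    rng = np.random.default_rng(0)
    shift = np.array([4.0, 0.0])
    base = rng.standard_normal((200, 2))
    base -= base.mean(axis=0)  # exact mirror symmetry of the two classes
    X = np.vstack([base - shift, base + shift])
    y = np.repeat(["a", "b"], 200)
    model = edda_fit(X, y, constraint="spherical-equal")
    _, post = edda_predict(model, np.array([[0.0, 3.0]]))
    assert post[0, 0] == pytest.approx(0.5, abs=1e-9)


def test_spherical_truth_gains_nothing_from_full_model(rng):
    """With isotropic equal-covariance classes the richest constraint
    cannot beat the matched simple one by more than chance."""
    n = 1500
    X = np.vstack(
        [rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + [2.0, 0.0]]
    )
    y = np.repeat(["a", "b"], n)
    Xt = np.vstack(
        [
            np.random.default_rng(7).standard_normal((n, 2)),
            np.random.default_rng(8).standard_normal((n, 2)) + [2.0, 0.0],
        ]
    )
    yt = np.repeat(["a", "b"], n)
    accs = {}
    for constraint in ("spherical-equal", "full-varying"):
        model = edda_fit(X, y, constraint=constraint)
        pred, _ = edda_predict(model, Xt)
        accs[constraint] = np.mean(pred == yt)
    assert abs(accs["spherical-equal"] - accs["full-varying"]) < 0.01


def test_auto_ties_break_toward_fewer_parameters(rng):
    X = np.vstack(
        [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 100.0]
    )
    y = np.repeat(["a", "b"], 30)
    model = edda_fit(X, y, constraint="auto", cv_seed=1)
    # perfectly separable: every constraint scores 0, simplest must win
    assert model.chosen_constraint == "spherical-equal"


def test_degenerate_class_rescued_or_rejected():
    X = np.vstack([np.zeros((5, 2)), np.random.default_rng(0).standard_normal((5, 2)) + 5])
    y = np.repeat(["a", "b"], 5)
    model = edda_fit(X, y, constraint="full-varying")  # floor rescues SPD-ness
    assert np.all(np.linalg.eigvalsh(model.covariances[0]) > 0)


# ---------------------------------------------------------------------------
# splits and evaluation
# ---------------------------------------------------------------------------

SUBJECTS = {
    "S_H": [f"S_H_{i:02d}" for i in range(1, 11)],
    "S_PD": [f"S_PD_{i:02d}" for i in range(1, 17)],
    "S_DBS": [f"S_DBS_{i:02d}" for i in range(1, 13)],
}


def test_splits_draw_five_per_group_without_overlap():
    splits = make_splits(SUBJECTS, n_splits=50, per_group=5, seed=0)
    assert len(splits) == 50
    for s in splits:
        train = [x for subs in s.train_subjects.values() for x in subs]
        test = [x for subs in s.test_subjects.values() for x in subs]
        assert len(train) == len(test) == 15
        assert not set(train) & set(test)
        for g in SUBJECTS:
            assert len(s.train_subjects[g]) == len(s.test_subjects[g]) == 5


def test_distinct_seed_derived_splits():
    splits = make_splits(SUBJECTS, n_splits=200, per_group=5, seed=1)
    signatures = {
        (tuple(sorted(sum(s.train_subjects.values(), []))),
         tuple(sorted(sum(s.test_subjects.values(), []))))
        for s in splits
    }
    assert len(signatures) > 190  # essentially all distinct


def test_group_too_small_for_split_rejected():
    bad = dict(SUBJECTS)
    bad["S_H"] = bad["S_H"][:9]
    with pytest.raises(ValueError, match="needs >= 10"):
        make_splits(bad, n_splits=10, per_group=5, seed=0)


def _synthetic_projection(rng, separation):
    """2-D observations for the standard cohort layout: 5 windows per
    subject, subject random effects, group centroids `separation` apart."""
    centroids = {
        "S_H": np.array([0.0, 0.0]),
        "S_PD": np.array([separation, 0.0]),
        "S_DBS": np.array([separation / 2, separation * 0.8]),
    }
    rows, coords = [], []
    for g, subs in SUBJECTS.items():
        for s in subs:
            subject_centre = centroids[g] + rng.standard_normal(2) * 0.5
            for trial in range(1, 6):
                rows.append({"subject_id": s, "group": g, "trial": trial})
                coords.append(subject_centre + rng.standard_normal(2) * 0.3)
    return np.array(coords), pd.DataFrame(rows)


def test_null_projection_classifies_at_chance(rng):
    coords, meta = _synthetic_projection(rng, separation=0.0)
    splits = make_splits(SUBJECTS, n_splits=150, per_group=5, seed=3)
    results = evaluate_splits(coords, meta, splits, seed=3)
    row = success_table_row(results, "test", canonical_classes(meta["group"]))
    assert row["MeanTP"] == pytest.approx(1 / 3, abs=0.05)


def test_separated_projection_classifies_well(rng):
    coords, meta = _synthetic_projection(rng, separation=6.0)
    splits = make_splits(SUBJECTS, n_splits=60, per_group=5, seed=4)
    results = evaluate_splits(coords, meta, splits, seed=4)
    row = success_table_row(results, "test", canonical_classes(meta["group"]))
    assert row["MeanTP"] > 0.9


def test_confusion_rows_are_stochastic(rng):
    coords, meta = _synthetic_projection(rng, separation=2.0)
    splits = make_splits(SUBJECTS, n_splits=25, per_group=5, seed=5)
    results = evaluate_splits(coords, meta, splits, seed=5)
    for r in results:
        np.testing.assert_allclose(r.confusion_train.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(r.confusion_test.sum(axis=1), 1.0, atol=1e-9)


def test_classification_rate_exceeds_test_rate_on_moderate_effect(rng):
    """Within-training CV rates are optimistic relative to held-out
    subject rates when subject effects are present."""
    coords, meta = _synthetic_projection(rng, separation=1.5)
    splits = make_splits(SUBJECTS, n_splits=100, per_group=5, seed=6)
    results = evaluate_splits(coords, meta, splits, seed=6)
    classes = canonical_classes(meta["group"])
    train = success_table_row(results, "train", classes)["MeanTP"]
    test = success_table_row(results, "test", classes)["MeanTP"]
    assert train > test
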