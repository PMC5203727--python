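"""Gaussian eigen-decomposition discriminant analysis (EDDA) and the
subject-wise resampling evaluation.

EDDA fits one Gaussian per class under a named covariance constraint.
In two dimensions the canonical covariance family reduces to six
parameterisations:

    spherical-equal    lambda I, shared             (1 parameter)
    spherical-varying  lambda_g I per class         (G)
    diagonal-equal     diag(a, b), shared           (2)
    diagonal-varying   diag(a_g, b_g) per class     (2G)
    full-equal         Sigma, shared (LDA geometry) (3)
    full-varying       Sigma_g per class (QDA)      (3G)

"auto" picks the constraint with the lowest 10-fold cross-validated
error on the training data, ties broken toward fewer parameters.
Prediction is the Bayes rule on the fitted class densities with
empirical priors.

Evaluation mirrors the resampling protocol: each of many splits draws
five training and five distinct test subjects per group (all task
windows of a subject travel together), reports 10-fold cross-validated
rates within the training data ("classification set") and held-out
rates on the test subjects, and aggregates the row-normalized 3x3
confusion matrices over splits with MeanTP/StdTP summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: reporting / tie-break order of the experimental groups
GROUP_ORDER = ("S_H", "S_PD", "S_DBS")


def canonical_classes(labels) -> list[str]:
    """Class labels in reporting order (S_H, S_PD, S_DBS first)."""
    present = set(str(l) for l in labels)
    ordered = [g for g in GROUP_ORDER if g in present]
    ordered += sorted(present - set(ordered))
    return ordered


#: constraints ordered by parameter count (tie-break order for "auto")
CONSTRAINTS: tuple[str, ...] = (
    "spherical-equal",
    "diagonal-equal",
    "full-equal",
    "spherical-varying",
    "diagonal-varying",
    "full-varying",
)


def _constraint_n_params(name: str, n_classes: int) -> int:
    per = {"spherical": 1, "diagonal": 2, "full": 3}[name.split("-")[0]]
    return per if name.endswith("equal") else per * n_classes


@dataclass
class EddaModel:
    classes: list[str]
    means: np.ndarray  # (G, 2)
    covariances: np.ndarray  # (G, 2, 2), symmetric positive-definite
    priors: np.ndarray  # (G,), sums to 1
    chosen_constraint: str
    selection_score: float  # CV error of the chosen constraint (auto) or training error


_COV_FLOOR = 1e-8


def _floor_spd(cov: np.ndarray) -> np.ndarray:
    """Clamp covariance eigenvalues to a floor relative to the trace."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    floor = _COV_FLOOR * max(np.trace(cov), _COV_FLOOR)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _fit_constrained(
    X: np.ndarray, y: np.ndarray, classes: list[str], constraint: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ML means / covariances / priors under one covariance constraint."""
    n, d = X.shape
    G = len(classes)
    means = np.empty((G, d))
    raw = np.empty((G, d, d))
    priors = np.empty(G)
    for g, cls in enumerate(classes):
        pts = X[y == cls]
        if len(pts) < 3:
            raise ValueError(f"class {cls} has fewer than 3 training points")
        means[g] = pts.mean(axis=0)
        centred = pts - means[g]
        raw[g] = centred.T @ centred / len(pts)  # ML (1/n) estimate
        priors[g] = len(pts) / n

    shape, pooling = constraint.split("-")
    if pooling == "equal":
        pooled = np.einsum("g,gij->ij", priors, raw)
        raw = np.broadcast_to(pooled, raw.shape).copy()
    if shape == "diagonal":
        raw = np.stack([np.diag(np.diag(c)) for c in raw])
    elif shape == "spherical":
        raw = np.stack([np.eye(d) * (np.trace(c) / d) for c in raw])
    covs = np.stack([_floor_spd(c) for c in raw])
    return means, covs, priors


def _log_density(model_means, model_covs, model_priors, X) -> np.ndarray:
    """Log prior x Gaussian density per class, shape (n, G)."""
    n = X.shape[0]
    G = model_means.shape[0]
    out = np.empty((n, G))
    for g in range(G):
        diff = X - model_means[g]
        cov = model_covs[g]
        chol = np.linalg.cholesky(cov)
        z = np.linalg.solve(chol, diff.T)
        maha = np.sum(z * z, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, g] = (
            np.log(model_priors[g])
            - 0.5 * (maha + logdet + X.shape[1] * np.log(2 * np.pi))
        )
    return out


def edda_predict(
    model: EddaModel, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bayes-rule prediction: labels and posterior matrix.

    Ties break toward the earlier class in the model's fixed class
    order (argmax on the log scores).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    logp = _log_density(model.means, model.covariances, model.priors, coords)
    shifted = logp - logp.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmax(logp, axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels, post


def _cv_error(
    X: np.ndarray,
    y: np.ndarray,
    classes: list[str],
    constraint: str,
    n_folds: int,
    rng: np.random.Generator,
) -> float:
    """Stratified K-fold cross-validated misclassification rate."""
    n = len(y)
    fold = np.empty(n, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    errors = 0
    counted = 0
    for f in range(n_folds):
        train = fold != f
        test = ~train
        if not test.any():
            continue
        # a fold whose training part lost a class cannot be scored fairly
        if any((y[train] == cls).sum() < 3 for cls in classes):
            continue
        means, covs, priors = _fit_constrained(X[train], y[train], classes, constraint)
        logp = _log_density(means, covs, priors, X[test])
        pred = np.asarray(classes, dtype=object)[np.argmax(logp, axis=1)]
        errors += int((pred != y[test]).sum())
        counted += int(test.sum())
    return errors / counted if counted else 1.0


def edda_fit(
    coords: np.ndarray,
    labels,
    constraint: str = "auto",
    n_folds: int = 10,
    cv_seed: int | None = 0,
) -> EddaModel:
    """Fit an EDDA model, selecting the covariance constraint by CV.

    With ``constraint="auto"`` the six parameterisations are compared
    by stratified ``n_folds``-fold cross-validated error on the
    training data; ties go to the model with fewer parameters.
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray([str(l) for l in labels], dtype=object)
    classes = canonical_classes(y)
    if len(classes) < 2:
        raise ValueError("classification requires at least 2 groups")
    for cls in classes:
        if (y == cls).sum() < 3:
            raise ValueError(f"class {cls} needs at least 3 observations")

    if constraint == "auto":
        rng = np.random.default_rng(cv_seed)
        best_name, best_err = None, np.inf
        for name in CONSTRAINTS:  # ordered by parameter count
            err = _cv_error(X, y, classes, name, n_folds, rng)
            if err < best_err - 1e-12:
                best_name, best_err = name, err
        constraint, score = best_name, best_err
    else:
        if constraint not in CONSTRAINTS:
            raise ValueError(f"unknown constraint {constraint!r}")
        score = np.nan

    means, covs, priors = _fit_constrained(X, y, classes, constraint)
    model = EddaModel(
        classes=classes,
        means=means,
        covariances=covs,
        priors=priors,
        chosen_constraint=constraint,
        selection_score=float(score) if np.isfinite(score) else float("nan"),
    )
    if not np.isfinite(score):
        pred, _ = edda_predict(model, X)
        model.selection_score = float(np.mean(pred != y))
    return model


# ---------------------------------------------------------------------------
# Subject-wise resampling evaluation
# ---------------------------------------------------------------------------


@dataclass
class Split:
    split_id: int
    train_subjects: dict[str, list[str]]
    test_subjects: dict[str, list[str]]


@dataclass
class SplitResult:
    split_id: int
    confusion_train: np.ndarray  # 3x3 row-normalized (CV within training)
    confusion_test: np.ndarray  # 3x3 row-normalized (held-out)
    chosen_constraint: str


def make_splits(
    subjects_by_group: dict[str, list[str]],
    n_splits: int = 1000,
    per_group: int = 5,
    seed: int | None = 0,
) -> list[Split]:
    """Random subject-wise train/test splits without repetition.

    Each split draws ``per_group`` training subjects from every group
    and ``per_group`` distinct test subjects from the remainder; every
    group therefore needs at least ``2 * per_group`` subjects.
    """
    for g, subs in subjects_by_group.items():
        if len(subs) < 2 * per_group:
            raise ValueError(
                f"group {g} has {len(subs)} subjects; needs >= {2 * per_group} "
                f"for {per_group} train + {per_group} test"
            )
    rng = np.random.default_rng(seed)
    splits = []
    for sid in range(n_splits):
        train: dict[str, list[str]] = {}
        test: dict[str, list[str]] = {}
        for g in sorted(subjects_by_group):
            subs = sorted(subjects_by_group[g])
            chosen = rng.choice(len(subs), size=2 * per_group, replace=False)
            train[g] = [subs[i] for i in chosen[:per_group]]
            test[g] = [subs[i] for i in chosen[per_group:]]
        splits.append(Split(split_id=sid, train_subjects=train, test_subjects=test))
    return splits


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               classes: list[str]) -> np.ndarray:
    """Row-normalized confusion matrix; empty rows stay all-zero."""
    G = len(classes)
    M = np.zeros((G, G))
    for i, ca in enumerate(classes):
        mask = y_true == ca
        if not mask.any():
            continue
        for j, cb in enumerate(classes):
            M[i, j] = np.mean(y_pred[mask] == cb)
    return M


def _cv_confusion(
    X, y, classes, constraint, n_folds, rng
) -> np.ndarray:
    """Row-normalized confusion from stratified K-fold CV predictions."""
    n = len(y)
    fold = np.empty(n, dtype=int)
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold[idx] = np.arange(len(idx)) % n_folds
    pred = np.empty(n, dtype=object)
    for f in range(n_folds):
        train = fold != f
        test = ~train
        if not test.any():
            continue
        means, covs, priors = _fit_constrained(X[train], y[train], classes, constraint)
        logp = _log_density(means, covs, priors, X[test])
        pred[test] = np.asarray(classes, dtype=object)[np.argmax(logp, axis=1)]
    return _confusion(y, pred, classes)


def evaluate_splits(
    coords: np.ndarray,
    meta: pd.DataFrame,
    splits: list[Split],
    constraint: str = "auto",
    n_folds: int = 10,
    seed: int | None = 0,
) -> list[SplitResult]:
    """Fit and score an EDDA model on every subject-wise split.

    Per split: constraint selection and the "classification set" rates
    come from ``n_folds``-fold CV within the training observations; the
    test rates come from predicting the held-out subjects' windows with
    the model refitted on all training observations. Splits whose
    training data lose a class are skipped.
    """
    coords = np.asarray(coords, dtype=float)
    subj = meta["subject_id"].to_numpy()
    grp = meta["group"].to_numpy(dtype=object)
    classes = canonical_classes(grp)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.generate_state(len(splits)) % (2**31)
    results: list[SplitResult] = []
    for split, child in zip(splits, child_seeds):
        train_set = {s for subs in split.train_subjects.values() for s in subs}
        test_set = {s for subs in split.test_subjects.values() for s in subs}
        assert not train_set & test_set, "subject leakage between halves"
        tr = np.isin(subj, sorted(train_set))
        te = np.isin(subj, sorted(test_set))
        ytr, yte = grp[tr], grp[te]
        if any((ytr == c).sum() < 3 for c in classes):
            continue  # degenerate training fold, logged by caller
        rng = np.random.default_rng(int(child))
        model = edda_fit(coords[tr], ytr, constraint=constraint,
                         n_folds=n_folds, cv_seed=int(child))
        conf_train = _cv_confusion(
            coords[tr], ytr, classes, model.chosen_constraint, n_folds, rng
        )
        pred, _ = edda_predict(model, coords[te])
        conf_test = _confusion(yte, pred, classes)
        results.append(
            SplitResult(
                split_id=split.split_id,
                confusion_train=conf_train,
                confusion_test=conf_test,
                chosen_constraint=model.chosen_constraint,
            )
        )
    return results


def success_table_row(
    results: list[SplitResult], which: str, classes: list[str]
) -> dict[str, float]:
    """Mean confusion cells over splits plus MeanTP/StdTP.

    ``which`` selects the classification-set ("train") or test-set
    ("test") confusion. Cell keys follow the actual(predicted) layout,
    e.g. ``S_H(S_PD)``; MeanTP/StdTP are the mean and SD of the three
    diagonal (true-positive) rates.
    """
    stack = np.stack(
        [
            r.confusion_train if which == "train" else r.confusion_test
            for r in results
        ]
    )
    mean_conf = stack.mean(axis=0)
    row: dict[str, float] = {}
    for i, ca in enumerate(classes):
        for j, cb in enumerate(classes):
            row[f"{ca}({cb})"] = float(mean_conf[i, j])
    diag = np.diag(mean_conf)
    row["MeanTP"] = float(diag.mean())
    row["StdTP"] = float(diag.std(ddof=1))
    return row
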