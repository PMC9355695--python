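"""Desk-scale scaffold of the stacked brain-age estimation design.

Chronological age is predicted from a subject-by-feature matrix in a
repeated k-fold cross-validation: within each repeat, every base learner
is fit on the training folds and produces out-of-fold predictions for
the held-out fold, so no subject's own data enters its base prediction.
The base predictions are then combined ("stacked") by least-squares
regression of chronological age on the pooled out-of-fold prediction
matrix, and stacked predictions are averaged across repeats. The brain
age gap is predicted minus chronological age; no bias adjustment is
applied here (the regression-dilution age bias is handled downstream by
including age and age^2 as covariates in association analyses).

Base learners are pluggable: anything with ``fit(X, y)`` and
``predict(X)`` (any scikit-learn regressor, optionally wrapped in a
pipeline with PCA reduction) qualifies. Defaults are two linear-family
learners; the full-scale design this scaffolds used relevance vector
machines and gradient boosting on 500 principal components of
voxel-based morphometry data, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "FoldAssignment",
    "StackedModel",
    "AccuracyReport",
    "assign_folds",
    "reduce_features",
    "cv_stack_predict",
    "compute_gap",
    "accuracy_metrics",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per (repeat, subject); every subject appears in exactly
    one fold per repeat and fold sizes differ by at most one."""

    n_subjects: int
    k: int
    repeats: int
    assignment: np.ndarray  # shape (repeats, n_subjects), values in [0, k)

    def test_mask(self, repeat: int, fold: int) -> np.ndarray:
        return self.assignment[repeat] == fold


@dataclass(frozen=True)
class StackedModel:
    """Linear stacking fit: age ~ intercept + weights . base predictions."""

    intercept: float
    weights: np.ndarray
    learner_labels: tuple[str, ...]

    def predict(self, base_predictions: np.ndarray) -> np.ndarray:
        return self.intercept + base_predictions @ self.weights


@dataclass(frozen=True)
class AccuracyReport:
    mae: float    # years
    wmae: float   # MAE / chronological age range
    r: float      # Pearson correlation predicted vs chronological
    n: int


def assign_folds(n_subjects: int, k: int, repeats: int,
                 seed: int) -> FoldAssignment:
    """Random balanced k-fold partition, re-drawn independently per repeat."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_subjects:
        raise ValueError(f"k={k} exceeds n_subjects={n_subjects}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.arange(n_subjects) % k  # balanced fold sizes
    assignment = np.stack([base[rng.permutation(n_subjects)]
                           for _ in range(repeats)])
    return FoldAssignment(n_subjects=n_subjects, k=k, repeats=repeats,
                          assignment=assignment)


def reduce_features(matrix: np.ndarray, n_components: int):
    """Principal-component feature reduction.

    Returns ``(scores, loadings, variance_explained)`` for a fit on the
    given rows. For leakage-safe use inside cross-validation, wrap PCA
    and a learner in a pipeline instead; this function documents the
    reduction itself.
    """
    matrix = np.asarray(matrix, dtype=float)
    max_rank = min(matrix.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n, p)={max_rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(matrix)
    return scores, pca.components_, pca.explained_variance_ratio_


def cv_stack_predict(
    matrix: np.ndarray,
    ages: np.ndarray,
    folds: FoldAssignment,
    learners: list[tuple[str, object]],
    aggregate: str = "mean",
    return_base: bool = False,
):
    """Out-of-fold base predictions, linear stacking, repeat averaging.

    Per repeat, each learner is fit on the training folds and predicts
    the held-out fold; stacking weights are then fit by least squares of
    chronological age on the pooled out-of-fold prediction matrix (the
    pseudo-inverse resolves collinear base predictions). The final
    per-subject prediction averages the stacked predictions across
    repeats (``aggregate="first"`` uses the first repeat only). The
    returned :class:`StackedModel` averages the per-repeat stacking fits.
    With ``return_base=True`` the out-of-fold base prediction array
    (repeats x subjects x learners) is returned as a third element.
    """
    matrix = np.asarray(matrix, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(matrix) != len(ages) or len(ages) != folds.n_subjects:
        raise ValueError("matrix, ages and fold assignment sizes disagree")
    if not learners:
        raise ValueError("need at least one base learner")
    labels = tuple(label for label, _ in learners)
    n, L = folds.n_subjects, len(learners)
    n_repeats = 1 if aggregate == "first" else folds.repeats

    stacked = np.empty((n_repeats, n))
    coefs = np.empty((n_repeats, L + 1))
    base_all = np.empty((n_repeats, n, L))
    for rep in range(n_repeats):
        base = base_all[rep]
        for fold in range(folds.k):
            test = folds.test_mask(rep, fold)
            train = ~test
            for li, (label, learner) in enumerate(learners):
                try:
                    model = learner.fit(matrix[train], ages[train])
                    base[test, li] = model.predict(matrix[test])
                except Exception as err:
                    raise RuntimeError(
                        f"base learner {label!r} failed in repeat {rep}, "
                        f"fold {fold}: {err}"
                    ) from err
        X = np.column_stack([np.ones(n), base])
        beta, *_ = np.linalg.lstsq(X, ages, rcond=None)
        coefs[rep] = beta
        stacked[rep] = X @ beta

    mean_coef = coefs.mean(axis=0)
    model = StackedModel(intercept=float(mean_coef[0]),
                         weights=mean_coef[1:], learner_labels=labels)
    if return_base:
        return stacked.mean(axis=0), model, base_all
    return stacked.mean(axis=0), model


def compute_gap(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Brain age gap in years: predicted minus chronological age."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological lengths differ")
    return predicted - chronological


def accuracy_metrics(predicted: np.ndarray,
                     chronological: np.ndarray) -> AccuracyReport:
    """MAE (years), weighted MAE (MAE over the chronological age range)
    and the Pearson correlation between predicted and chronological age."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological lengths differ")
    n = len(predicted)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    age_range = chronological.max() - chronological.min()
    if age_range <= 0:
        raise ValueError("zero chronological age range; wMAE undefined")
    mae = float(np.mean(np.abs(predicted - chronological)))
    r = float(stats.pearsonr(predicted, chronological).statistic)
    return AccuracyReport(mae=mae, wmae=mae / age_range, r=r, n=n)
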