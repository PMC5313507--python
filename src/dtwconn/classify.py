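"""Sparse (L1) connectome classification with leave-subject-out validation.

The classifier is a LASSO regression on pairwise-connectivity feature
vectors: it minimizes ``(1/N) ||y - X theta - b||^2 + lambda ||theta||_1``
(intercept unpenalized) by cyclic coordinate descent, and thresholds the
continuous prediction at 0.5 to obtain binary labels.  Hyper-parameter
selection and accuracy estimation follow a nested leave-one-subject-out
protocol: all runs of a subject are held out together, and the inner loop
selects the regularization weight from a grid spanning [0.0005, 0.5] using
training subjects only.  Chance levels come from a coin-flip null (iid
Bernoulli(1/2) predicted labels) and from subject-level label-permutation
runs of the full nested pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ClassificationDataset",
    "LassoModel",
    "CvResult",
    "DEFAULT_LAMBDA_GRID",
    "lambda_max",
    "lasso_fit",
    "lasso_objective",
    "predict_labels",
    "nested_loso_cv",
    "coin_flip_threshold",
    "permutation_threshold",
]

#: 25 log-spaced regularization weights spanning [0.0005, 0.5].
DEFAULT_LAMBDA_GRID = np.logspace(np.log10(5e-4), np.log10(0.5), 25)


@dataclass(frozen=True)
class ClassificationDataset:
    """Instance-by-feature table with binary labels and subject grouping."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        subjects = np.asarray(self.subjects)
        if X.ndim != 2 or y.shape != (X.shape[0],) or subjects.shape != (X.shape[0],):
            raise ValueError("X must be (N, d) with matching y and subjects")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        for s in np.unique(subjects):
            if np.unique(y[subjects == s]).size != 1:
                raise ValueError(f"subject {s} has inconsistent labels")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "subjects", subjects)

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def with_labels(self, y) -> "ClassificationDataset":
        return ClassificationDataset(X=self.X, y=y, subjects=self.subjects)


@dataclass(frozen=True)
class LassoModel:
    coef: np.ndarray
    intercept: float
    lam: float
    n_sweeps: int = 0

    def predict_continuous(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


@njit(cache=True)
def _cd_one_sweep(XT, r, theta, lam_half, n, active_only):  # pragma: no cover
    d = theta.size
    max_delta = 0.0
    for j in range(d):
        tj = theta[j]
        if active_only and tj == 0.0:
            continue
        rho = tj
        for i in range(n):
            rho += XT[j, i] * r[i] / n
        if rho > lam_half:
            tnew = rho - lam_half
        elif rho < -lam_half:
            tnew = rho + lam_half
        else:
            tnew = 0.0
        if tnew != tj:
            diff = tj - tnew
            for i in range(n):
                r[i] += XT[j, i] * diff
            theta[j] = tnew
            ad = abs(diff)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _cd_sweeps(XT, r, theta, lam_half, n, max_sweeps, tol):  # pragma: no cover
    """Cyclic coordinate descent on standardized columns (XT is d x n).

    ``r`` is the current residual ``y - b - X theta``; with columns scaled
    to ||x_j||^2 = n the update is the soft threshold of
    ``rho_j = theta_j + x_j . r / n`` at ``lam/2``.  Between full sweeps the
    iteration restricts itself to the active (nonzero) set, the usual
    coordinate-descent speed-up; a final full sweep certifies convergence.
    """
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        full_delta = _cd_one_sweep(XT, r, theta, lam_half, n, False)
        if full_delta < tol:
            break
        while sweeps < max_sweeps:
            sweeps += 1
            if _cd_one_sweep(XT, r, theta, lam_half, n, True) < tol:
                break
    return sweeps


def lasso_objective(X, y, coef, intercept, lam) -> float:
    """The penalized objective ``(1/N)||y - X theta - b||^2 + lam ||theta||_1``."""
    resid = np.asarray(y, float) - np.asarray(X, float) @ coef - intercept
    n = resid.size
    return float(resid @ resid / n + lam * np.abs(coef).sum())


def lambda_max(X, y) -> float:
    """Smallest regularization weight at which the solution is all-zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    return float(2.0 * np.abs(X.T @ (y - y.mean())).max() / n)


def lasso_fit(
    X,
    y,
    lam: float,
    *,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    warm_start: np.ndarray | None = None,
) -> LassoModel:
    """Fit the LASSO by cyclic coordinate descent.

    ``X`` is expected standardized per feature over the training rows (mean
    0, population sd 1) so that each coordinate update is an exact soft
    threshold.  Convergence: max coefficient change < ``tol`` or
    ``max_sweeps`` sweeps.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, d = X.shape
    intercept = float(y.mean())
    theta = np.zeros(d) if warm_start is None else np.asarray(warm_start, float).copy()
    r = y - intercept - X @ theta
    XT = np.ascontiguousarray(X.T)
    sweeps = _cd_sweeps(XT, r, theta, lam / 2.0, n, max_sweeps, tol)
    return LassoModel(coef=theta, intercept=intercept, lam=float(lam), n_sweeps=int(sweeps))


def predict_labels(model: LassoModel, X) -> np.ndarray:
    """Binary decision rule: continuous regression output thresholded at 0.5."""
    return (model.predict_continuous(X) >= 0.5).astype(int)


def _standardize_fit(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


@dataclass(frozen=True)
class CvResult:
    """Nested leave-subject-out cross-validation outcome."""

    accuracy: float
    fold_subjects: list
    fold_lambdas: np.ndarray
    predictions: np.ndarray
    true_labels: np.ndarray
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID)


def _fit_lambda_path(Xs, y, grid_desc):
    """Warm-started fits along a descending lambda grid; returns models."""
    models = []
    warm = None
    for lam in grid_desc:
        m = lasso_fit(Xs, y, lam, warm_start=warm)
        warm = m.coef
        models.append(m)
    return models


def nested_loso_cv(
    dataset: ClassificationDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> CvResult:
    """Nested leave-one-subject-out cross-validation.

    Outer loop: all runs of one subject are held out.  Inner loop: a second
    LOSO over the remaining subjects scores every lambda in the grid; the
    weight maximizing inner accuracy is chosen (ties break toward the larger
    weight, i.e. the sparser model), the model is refit on the full training
    set, and the held-out runs are predicted.  Feature standardization is
    estimated on training rows only.
    """
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    grid_desc = grid[::-1]
    subjects = np.unique(dataset.subjects)
    if subjects.size < 3:
        raise ValueError("need at least 3 subjects for nested LOSO")
    preds = np.empty(dataset.n_instances, dtype=int)
    fold_lambdas = []
    fold_subjects = []
    for s_out in subjects:
        test_rows = dataset.subjects == s_out
        train_rows = ~test_rows
        Xtr, ytr = dataset.X[train_rows], dataset.y[train_rows]
        tr_subjects = dataset.subjects[train_rows]
        # inner LOSO: count correct predictions per lambda
        correct = np.zeros(grid_desc.size)
        total = 0
        for s_in in np.unique(tr_subjects):
            in_test = tr_subjects == s_in
            in_train = ~in_test
            y_in = ytr[in_train]
            if np.unique(y_in).size < 2:
                warnings.warn(f"inner fold {s_in}: single-class training set, skipped")
                continue
            mean, sd = _standardize_fit(Xtr[in_train])
            Xs = (Xtr[in_train] - mean) / sd
            Xv = (Xtr[in_test] - mean) / sd
            for k, m in enumerate(_fit_lambda_path(Xs, y_in, grid_desc)):
                correct[k] += int((predict_labels(m, Xv) == ytr[in_test]).sum())
            total += int(in_test.sum())
        # ties toward larger lambda: grid_desc is descending, argmax takes first
        best_lam = float(grid_desc[int(np.argmax(correct))])
        mean, sd = _standardize_fit(Xtr)
        Xs = (Xtr - mean) / sd
        model = lasso_fit(Xs, ytr, best_lam)
        Xt = (dataset.X[test_rows] - mean) / sd
        preds[test_rows] = predict_labels(model, Xt)
        fold_lambdas.append(best_lam)
        fold_subjects.append(s_out)
    accuracy = float((preds == dataset.y).mean())
    return CvResult(
        accuracy=accuracy,
        fold_subjects=fold_subjects,
        fold_lambdas=np.asarray(fold_lambdas),
        predictions=preds,
        true_labels=dataset.y.copy(),
        lambda_grid=grid,
    )


def coin_flip_threshold(y, n_draws: int = 100_000, percentile: float = 95.0, seed=0) -> float:
    """Accuracy percentile of iid Bernoulli(1/2) label guessing against ``y``."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = y.size
    draws = rng.integers(0, 2, size=(n_draws, n))
    acc = (draws == y[None, :]).mean(axis=1)
    return float(np.percentile(acc, percentile))


def permutation_threshold(
    dataset: ClassificationDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed=0,
) -> tuple[float, np.ndarray]:
    """Accuracy percentile of the full nested pipeline on permuted labels.

    Labels are permuted at the subject level (all runs of a subject keep a
    common label), respecting exchangeability under leave-subject-out CV.
    Returns the threshold and the permuted accuracies.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    subjects = np.unique(dataset.subjects)
    subj_label = {s: int(dataset.y[dataset.subjects == s][0]) for s in subjects}
    base = np.array([subj_label[s] for s in subjects])
    accs = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(base)
        lab_of = dict(zip(subjects, perm))
        y_perm = np.array([lab_of[s] for s in dataset.subjects])
        accs[k] = nested_loso_cv(dataset.with_labels(y_perm), lambda_grid).accuracy
    return float(np.percentile(accs, percentile)), accs
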