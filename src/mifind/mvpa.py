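"""Multivariate pattern analyses.

Two analysis paths over run-structured beta patterns:

* **Representational distances.**  Per-run condition-mean patterns are
  prewhitened with a shrinkage estimate of the voxel noise covariance
  (from the model-fit residuals) and compared through the
  cross-validated Mahalanobis ("crossnobis") distance, which averages
  the inner products of pattern differences across independent run
  folds.  Crossnobis is unbiased: its expected value is 0 when the
  conditions are statistically indistinguishable, so single estimates
  may legitimately be negative and are never clipped.

* **Decoding.**  A linear support-vector machine (C = 1, l2 penalty)
  classifies single-trial betas — leave-one-run-out within the
  execution task, or trained on execution and tested on imagery trials
  (cross-task).  Significance comes from a permutation null over trial
  labels, with Fisher combination across participants and
  Benjamini-Hochberg FDR across comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .datasets import DistanceMatrix, PatternDataset

__all__ = [
    "shrink_covariance",
    "whitener",
    "crossnobis",
    "avg_interfinger",
    "zscale",
    "apply_scaler",
    "loro_cv",
    "cross_task",
    "permutation_null",
    "permutation_null_refit",
    "empirical_p",
    "fisher_combine",
    "bh_fdr",
]

SVM_TOL = 1e-6  # fixed optimizer tolerance so fits are reproducible


# ---------------------------------------------------------------------------
# noise covariance and prewhitening
# ---------------------------------------------------------------------------

def shrink_covariance(residuals: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrinkage covariance of residual samples, target = its own diagonal.

    Analytic (Ledoit-Wolf-type) shrinkage of the sample covariance
    toward its diagonal, with the weight chosen from the estimated
    variance of the off-diagonal entries.  Guarantees a symmetric
    positive-definite estimate even with few samples.  Returns
    ``(sigma, shrinkage_weight)``.
    """
    X = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 residual samples (samples x voxels)")
    n, p = X.shape
    X = X - X.mean(axis=0)
    S = X.T @ X / (n - 1)
    # variance of each entry of S (Schafer-Strimmer)
    X2 = X * X
    var_S = (X2.T @ X2 / n - (X.T @ X / n) ** 2) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = float((S[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_S[off].sum() / denom, 0.0, 1.0))
    sigma = lam * np.diag(np.diag(S)) + (1.0 - lam) * S
    # keep strictly PD even if some voxel had zero variance
    eps = 1e-12 * max(np.trace(sigma) / p, 1.0)
    sigma[np.diag_indices(p)] += eps
    return sigma, lam


def whitener(sigma: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of a covariance matrix."""
    vals, vecs = np.linalg.eigh(np.asarray(sigma, dtype=float))
    if np.any(vals <= 0):
        raise ValueError("covariance must be positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


# ---------------------------------------------------------------------------
# crossnobis distances
# ---------------------------------------------------------------------------

def crossnobis(dataset: PatternDataset, sigma: np.ndarray | None = None) -> DistanceMatrix:
    """Cross-validated Mahalanobis distances between all condition pairs.

    With whitened per-run condition patterns ``w`` the distance for a
    pair (i, j) is::

        d(i,j) = 1 / (M (M-1) P) * sum_{m != n} (w_im - w_jm) . (w_in - w_jn)

    over the ``M`` runs (folds) and ``P`` voxels.  The noise covariance
    defaults to the shrinkage estimate from the dataset's pooled
    residuals.
    """
    m = dataset.n_runs
    if m < 2:
        raise ValueError("crossnobis needs at least 2 runs")
    if sigma is None:
        sigma, _ = shrink_covariance(dataset.pooled_residuals())
    w = dataset.condition_means() @ whitener(sigma)     # (M, K, P)
    k, p = w.shape[1], w.shape[2]
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            delta = w[:, i, :] - w[:, j, :]             # (M, P)
            total = delta.sum(axis=0)
            cross = float(total @ total - np.einsum("mp,mp->", delta, delta))
            values[i, j] = values[j, i] = cross / (m * (m - 1) * p)
    return DistanceMatrix(conditions=dataset.conditions, values=values, n_folds=m,
                          meta={"task": dataset.task, "session": dataset.session})


def avg_interfinger(distmat: DistanceMatrix) -> float:
    """Average of the pairwise distances — the strength of the finger representation."""
    return float(distmat.off_diagonal().mean())


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def zscale(train_features: np.ndarray) -> StandardScaler:
    """Per-feature center/scale fitted on training data only.

    Constant features get a unit divisor, so the transform is always
    defined and affine-invertible.
    """
    return StandardScaler().fit(np.asarray(train_features, dtype=float))


def apply_scaler(scaler: StandardScaler, features: np.ndarray) -> np.ndarray:
    """Apply a previously fitted scaler, unchanged, to new data."""
    return scaler.transform(np.asarray(features, dtype=float))


def _svm() -> SVC:
    return SVC(kernel="linear", C=1.0, tol=SVM_TOL)


def loro_cv(X: np.ndarray, y: np.ndarray, runs: np.ndarray) -> float:
    """Leave-one-run-out decoding accuracy (%) with a linear SVM.

    For every left-out run the scaler and the classifier are fitted on
    the remaining runs only; the reported accuracy is the mean of the
    per-fold accuracies, in percent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs = np.asarray(runs)
    fold_acc = []
    for r in np.unique(runs):
        test = runs == r
        scaler = zscale(X[~test])
        clf = _svm().fit(apply_scaler(scaler, X[~test]), y[~test])
        pred = clf.predict(apply_scaler(scaler, X[test]))
        fold_acc.append(float(np.mean(pred == y[test])))
    return float(np.mean(fold_acc) * 100.0)


def cross_task(X_train: np.ndarray, y_train: np.ndarray,
               X_test: np.ndarray, y_test: np.ndarray,
               train_scaler: StandardScaler | None = None,
               test_scaler: StandardScaler | None = None,
               return_predictions: bool = False):
    """Train on one task's trials, test on the other's; accuracy in %.

    Scaling is fitted separately per task: the training scaler on the
    (full) training-task data and the test scaler on the test-task
    data, mirroring a transfer analysis where both tasks are scaled
    across all of their own runs.  Pass ``test_scaler`` fitted on both
    sessions' test-task trials when evaluating sessions separately.
    """
    train_scaler = train_scaler or zscale(X_train)
    test_scaler = test_scaler or zscale(X_test)
    clf = _svm().fit(apply_scaler(train_scaler, X_train), np.asarray(y_train))
    pred = clf.predict(apply_scaler(test_scaler, X_test))
    acc = float(np.mean(pred == np.asarray(y_test)) * 100.0)
    if return_predictions:
        return acc, pred
    return acc


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_null(y_pred: np.ndarray, y_test: np.ndarray, n_perm: int = 1000,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Null accuracies (%) from shuffling the test-trial labels.

    The classifier's predictions stay fixed; each permutation re-scores
    them against a label shuffle, which preserves the class counts.
    This is the null for transfer decoding, where only the test set's
    labels are exchangeable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    y_pred = np.asarray(y_pred)
    y_test = np.asarray(y_test)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = np.mean(y_pred == rng.permutation(y_test)) * 100.0
    return null


def permutation_null_refit(X: np.ndarray, y: np.ndarray, runs: np.ndarray,
                           n_perm: int = 1000,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Null accuracies (%) from shuffling all trial labels and refitting.

    The scope for within-task cross-validated decoding: each
    permutation relabels every trial (class counts preserved) and
    reruns the full leave-one-run-out pipeline.  Far more expensive
    than :func:`permutation_null`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y)
    return np.array([loro_cv(X, rng.permutation(y), runs) for _ in range(n_perm)])


def empirical_p(true_score: float, null_scores: np.ndarray) -> float:
    """(count of null >= true, plus 1) over (number of permutations, plus 1)."""
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size < 1:
        raise ValueError("empty null distribution")
    return float((np.sum(null_scores >= true_score) + 1) / (null_scores.size + 1))


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: statistic -2 sum(ln p), chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, float(stats.chi2.sf(stat, df))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
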