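"""Family classification: equal-prior LDA, leave-one-out CV, permutation null.

The classifier is Gaussian linear discriminant analysis with a pooled
within-class covariance and *equal priors across classes* — class
imbalance never tilts the decision rule.  Performance is measured by
leave-one-out cross-validation: each sample is predicted by discriminants
trained on all remaining samples.  Significance of the observed accuracy is
assessed against a null built by permuting class labels against the shape
data and re-running the full leave-one-out procedure; the p-value uses the
add-one estimator p = (1 + #{null >= observed}) / (B + 1), so it is never
exactly zero.

The leave-one-out loop downdates per-class sums and scatter matrices rather
than refitting from scratch, which keeps a 1,000-permutation null on a few
hundred samples cheap.  scikit-learn's LinearDiscriminantAnalysis with
uniform priors is the independent reference implementation the test suite
checks this module against.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import ClassificationError, ConfigurationError, ValidationError

__all__ = [
    "ClassificationResult",
    "PermutationResult",
    "lda_loo",
    "permutation_test",
]


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Held-out predictions from leave-one-out LDA.

    ``confusion`` rows are actual classes, columns predicted classes, with
    each row normalized to sum to 1 over the samples of that actual class.
    """

    predicted: np.ndarray
    actual: np.ndarray
    confusion: pd.DataFrame
    accuracy: float


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_accuracies: np.ndarray
    p_value: float
    seed: int


class _PooledLDA:
    """Equal-prior Gaussian LDA with pooled covariance and LOO downdating."""

    def __init__(self, X: np.ndarray, y: np.ndarray, shrinkage: float | None = None):
        self.X = X
        self.y = y
        self.shrinkage = shrinkage
        self.classes, self.y_idx = np.unique(y, return_inverse=True)
        self.n, self.k = X.shape
        self.n_classes = self.classes.size
        self.counts = np.bincount(self.y_idx, minlength=self.n_classes).astype(float)
        # per-class sufficient statistics
        self.sums = np.zeros((self.n_classes, self.k))
        self.sqs = np.zeros((self.n_classes, self.k, self.k))
        for c in range(self.n_classes):
            Xc = X[self.y_idx == c]
            self.sums[c] = Xc.sum(axis=0)
            self.sqs[c] = Xc.T @ Xc

    @staticmethod
    def _scatter(sq: np.ndarray, s: np.ndarray, n: float) -> np.ndarray:
        return sq - np.outer(s, s) / n

    def _chol(self, pooled_scatter: np.ndarray, dof: float) -> np.ndarray:
        cov = pooled_scatter / dof
        if self.shrinkage:
            alpha = self.shrinkage
            cov = (1.0 - alpha) * cov + alpha * (np.trace(cov) / self.k) * np.eye(
                self.k
            )
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ClassificationError(
                "singular pooled within-class covariance; use fewer components "
                "or enable shrinkage"
            ) from exc

    def predict_loo(self) -> np.ndarray:
        """Held-out class index for every sample."""
        base_scatter = np.zeros((self.k, self.k))
        class_scatter = np.empty_like(self.sqs)
        for c in range(self.n_classes):
            class_scatter[c] = self._scatter(self.sqs[c], self.sums[c], self.counts[c])
            base_scatter += class_scatter[c]
        base_means = self.sums / self.counts[:, None]
        predictions = np.empty(self.n, dtype=int)
        dof = (self.n - 1) - self.n_classes
        if dof <= 0:
            raise ClassificationError(
                "not enough samples for the pooled covariance; use fewer components"
            )
        for i in range(self.n):
            c = self.y_idx[i]
            x = self.X[i]
            s_held = self.sums[c] - x
            n_held = self.counts[c] - 1.0
            means = base_means.copy()
            means[c] = s_held / n_held
            scatter_held = self._scatter(self.sqs[c] - np.outer(x, x), s_held, n_held)
            pooled = base_scatter - class_scatter[c] + scatter_held
            chol = self._chol(pooled, dof)
            diff = x[None, :] - means
            sol = solve_triangular(chol, diff.T, lower=True, check_finite=False)
            d2 = (sol**2).sum(axis=0)
            predictions[i] = int(np.argmin(d2))
        return predictions


def _prepare(scores: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("scores and labels must have equal sample counts")
    if not np.all(np.isfinite(X)):
        raise ValidationError("scores contain non-finite entries")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        if small.size == classes.size:
            raise ClassificationError("every class has a single sample; cannot train")
        warnings.warn(
            f"dropping classes with a single sample: {', '.join(map(str, small))}",
            RuntimeWarning,
            stacklevel=3,
        )
        keep = ~np.isin(y, small)
        X, y = X[keep], y[keep]
    if np.unique(y).size < 2:
        raise ClassificationError("need at least 2 classes with >= 2 samples each")
    return X, y


def lda_loo(
    scores: np.ndarray, labels, shrinkage: float | None = None
) -> ClassificationResult:
    """Leave-one-out cross-validated LDA with equal class priors.

    Classes with a single sample are dropped with a warning.  A singular
    pooled covariance raises :class:`ClassificationError` advising fewer
    components (pass ``shrinkage`` in (0, 1) to opt in to diagonal
    regularization instead).

    Returns
    -------
    ClassificationResult
        Held-out predictions, row-normalized confusion matrix, accuracy.
    """
    X, y = _prepare(scores, labels)
    model = _PooledLDA(X, y, shrinkage=shrinkage)
    pred_idx = model.predict_loo()
    predicted = model.classes[pred_idx]
    accuracy = float(np.mean(predicted == y))
    confusion = pd.crosstab(
        pd.Series(y, name="actual"),
        pd.Series(predicted, name="predicted"),
        dropna=False,
    ).reindex(index=model.classes, columns=model.classes, fill_value=0)
    confusion = confusion.div(confusion.sum(axis=1), axis=0)
    return ClassificationResult(
        predicted=predicted, actual=y, confusion=confusion, accuracy=accuracy
    )


def permutation_test(
    scores: np.ndarray,
    labels,
    B: int = 1000,
    seed: int = 0,
    shrinkage: float | None = None,
) -> PermutationResult:
    """Label-permutation null for the leave-one-out LDA accuracy.

    For b = 1..B the class labels are permuted uniformly at random against
    the score rows, the full leave-one-out LDA is re-run, and its accuracy
    recorded; p = (1 + #{null >= observed}) / (B + 1).
    """
    if B < 1:
        raise ConfigurationError(f"B must be >= 1, got {B}")
    observed = lda_loo(scores, labels, shrinkage=shrinkage).accuracy
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    null = np.empty(B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(B):
            null[b] = lda_loo(
                scores, rng.permutation(y), shrinkage=shrinkage
            ).accuracy
    p_value = (1.0 + float(np.count_nonzero(null >= observed))) / (B + 1.0)
    return PermutationResult(
        observed=observed, null_accuracies=null, p_value=p_value, seed=seed
    )
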