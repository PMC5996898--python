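"""PCA morphospace over descriptor matrices and descriptor-PC correlations.

Each leaf is a row of a samples x features matrix (8,000 EC-curve values
with default descriptor settings).  The morphospace is a mean-centered PCA
(no per-feature scaling: EC curves share one common scale), giving scores,
loadings, and explained-variance fractions.  Downstream analyses pick the
leading components covering a cumulative variance fraction (e.g. >= 95%)
and relate classic shape descriptors to PC scores by Spearman rank
correlation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Morphospace",
    "fit_pca",
    "select_components",
    "descriptor_pc_correlation",
]


@dataclasses.dataclass(frozen=True)
class Morphospace:
    """Fitted PCA decomposition of a descriptor matrix.

    Attributes
    ----------
    scores : ndarray, shape (n_samples, n_components)
        Centered data projected on the loadings.
    loadings : ndarray, shape (n_components, n_features)
        Orthonormal principal axes, ordered by decreasing variance.
    explained : ndarray, shape (n_components,)
        Fractions of total variance, non-increasing, summing to 1.
    feature_mean : ndarray, shape (n_features,)
        The centering vector.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    feature_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.explained.size)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new descriptor rows into the fitted morphospace."""
        return (np.asarray(X, dtype=float) - self.feature_mean) @ self.loadings.T


def fit_pca(X: np.ndarray) -> Morphospace:
    """Mean-centered PCA (no feature scaling) of a samples x features matrix.

    Computes the thin decomposition: min(n_samples, n_features) components,
    ordered by decreasing variance.  For reproducibility across linear
    algebra backends each loading vector is oriented so its entry of
    largest magnitude is positive.

    Raises
    ------
    ValidationError
        On fewer than 2 samples or non-finite entries.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("fit_pca needs a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("fit_pca input contains non-finite entries")
    n_components = min(X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-magnitude entry of each axis positive
    flip_idx = np.argmax(np.abs(loadings), axis=1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), flip_idx])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = scores * signs[None, :]
    return Morphospace(
        scores=scores,
        loadings=loadings,
        explained=pca.explained_variance_ratio_,
        feature_mean=pca.mean_,
    )


def select_components(m: Morphospace, frac: float) -> int:
    """Smallest k whose cumulative explained-variance fraction reaches ``frac``.

    ``frac`` must lie in (0, 1]; frac = 1.0 returns the number of
    positive-variance components.
    """
    if not 0.0 < frac <= 1.0:
        raise ConfigurationError(f"frac must be in (0, 1], got {frac}")
    cumulative = np.cumsum(m.explained)
    reached = np.nonzero(cumulative >= frac - 1e-12)[0]
    if reached.size == 0:  # numerical shortfall; use everything informative
        return int(np.count_nonzero(m.explained > 0))
    return int(reached[0]) + 1


def descriptor_pc_correlation(scores: np.ndarray, descriptor: np.ndarray) -> np.ndarray:
    """Spearman rank correlation between one descriptor and each PC's scores.

    Returns an array of length k (= number of score columns).  A constant
    descriptor has no defined rank correlation: NaN is returned for every
    component, with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    descriptor = np.asarray(descriptor, dtype=float)
    if descriptor.shape[0] != scores.shape[0]:
        raise ValidationError("descriptor and scores must have equal sample counts")
    if np.ptp(descriptor) == 0.0:
        warnings.warn(
            "constant descriptor: Spearman correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(scores.shape[1], np.nan)
    out = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        rho = stats.spearmanr(descriptor, scores[:, j]).statistic
        out[j] = rho
    return out
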