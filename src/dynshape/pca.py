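"""Single-level PCA of trajectory feature vectors.

The sample covariance over n feature vectors X_i of length L,

    K = 1/(n-1) * sum_i (X_i - eta)(X_i - eta)^T,    eta = mean_i X_i,

is eigendecomposed into non-negative eigenvalues theta_l (descending) and
orthonormal eigenvectors psi_l ("modes of variation"). A trajectory is
expanded about the mean as  X ~= eta + sum_l a_l psi_l  with component
scores  a_l = (X - eta) . psi_l, standardized by a_l / sqrt(theta_l).

When n < L the covariance is never materialized: the snapshot method
diagonalizes the n x n inner-product matrix instead, which carries the
identical nonzero spectrum.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._eig import ZERO_TOL, eig_from_factor, nonzero_count
from .trajectory import GroupedDataset

__all__ = [
    "TrajectoryPCA",
    "DegenerateModeError",
    "fit_pca",
    "pca_scores",
    "reconstruct",
    "standardize_scores",
]


class DegenerateModeError(ValueError):
    """A zero-variance mode was asked to do something meaningless."""


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, GroupedDataset):
        X = X.X
    elif isinstance(X, (list, tuple)) and X and hasattr(X[0], "values"):
        X = np.vstack([np.asarray(f.values, dtype=float) for f in X])
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    return X


class TrajectoryPCA(BaseEstimator, TransformerMixin):
    """Single-level PCA over flattened trajectory feature vectors.

    Parameters
    ----------
    n_components : int or None
        Number of modes retained for transform/inverse_transform. None
        keeps every mode with a nonzero eigenvalue.
    zero_tol : float
        Relative tolerance below which an eigenvalue counts as zero
        (threshold ``zero_tol * max(theta_1, 1)``).

    Attributes
    ----------
    mean_ : (L,) mean feature vector eta.
    eigenvalues_ : descending, clamped non-negative; length min(n, L).
    components_ : (k, L) eigenvectors as rows, sign-fixed so each row's
        largest-magnitude entry is positive.
    rank_ : number of nonzero eigenvalues under ``zero_tol``.
    n_samples_, n_features_in_ : training shape.
    """

    def __init__(self, n_components: int | None = None, zero_tol: float = ZERO_TOL):
        self.n_components = n_components
        self.zero_tol = zero_tol

    def fit(self, X, y=None) -> "TrajectoryPCA":
        X = _as_matrix(X)
        n, L = X.shape
        if n < 2:
            raise ValueError(f"PCA needs at least 2 subjects, got {n}")
        self.mean_ = X.mean(axis=0)
        B = (X - self.mean_) / np.sqrt(n - 1)
        vals, vecs = eig_from_factor(B)
        self.eigenvalues_ = vals
        self.components_ = vecs.T
        self.rank_ = nonzero_count(vals, self.zero_tol)
        self.n_samples_ = n
        self.n_features_in_ = L
        return self

    # -- helpers -------------------------------------------------------

    def _n_retained(self) -> int:
        if self.n_components is None:
            return self.rank_
        if self.n_components > self.components_.shape[0]:
            raise ValueError(
                f"n_components={self.n_components} exceeds the "
                f"{self.components_.shape[0]} available modes"
            )
        return self.n_components

    def _check_vector(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"expected vectors of length {self.n_features_in_}, got {x.shape[-1]}"
            )
        return x

    # -- sklearn surface ----------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Component scores a_l = (X - eta) . psi_l, one row per subject."""
        check_is_fitted(self, "mean_")
        X = self._check_vector(_as_matrix(X))
        m = self._n_retained()
        return (X - self.mean_) @ self.components_[:m].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruction eta + sum_l a_l psi_l from (possibly fewer) scores."""
        check_is_fitted(self, "mean_")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        m = scores.shape[1]
        if m > self.components_.shape[0]:
            raise ValueError("more scores than available modes")
        rec = self.mean_ + scores @ self.components_[:m]
        return rec[0] if rec.shape[0] == 1 else rec

    def standardize(self, scores: np.ndarray) -> np.ndarray:
        """Scores divided by sqrt(theta_l), per retained mode.

        Raises :class:`DegenerateModeError` if any requested mode has a
        zero eigenvalue under the tolerance.
        """
        check_is_fitted(self, "mean_")
        scores = np.asarray(scores, dtype=float)
        m = scores.shape[-1]
        if m > self.rank_:
            raise DegenerateModeError(
                f"cannot standardize {m} modes: only {self.rank_} have "
                "nonzero eigenvalues"
            )
        return scores / np.sqrt(self.eigenvalues_[:m])

    def explained_variance_ratio_(self) -> np.ndarray:
        check_is_fitted(self, "mean_")
        total = self.eigenvalues_.sum()
        return self.eigenvalues_ / total if total > 0 else self.eigenvalues_ * 0.0

    # -- serialization -------------------------------------------------

    def save(self, path) -> None:
        """Archive mean, spectrum, modes and layout metadata to ``.npz``."""
        check_is_fitted(self, "mean_")
        meta = getattr(self, "layout_", {})
        np.savez(
            path,
            mean=self.mean_,
            eigenvalues=self.eigenvalues_,
            components=self.components_,
            n_samples=self.n_samples_,
            zero_tol=self.zero_tol,
            layout_dim=meta.get("Dim", 0),
            layout_m=meta.get("M", 0),
            layout_t=meta.get("T", 0),
            flattening="time-major",
        )

    @classmethod
    def load(cls, path) -> "TrajectoryPCA":
        with np.load(path, allow_pickle=False) as z:
            model = cls(zero_tol=float(z["zero_tol"]))
            model.mean_ = z["mean"]
            model.eigenvalues_ = z["eigenvalues"]
            model.components_ = z["components"]
            model.n_samples_ = int(z["n_samples"])
            model.n_features_in_ = model.mean_.size
            model.rank_ = nonzero_count(model.eigenvalues_, model.zero_tol)
            if int(z["layout_dim"]):
                model.layout_ = {
                    "Dim": int(z["layout_dim"]),
                    "M": int(z["layout_m"]),
                    "T": int(z["layout_t"]),
                }
        return model


# ---------------------------------------------------------------------
# thin functional wrappers

def fit_pca(data, n_components: int | None = None) -> TrajectoryPCA:
    """Fit single-level trajectory PCA on a GroupedDataset or (n, L) array."""
    model = TrajectoryPCA(n_components=n_components).fit(data)
    if isinstance(data, GroupedDataset):
        model.layout_ = {"Dim": data.Dim, "M": data.M, "T": data.grid.T}
    return model


def pca_scores(model: TrajectoryPCA, x, m: int | None = None) -> np.ndarray:
    """Scores of one feature vector on the first m modes."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    if m is not None and m > model.components_.shape[0]:
        raise ValueError(f"m={m} exceeds available modes")
    scores = (x - model.mean_) @ model.components_.T
    return scores[: m if m is not None else model.rank_]


def reconstruct(model: TrajectoryPCA, scores) -> np.ndarray:
    """eta + sum_l a_l psi_l for a single score vector."""
    return model.inverse_transform(np.atleast_2d(scores))


def standardize_scores(model: TrajectoryPCA, scores) -> np.ndarray:
    """a_l / sqrt(theta_l) per mode; errors on zero-eigenvalue modes."""
    return model.standardize(scores)
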