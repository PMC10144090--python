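"""Two-level multilevel PCA (mPCA) of trajectory feature vectors.

With subjects X^{i,j} nested in p groups, the model splits variation into
two levels, each with its own PCA:

* level 2 (within-group): per-group covariances about the group means
  eta^j (divisor n_j - 1) are pooled into a single "common" covariance
  with equal weight 1/p per group,

      K2 = 1/p * sum_j K2_j,

  deliberately treating every group alike irrespective of its size (the
  maximum-likelihood n_j/n weighting is available as an option);

* level 1 (between-group): the covariance of the group means about the
  grand mean eta = 1/p * sum_j eta^j, with divisor p - 1. Its rank — and
  hence the number of nonzero level-1 eigenvalues — is at most p - 1.

A trajectory is expanded as

    X ~= eta + sum_l a_l^1 psi_l^1 + sum_l a_l^2 psi_l^2,

and because the two levels' modes are not mutually orthogonal the scores
(a^1, a^2) are fitted jointly by least squares over the concatenated mode
matrix; the objective is quadratic so this closed form IS the global
optimum, with the minimum-norm solution breaking any collinearity.
Standardized scores divide by sqrt(theta) per mode at each level. Mode-of-
variation trajectories are eta + c * sqrt(theta_l) * psi_l.

Two-level mPCA is equivalent to between-group PCA (bgPCA) and inherits its
small-sample pathology: spurious group separation when n_j is below the
feature length. Fitting warns in that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._eig import ZERO_TOL, eig_from_factor, nonzero_count
from .pca import DegenerateModeError, _as_matrix
from .trajectory import GroupedDataset, SmallSamplePathologyWarning, unflatten_frames

__all__ = [
    "MultilevelPCA",
    "MPCAScoreSet",
    "fit_mpca",
    "mpca_fit_scores",
    "mpca_standardize",
    "mode_trajectory",
    "eigen_report",
]


@dataclass
class MPCAScoreSet:
    """Per-subject raw and standardized component scores at both levels."""

    subject_ids: list[str]
    group_ids: list[str]
    between: np.ndarray        # (n, m1) level-1 scores
    within: np.ndarray         # (n, m2) level-2 scores
    between_std: np.ndarray    # standardized variants
    within_std: np.ndarray
    residual_norm: np.ndarray  # (n,) Euclidean norm of the expansion residual

    def to_frame(self) -> pd.DataFrame:
        cols = {"subject": self.subject_ids, "group": self.group_ids}
        for l in range(self.between.shape[1]):
            cols[f"a1_{l + 1}"] = self.between[:, l]
            cols[f"z1_{l + 1}"] = self.between_std[:, l]
        for l in range(self.within.shape[1]):
            cols[f"a2_{l + 1}"] = self.within[:, l]
            cols[f"z2_{l + 1}"] = self.within_std[:, l]
        cols["residual_norm"] = self.residual_norm
        return pd.DataFrame(cols)


class MultilevelPCA(BaseEstimator):
    """Two-level mPCA estimator over grouped trajectory feature vectors.

    Parameters
    ----------
    n_components_between : int or None
        Level-1 modes retained for score fitting (m1). None keeps every
        nonzero level-1 mode.
    n_components_within : int or None
        Level-2 modes retained (m2). None keeps the smallest number of
        modes reaching ``within_variance`` of the level-2 variance.
    within_variance : float
        Cumulative level-2 variance fraction used when
        ``n_components_within`` is None.
    within_weighting : {"equal", "size"}
        "equal" pools per-group covariances with weight 1/p; "size" uses
        the maximum-likelihood n_j/n weighting.
    zero_tol : float
        Relative nonzero-eigenvalue tolerance, as in TrajectoryPCA.

    Attributes
    ----------
    grand_mean_ : (L,) unweighted average of the group means.
    group_means_ : (p, L), rows ordered as ``groups_``.
    eigenvalues_between_, components_between_ : level-1 spectrum/modes.
    eigenvalues_within_, components_within_ : level-2 spectrum/modes.
    rank_between_, rank_within_ : nonzero counts under ``zero_tol``.
    m1_, m2_ : retained mode counts used by :meth:`transform`.
    """

    def __init__(
        self,
        n_components_between: int | None = None,
        n_components_within: int | None = None,
        within_variance: float = 0.95,
        within_weighting: str = "equal",
        zero_tol: float = ZERO_TOL,
    ):
        self.n_components_between = n_components_between
        self.n_components_within = n_components_within
        self.within_variance = within_variance
        self.within_weighting = within_weighting
        self.zero_tol = zero_tol

    # -- fitting -------------------------------------------------------

    def fit(self, X, y=None) -> "MultilevelPCA":
        """Fit from a GroupedDataset, or an (n, L) array with labels y."""
        if isinstance(X, GroupedDataset):
            labels = np.asarray(X.group_ids)
            self.layout_ = {"Dim": X.Dim, "M": X.M, "T": X.grid.T}
        else:
            if y is None:
                raise ValueError("group labels y are required for array input")
            labels = np.asarray(y)
        M = _as_matrix(X)
        if labels.shape[0] != M.shape[0]:
            raise ValueError("label count does not match subject count")
        if self.within_weighting not in ("equal", "size"):
            raise ValueError(f"unknown within_weighting {self.within_weighting!r}")

        groups, inverse = np.unique(labels, return_inverse=True)
        p = groups.size
        if p < 2:
            raise ValueError(
                f"mPCA needs at least 2 groups to form level 1, got {p} "
                f"({list(groups)})"
            )
        sizes = np.bincount(inverse, minlength=p)
        n, L = M.shape

        singletons = [str(groups[j]) for j in range(p) if sizes[j] < 2]
        if singletons:
            warnings.warn(
                f"groups {singletons} have a single subject; they contribute "
                "zero within-group covariance",
                UserWarning,
                stacklevel=2,
            )
        if np.any(sizes < L):
            small = [str(groups[j]) for j in range(p) if sizes[j] < L]
            warnings.warn(
                f"per-group sample size below the feature-vector length L={L} "
                f"for groups {small}; between-group modes may show spurious "
                "separation",
                SmallSamplePathologyWarning,
                stacklevel=2,
            )

        means = np.empty((p, L))
        rows = []
        total_weight = n if self.within_weighting == "size" else p
        for j in range(p):
            Xj = M[inverse == j]
            means[j] = Xj.mean(axis=0)
            if sizes[j] < 2:
                continue
            if self.within_weighting == "equal":
                w = 1.0 / (p * (sizes[j] - 1))
            else:
                w = sizes[j] / (n * (sizes[j] - 1))
            rows.append((Xj - means[j]) * np.sqrt(w))
        grand = means.mean(axis=0)

        if rows:
            within_vals, within_vecs = eig_from_factor(np.vstack(rows))
        else:
            within_vals = np.zeros(min(n, L))
            within_vecs = np.zeros((L, min(n, L)))
        between_vals, between_vecs = eig_from_factor(
            (means - grand) / np.sqrt(p - 1)
        )

        self.groups_ = [str(g) for g in groups]
        self.group_sizes_ = dict(zip(self.groups_, sizes.tolist()))
        self.group_means_ = means
        self.grand_mean_ = grand
        self.eigenvalues_between_ = between_vals
        self.components_between_ = between_vecs.T
        self.eigenvalues_within_ = within_vals
        self.components_within_ = within_vecs.T
        self.rank_between_ = nonzero_count(between_vals, self.zero_tol)
        self.rank_within_ = nonzero_count(within_vals, self.zero_tol)
        self.n_samples_ = n
        self.n_features_in_ = L
        self.m1_ = self._pick_m1()
        self.m2_ = self._pick_m2()
        return self

    def _pick_m1(self) -> int:
        if self.n_components_between is not None:
            return min(self.n_components_between, self.components_between_.shape[0])
        return self.rank_between_

    def _pick_m2(self) -> int:
        if self.n_components_within is not None:
            return min(self.n_components_within, self.components_within_.shape[0])
        ev = self.eigenvalues_within_[: self.rank_within_]
        if ev.size == 0:
            return 0
        frac = np.cumsum(ev) / ev.sum()
        return int(np.searchsorted(frac, self.within_variance - 1e-12) + 1)

    # -- score fitting -------------------------------------------------

    def _mode_matrix(self) -> np.ndarray:
        return np.hstack(
            [
                self.components_between_[: self.m1_].T,
                self.components_within_[: self.m2_].T,
            ]
        )

    def _mode_scales(self) -> np.ndarray:
        ev = np.concatenate(
            [
                self.eigenvalues_between_[: self.m1_],
                self.eigenvalues_within_[: self.m2_],
            ]
        )
        top = max(float(ev[0]) if ev.size else 0.0, 1.0)
        scales = np.sqrt(np.maximum(ev, 0.0))
        scales[ev <= self.zero_tol * top] = 1.0  # keep zero-variance modes usable
        return scales

    def transform(self, X) -> np.ndarray:
        """Jointly fitted (a^1, a^2) scores, concatenated per subject.

        The scores minimize the residual of the two-level expansion; the
        objective is quadratic, so the least-squares solution is the
        global optimum. When the level-1 and level-2 modes are collinear
        (the minimizer is non-unique) the tie is broken by minimizing the
        standardized-score norm sum_l a_l^2 / theta_l, which attributes
        shared directions to the level with the larger eigenvalue —
        between-group structure to level 1, noise to level 2.
        """
        check_is_fitted(self, "grand_mean_")
        M = _as_matrix(X)
        if M.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected vectors of length {self.n_features_in_}, got {M.shape[1]}"
            )
        Psi = self._mode_matrix()
        if Psi.shape[1] == 0:
            return np.zeros((M.shape[0], 0))
        scales = self._mode_scales()
        sol, *_ = np.linalg.lstsq(Psi * scales, (M - self.grand_mean_).T, rcond=None)
        return sol.T * scales

    def fit_scores(self, X, subject_ids=None, group_ids=None) -> MPCAScoreSet:
        """Full score set: raw + standardized scores and residual norms."""
        if isinstance(X, GroupedDataset):
            subject_ids = list(X.subject_ids)
            group_ids = list(X.group_ids)
        M = _as_matrix(X)
        n = M.shape[0]
        scores = self.transform(M)
        a1, a2 = scores[:, : self.m1_], scores[:, self.m1_:]
        recon = self.grand_mean_ + scores @ self._mode_matrix().T
        residual = np.linalg.norm(M - recon, axis=1)
        return MPCAScoreSet(
            subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)],
            group_ids=list(group_ids) if group_ids is not None else [""] * n,
            between=a1,
            within=a2,
            between_std=self.standardize(a1, level=1),
            within_std=self.standardize(a2, level=2),
            residual_norm=residual,
        )

    def standardize(self, scores: np.ndarray, level: int) -> np.ndarray:
        """Divide level-``level`` scores by sqrt(theta_l) of that level."""
        check_is_fitted(self, "grand_mean_")
        ev, rank = self._level(level)[:2]
        scores = np.asarray(scores, dtype=float)
        m = scores.shape[-1]
        if m > rank:
            raise DegenerateModeError(
                f"cannot standardize {m} level-{level} modes: only {rank} "
                "have nonzero eigenvalues"
            )
        return scores / np.sqrt(ev[:m]) if m else scores.copy()

    def _level(self, level: int):
        if level == 1:
            return self.eigenvalues_between_, self.rank_between_, self.components_between_
        if level == 2:
            return self.eigenvalues_within_, self.rank_within_, self.components_within_
        raise ValueError(f"level must be 1 or 2, got {level}")

    # -- modes of variation -------------------------------------------

    def mode_trajectory(self, level: int, mode: int = 0, c: float = 0.0) -> np.ndarray:
        """Grand mean perturbed along one mode: eta + c*sqrt(theta)*psi.

        ``mode`` is 0-based within the requested level. Raises
        :class:`DegenerateModeError` for zero-eigenvalue modes (unless
        c == 0, where the grand mean is returned regardless).
        """
        check_is_fitted(self, "grand_mean_")
        if c == 0.0:
            return self.grand_mean_.copy()
        ev, rank, comps = self._level(level)
        if mode >= rank:
            raise DegenerateModeError(
                f"level-{level} mode {mode} has a zero eigenvalue"
            )
        return self.grand_mean_ + c * np.sqrt(ev[mode]) * comps[mode]

    def mode_frames(self, level: int, mode: int = 0, c: float = 0.0) -> np.ndarray:
        """Mode trajectory unflattened to a (T, M, Dim) frame stack."""
        layout = getattr(self, "layout_", None)
        if layout is None:
            raise ValueError("model carries no layout metadata; fit on a GroupedDataset")
        return unflatten_frames(
            self.mode_trajectory(level, mode, c), layout["M"], layout["Dim"]
        )

    def eigen_report(self) -> pd.DataFrame:
        """Per-level eigenvalue table with nonzero flags and cumulative shares."""
        check_is_fitted(self, "grand_mean_")
        rows = []
        for level in (1, 2):
            ev, rank = self._level(level)[:2]
            total = ev.sum()
            cum = np.cumsum(ev) / total if total > 0 else np.zeros_like(ev)
            for l, theta in enumerate(ev):
                rows.append(
                    {
                        "level": level,
                        "mode": l + 1,
                        "eigenvalue": theta,
                        "nonzero": l < rank,
                        "variance_fraction": theta / total if total > 0 else 0.0,
                        "cumulative_fraction": cum[l],
                    }
                )
        return pd.DataFrame(rows)

    # -- serialization -------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "grand_mean_")
        meta = getattr(self, "layout_", {})
        np.savez(
            path,
            grand_mean=self.grand_mean_,
            group_means=self.group_means_,
            groups=np.asarray(self.groups_, dtype="U"),
            group_sizes=np.asarray([self.group_sizes_[g] for g in self.groups_]),
            eigenvalues_between=self.eigenvalues_between_,
            components_between=self.components_between_,
            eigenvalues_within=self.eigenvalues_within_,
            components_within=self.components_within_,
            m1=self.m1_,
            m2=self.m2_,
            n_samples=self.n_samples_,
            zero_tol=self.zero_tol,
            within_weighting=self.within_weighting,
            layout_dim=meta.get("Dim", 0),
            layout_m=meta.get("M", 0),
            layout_t=meta.get("T", 0),
            flattening="time-major",
        )

    @classmethod
    def load(cls, path) -> "MultilevelPCA":
        with np.load(path, allow_pickle=False) as z:
            model = cls(
                zero_tol=float(z["zero_tol"]),
                within_weighting=str(z["within_weighting"]),
            )
            model.grand_mean_ = z["grand_mean"]
            model.group_means_ = z["group_means"]
            model.groups_ = [str(g) for g in z["groups"]]
            model.group_sizes_ = dict(
                zip(model.groups_, z["group_sizes"].tolist())
            )
            model.eigenvalues_between_ = z["eigenvalues_between"]
            model.components_between_ = z["components_between"]
            model.eigenvalues_within_ = z["eigenvalues_within"]
            model.components_within_ = z["components_within"]
            model.m1_ = int(z["m1"])
            model.m2_ = int(z["m2"])
            model.n_samples_ = int(z["n_samples"])
            model.n_features_in_ = model.grand_mean_.size
            model.rank_between_ = nonzero_count(
                model.eigenvalues_between_, model.zero_tol
            )
            model.rank_within_ = nonzero_count(
                model.eigenvalues_within_, model.zero_tol
            )
            if int(z["layout_dim"]):
                model.layout_ = {
                    "Dim": int(z["layout_dim"]),
                    "M": int(z["layout_m"]),
                    "T": int(z["layout_t"]),
                }
        return model


# ---------------------------------------------------------------------
# thin functional wrappers

def fit_mpca(
    data: GroupedDataset,
    m1: int | None = None,
    m2: int | None = None,
    within_weighting: str = "equal",
) -> MultilevelPCA:
    """Fit a two-level mPCA model on a grouped dataset."""
    return MultilevelPCA(
        n_components_between=m1,
        n_components_within=m2,
        within_weighting=within_weighting,
    ).fit(data)


def mpca_fit_scores(model: MultilevelPCA, x) -> MPCAScoreSet:
    """Joint least-squares score fit for one or more feature vectors."""
    values = np.atleast_2d(np.asarray(getattr(x, "values", x), dtype=float))
    sid = [getattr(x, "subject_id", "0")] * values.shape[0]
    gid = [getattr(x, "group_id", "")] * values.shape[0]
    return model.fit_scores(values, subject_ids=sid, group_ids=gid)


def mpca_standardize(model: MultilevelPCA, scores, level: int) -> np.ndarray:
    return model.standardize(scores, level=level)


def mode_trajectory(model: MultilevelPCA, level: int, mode: int, c: float) -> np.ndarray:
    return model.mode_trajectory(level=level, mode=mode, c=c)


def eigen_report(model: MultilevelPCA) -> pd.DataFrame:
    return model.eigen_report()
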