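"""Landmark-trajectory data model, spline resampling and file I/O.

A subject's recording is a sequence of frames, each holding the same M
landmarks in ``Dim`` spatial dimensions, with (possibly irregular) time
stamps. For analysis every subject is resampled onto a common regular grid
of T normalized time points and flattened into a single feature vector of
length ``Dim * M * T`` (just ``T`` for univariate outcomes). The flattening
convention is time-major: element ``t * (Dim*M) + m * Dim + d`` holds
coordinate ``d`` of landmark ``m`` at grid time ``t``. All covariance
indexing elsewhere in the package inherits this single convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

__all__ = [
    "TimeGrid",
    "SubjectTrajectory",
    "FeatureVector",
    "GroupedDataset",
    "TrajectoryFormatError",
    "SmallSamplePathologyWarning",
    "flatten_frames",
    "unflatten_frames",
    "resample_subject",
    "center_frames",
    "assemble_dataset",
    "read_trajectories",
    "write_trajectories",
]

_COORD_COLS = ("x", "y", "z")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table violates the expected schema."""


class SmallSamplePathologyWarning(UserWarning):
    """Group sample size is below the feature-vector length.

    Between-group PCA is prone to spurious group separation when the
    per-group sample size is smaller than the feature dimension; this
    warning flags that regime, it does not correct for it.
    """


@dataclass(frozen=True)
class TimeGrid:
    """T equally spaced time points on the normalized interval [0, 1]."""

    T: int

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"TimeGrid needs T >= 2, got {self.T}")

    @property
    def t_values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.T)


@dataclass
class SubjectTrajectory:
    """One subject's raw landmark frames with time stamps and group label.

    ``landmarks`` has shape (n_frames, M, Dim); ``times`` is strictly
    increasing and need not be regular.
    """

    subject_id: str
    group_id: str
    times: np.ndarray
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 3:
            raise ValueError(
                "landmarks must have shape (n_frames, M, Dim), got "
                f"{self.landmarks.shape}"
            )
        if self.times.ndim != 1 or self.times.shape[0] != self.landmarks.shape[0]:
            raise ValueError("times must be 1-D and match the frame count")
        if self.n_frames < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 2 frames"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: time stamps must be strictly increasing"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.landmarks)
        ):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values")

    @property
    def n_frames(self) -> int:
        return self.landmarks.shape[0]

    @property
    def M(self) -> int:
        return self.landmarks.shape[1]

    @property
    def Dim(self) -> int:
        return self.landmarks.shape[2]


@dataclass
class FeatureVector:
    """A subject's trajectory resampled and flattened to length Dim*M*T."""

    subject_id: str
    group_id: str
    values: np.ndarray
    M: int
    Dim: int
    T: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.Dim * self.M * self.T:
            raise ValueError(
                f"feature vector length {self.values.size} != Dim*M*T = "
                f"{self.Dim * self.M * self.T}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite features")

    def frames(self) -> np.ndarray:
        """Unflattened (T, M, Dim) view of the feature vector."""
        return unflatten_frames(self.values, self.M, self.Dim)


def flatten_frames(frames: np.ndarray) -> np.ndarray:
    """Flatten a (T, M, Dim) frame stack time-major into a vector."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (T, M, Dim)")
    return frames.reshape(-1)


def unflatten_frames(values: np.ndarray, M: int, Dim: int) -> np.ndarray:
    """Inverse of :func:`flatten_frames`; infers T from the length."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size % (M * Dim):
        raise ValueError("vector length is not a multiple of M*Dim")
    return values.reshape(-1, M, Dim)


@dataclass
class GroupedDataset:
    """All subjects' feature vectors partitioned into groups.

    The matrix ``X`` stacks one feature vector per row; ``group_ids`` and
    ``subject_ids`` run parallel to its rows.
    """

    X: np.ndarray
    subject_ids: list[str]
    group_ids: list[str]
    grid: TimeGrid
    M: int
    Dim: int

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != len(self.subject_ids) or self.X.shape[0] != len(
            self.group_ids
        ):
            raise ValueError("X rows must match subject_ids / group_ids")
        L = self.Dim * self.M * self.grid.T
        if self.X.shape[1] != L:
            raise ValueError(f"feature length {self.X.shape[1]} != Dim*M*T = {L}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return len(self.group_sizes)

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.group_ids:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def groups(self) -> dict[str, list[FeatureVector]]:
        out: dict[str, list[FeatureVector]] = {}
        for i, g in enumerate(self.group_ids):
            out.setdefault(g, []).append(
                FeatureVector(
                    subject_id=self.subject_ids[i],
                    group_id=g,
                    values=self.X[i],
                    M=self.M,
                    Dim=self.Dim,
                    T=self.grid.T,
                )
            )
        return out


def _normalize_times(times: np.ndarray) -> np.ndarray:
    span = times[-1] - times[0]
    return (times - times[0]) / span


def resample_subject(traj: SubjectTrajectory, grid: TimeGrid) -> FeatureVector:
    """Spline-resample one subject onto a regular grid and flatten.

    Each of the Dim*M coordinate channels is fitted independently with an
    interpolating spline (cubic with not-a-knot ends when >= 4 frames;
    degree degrades to quadratic/linear for 3/2 frames) against the
    subject's time axis affinely mapped to [0, 1], then evaluated at the
    grid times. Endpoints map exactly, so no extrapolation occurs.
    """
    tn = _normalize_times(traj.times)
    k = min(3, traj.n_frames - 1)
    spline = make_interp_spline(tn, traj.landmarks, k=k, axis=0)
    resampled = spline(grid.t_values)
    return FeatureVector(
        subject_id=traj.subject_id,
        group_id=traj.group_id,
        values=flatten_frames(resampled),
        M=traj.M,
        Dim=traj.Dim,
        T=grid.T,
    )


def center_frames(traj: SubjectTrajectory) -> SubjectTrajectory:
    """Translate each frame's landmark centroid to the origin.

    A no-op for univariate outcomes (Dim == 1), where "shape" has no
    translational component to remove. No rotation or scaling is applied.
    """
    if traj.Dim < 2:
        return traj
    centroids = traj.landmarks.mean(axis=1, keepdims=True)
    return SubjectTrajectory(
        subject_id=traj.subject_id,
        group_id=traj.group_id,
        times=traj.times.copy(),
        landmarks=traj.landmarks - centroids,
    )


def assemble_dataset(
    trajs: Sequence[SubjectTrajectory],
    grid: TimeGrid,
    center: bool = False,
) -> GroupedDataset:
    """Center (optionally), resample and group a set of subject trajectories.

    Warns with :class:`SmallSamplePathologyWarning` when any group has fewer
    subjects than the feature-vector length Dim*M*T.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("assemble_dataset: empty trajectory list")
    M, Dim = trajs[0].M, trajs[0].Dim
    for tr in trajs:
        if (tr.M, tr.Dim) != (M, Dim):
            raise ValueError(
                f"subject {tr.subject_id!r} has (M={tr.M}, Dim={tr.Dim}); "
                f"expected (M={M}, Dim={Dim})"
            )
    if center:
        trajs = [center_frames(tr) for tr in trajs]
    feats = [resample_subject(tr, grid) for tr in trajs]
    ds = GroupedDataset(
        X=np.vstack([f.values for f in feats]),
        subject_ids=[f.subject_id for f in feats],
        group_ids=[f.group_id for f in feats],
        grid=grid,
        M=M,
        Dim=Dim,
    )
    small = {g: nj for g, nj in ds.group_sizes.items() if nj < ds.L}
    if small:
        warnings.warn(
            "per-group sample size below the feature-vector length "
            f"L={ds.L} for groups {sorted(small)}; between-group modes may "
            "show spurious separation",
            SmallSamplePathologyWarning,
            stacklevel=2,
        )
    return ds


def _coord_cols(Dim: int) -> list[str]:
    return list(_COORD_COLS[:Dim])


def write_trajectories(
    trajs: Iterable[SubjectTrajectory], path, fmt: str = "csv"
) -> None:
    """Write trajectories to a long-format delimited text file.

    Columns: ``subject,group,frame_time,landmark,x[,y[,z]]`` with a 0-based
    landmark index; one row per subject/frame/landmark.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    trajs = list(trajs)
    if not trajs:
        raise ValueError("write_trajectories: nothing to write")
    Dim = trajs[0].Dim
    rows = []
    for tr in trajs:
        for f in range(tr.n_frames):
            for m in range(tr.M):
                rows.append(
                    (tr.subject_id, tr.group_id, tr.times[f], m)
                    + tuple(tr.landmarks[f, m])
                )
    df = pd.DataFrame(
        rows, columns=["subject", "group", "frame_time", "landmark"] + _coord_cols(Dim)
    )
    # %.17g round-trips IEEE doubles exactly (lossless re-read)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path, fmt: str = "csv") -> list[SubjectTrajectory]:
    """Read trajectories from the long-format CSV dialect.

    Validates the schema and that every frame carries the full landmark
    set; errors name the offending subject and frame.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        df = pd.read_csv(
            path, dtype={"subject": str, "group": str}, float_precision="round_trip"
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TrajectoryFormatError(f"{path}: not a trajectory table ({exc})")
    required = {"subject", "group", "frame_time", "landmark"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {sorted(missing)}")
    dims = [c for c in _COORD_COLS if c in df.columns]
    if not dims or dims != _coord_cols(len(dims)):
        raise TrajectoryFormatError(
            f"{path}: need coordinate columns x[,y[,z]], found {list(df.columns)}"
        )
    if df.empty:
        raise TrajectoryFormatError(f"{path}: table has no rows")
    Dim = len(dims)

    out: list[SubjectTrajectory] = []
    M_expected: int | None = None
    for subject, sdf in df.groupby("subject", sort=False):
        groups = sdf["group"].unique()
        if len(groups) != 1:
            raise TrajectoryFormatError(
                f"subject {subject!r}: multiple group labels {list(groups)}"
            )
        frames, times = [], []
        for t, fdf in sdf.groupby("frame_time", sort=True):
            lm = np.sort(fdf["landmark"].to_numpy())
            M = lm.size
            if M_expected is None:
                M_expected = M
            if M != M_expected or not np.array_equal(lm, np.arange(M_expected)):
                raise TrajectoryFormatError(
                    f"subject {subject!r}, frame_time {t}: expected landmarks "
                    f"0..{(M_expected or M) - 1}, got {sorted(fdf['landmark'])}"
                )
            coords = (
                fdf.sort_values("landmark")[dims].to_numpy(dtype=float)
            )
            frames.append(coords)
            times.append(t)
        out.append(
            SubjectTrajectory(
                subject_id=str(subject),
                group_id=str(groups[0]),
                times=np.asarray(times, dtype=float),
                landmarks=np.stack(frames),
            )
        )
    return out
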