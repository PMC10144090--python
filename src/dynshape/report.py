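"""End-to-end pipeline: simulate/load, preprocess, fit, export reports.

`run_pipeline` ties the simulators, spline resampling, single-level PCA
and mPCA together and writes delimited-text artifacts: per-level
eigenvalue spectra, per-subject raw and standardized scores, group score
centroids with pairwise separations, mode-of-variation trajectories
unflattened to frame tables at c in {-1.96, 0, +1.96}, per-subject
reconstruction residuals, and a YAML manifest recording the full
configuration, seed and library versions. Outputs are deterministic given
the seed; numeric exports are never smoothed.
"""

from __future__ import annotations

import itertools
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mpca import MPCAScoreSet, MultilevelPCA
from .pca import TrajectoryPCA
from .simulate import _SIMULATORS
from .trajectory import (
    GroupedDataset,
    TimeGrid,
    assemble_dataset,
    read_trajectories,
    unflatten_frames,
)

__all__ = ["RunConfig", "run_pipeline", "centroid_separation"]

MODE_MULTIPLIERS = (-1.96, 0.0, 1.96)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    outdir: str
    input_csv: str | None = None
    simulator: str | None = None       # "sine" | "blink" | "smile"
    simulator_overrides: dict = field(default_factory=dict)
    T: int = 101
    center: bool = False
    model: str = "both"                # "pca" | "mpca" | "both"
    m1: int | None = None
    m2: int | None = None
    seed: int = 0
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulator is None):
            raise ValueError("give exactly one of input_csv or simulator")
        if self.simulator is not None and self.simulator not in _SIMULATORS:
            raise ValueError(f"unknown simulator {self.simulator!r}")
        if self.model not in ("pca", "mpca", "both"):
            raise ValueError(f"model must be pca|mpca|both, got {self.model!r}")
        if self.T < 2:
            raise ValueError("T must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def centroid_separation(
    scores: pd.DataFrame | MPCAScoreSet, level: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group centroids of standardized scores and their pairwise distances.

    ``scores`` is an :class:`MPCAScoreSet` or its ``to_frame()`` table;
    the standardized columns of ``level`` (``z{level}_*``) are used.
    """
    if isinstance(scores, MPCAScoreSet):
        scores = scores.to_frame()
    cols = [c for c in scores.columns if c.startswith(f"z{level}_")]
    groups = sorted(scores["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"centroid separation needs >= 2 groups, got {groups}")
    centroids = scores.groupby("group")[cols].mean().loc[groups]
    rows = [
        {
            "group_a": a,
            "group_b": b,
            "separation": float(
                np.linalg.norm(centroids.loc[a].to_numpy() - centroids.loc[b].to_numpy())
            ),
        }
        for a, b in itertools.combinations(groups, 2)
    ]
    return centroids.reset_index(), pd.DataFrame(rows)


def _load_dataset(config: RunConfig) -> GroupedDataset:
    grid = TimeGrid(config.T)
    if config.simulator is not None:
        cfg_cls, fn = _SIMULATORS[config.simulator]
        overrides = dict(config.simulator_overrides)
        overrides.setdefault("seed", config.seed)
        trajs = fn(cfg_cls(**overrides))
    else:
        trajs = read_trajectories(config.input_csv)
    return assemble_dataset(trajs, grid, center=config.center)


def _frame_table(vector: np.ndarray, M: int, Dim: int) -> pd.DataFrame:
    frames = unflatten_frames(vector, M, Dim)
    T = frames.shape[0]
    cols = ["x", "y", "z"][:Dim]
    rows = []
    for t in range(T):
        for m in range(M):
            rows.append((t, m) + tuple(frames[t, m]))
    return pd.DataFrame(rows, columns=["time_index", "landmark"] + cols)


def _pca_outputs(ds: GroupedDataset, outdir: Path, written: list[Path]) -> None:
    model = TrajectoryPCA().fit(ds)
    ev = model.eigenvalues_
    total = ev.sum()
    spec = pd.DataFrame(
        {
            "mode": np.arange(1, ev.size + 1),
            "eigenvalue": ev,
            "nonzero": np.arange(ev.size) < model.rank_,
            "variance_fraction": ev / total if total > 0 else 0.0 * ev,
            "cumulative_fraction": np.cumsum(ev) / total if total > 0 else 0.0 * ev,
        }
    )
    _write(spec, outdir / "eigenvalues_pca.csv", written)

    scores = model.transform(ds)
    table = pd.DataFrame({"subject": ds.subject_ids, "group": ds.group_ids})
    for l in range(scores.shape[1]):
        table[f"a_{l + 1}"] = scores[:, l]
    std = model.standardize(scores)
    for l in range(std.shape[1]):
        table[f"z_{l + 1}"] = std[:, l]
    recon = model.inverse_transform(scores)
    table["residual_norm"] = np.linalg.norm(ds.X - np.atleast_2d(recon), axis=1)
    _write(table, outdir / "scores_pca.csv", written)


def _mpca_outputs(config: RunConfig, ds: GroupedDataset, outdir: Path, written: list[Path]) -> None:
    model = MultilevelPCA(
        n_components_between=config.m1,
        n_components_within=config.m2,
        zero_tol=config.zero_tol,
    ).fit(ds)
    _write(model.eigen_report(), outdir / "eigenvalues_mpca.csv", written)

    score_set = model.fit_scores(ds)
    _write(score_set.to_frame(), outdir / "scores_mpca.csv", written)
    _write(
        score_set.to_frame()[["subject", "group", "residual_norm"]],
        outdir / "residuals_mpca.csv",
        written,
    )

    for level in (1, 2):
        rank = model.rank_between_ if level == 1 else model.rank_within_
        if rank == 0:
            continue
        tables = []
        for c in MODE_MULTIPLIERS:
            tab = _frame_table(model.mode_trajectory(level, 0, c), ds.M, ds.Dim)
            tab.insert(0, "c", c)
            tables.append(tab)
        _write(
            pd.concat(tables, ignore_index=True),
            outdir / f"mode_mpca_level{level}_mode1.csv",
            written,
        )
        try:
            centroids, seps = centroid_separation(score_set, level)
        except ValueError:
            continue
        if not centroids.columns.size > 1:
            continue
        _write(centroids, outdir / f"centroids_mpca_level{level}.csv", written)
        _write(seps, outdir / f"separations_mpca_level{level}.csv", written)


def _write(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False)
    written.append(path)


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured workflow; returns the output directory.

    On failure every artifact written so far is removed, so a run
    directory is either complete or absent.
    """
    outdir = Path(config.outdir)
    created_dir = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ds = _load_dataset(config)
        if config.model in ("pca", "both"):
            _pca_outputs(ds, outdir, written)
        if config.model in ("mpca", "both"):
            _mpca_outputs(config, ds, outdir, written)
        manifest = {
            "config": {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in vars(config).items()
            },
            "versions": {
                "dynshape": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "artifacts": [p.name for p in written],
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        if created_dir:
            shutil.rmtree(outdir, ignore_errors=True)
        raise
    return outdir
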