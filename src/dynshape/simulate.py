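"""Monte Carlo generators for landmark-trajectory test datasets.

Three seeded generators emulate the package's study conditions:

* ``simulate_sine`` — two groups of univariate sine trajectories with
  periods (2, 1.5), amplitudes (0.5, 0.4) and per-subject Gaussian
  amplitude noise of s.d. 0.03, sampled over one full period of group 1
  ([0, 2] in arbitrary time units). Between-group variation dominates
  within-group variation by roughly two orders of magnitude because
  variance scales with amplitude squared.

* ``simulate_blink`` — 16 2D landmarks delineating an eye boundary (two
  parabolic arcs through shared corner points). Group "blink" closes the
  aperture almost fully at mid-trajectory; group "surprise" opens it
  wider; both return to rest. Per-subject amplitude noise scales each
  subject's whole aperture trajectory, mirroring the sine generator, so
  each class contributes one within-group variation direction.

* ``simulate_smile_like`` — a synthetic stand-in for dynamic 3D mouth
  captures: 12 lip landmarks, ~60 subjects in two sex groups, irregular
  frame counts (100-250). The smile pulls the mouth corners outward and
  backward toward mid-trajectory; a per-subject resting-curvature mode
  makes mouths upturned or downturned (the dominant within-group mode),
  and the between-sex mean offset is small by default. It makes no claim
  about any real capture system.

Every generator is deterministic given its seed; the noiseless structure
is identical across seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trajectory import SubjectTrajectory, write_trajectories

__all__ = [
    "SineWaveConfig",
    "BlinkConfig",
    "SmileLikeConfig",
    "simulate_sine",
    "simulate_blink",
    "simulate_smile_like",
    "simulate",
    "write_simulated",
]


@dataclass
class SineWaveConfig:
    """Two groups of sine trajectories differing in period and amplitude."""

    periods: tuple[float, float] = (2.0, 1.5)
    amplitudes: tuple[float, float] = (0.5, 0.4)
    noise_sd: float = 0.03
    n_per_group: int = 1000
    T: int = 101
    window: float = 2.0          # observation window in the sine's time units
    noise_mode: str = "amplitude"  # "amplitude" (one eps per subject) or "pointwise"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.periods) <= 0 or min(self.amplitudes) <= 0:
            raise ValueError("periods and amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_mode not in ("amplitude", "pointwise"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


def simulate_sine(config: SineWaveConfig) -> list[SubjectTrajectory]:
    """x_i(t) = (A_j + eps_i) * sin(2*pi*t / P_j) on T regular times in [0, window]."""
    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, config.window, config.T)
    out: list[SubjectTrajectory] = []
    for j, (P, A) in enumerate(zip(config.periods, config.amplitudes)):
        base = np.sin(2.0 * np.pi * t / P)
        for i in range(config.n_per_group):
            if config.noise_mode == "amplitude":
                amp = A + rng.normal(0.0, config.noise_sd)
                x = amp * base
            else:
                x = (A + rng.normal(0.0, config.noise_sd, size=config.T)) * base
            out.append(
                SubjectTrajectory(
                    subject_id=f"g{j + 1}s{i:04d}",
                    group_id=f"group{j + 1}",
                    times=t.copy(),
                    landmarks=x.reshape(-1, 1, 1),
                )
            )
    return out


@dataclass
class BlinkConfig:
    """Eye-boundary generator: a blink class and a surprise class."""

    n_points_per_arc: int = 8     # upper + lower arc -> 16 landmarks
    upper_height: float = 0.5
    lower_height: float = 0.3
    half_width: float = 1.0
    blink_min_aperture: float = 0.02   # fraction of rest aperture at closure
    surprise_max_aperture: float = 1.30
    noise_sd: float = 0.03
    n_per_group: int = 10_000
    T: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.blink_min_aperture < 1 < self.surprise_max_aperture:
            raise ValueError("need blink_min_aperture < 1 < surprise_max_aperture")


def _eye_rest(config: BlinkConfig) -> np.ndarray:
    """Rest outline: landmarks 0..7 upper arc, 8..15 lower arc, x ascending."""
    x = np.linspace(-config.half_width, config.half_width, config.n_points_per_arc)
    shape = 1.0 - (x / config.half_width) ** 2
    upper = np.stack([x, config.upper_height * shape], axis=1)
    lower = np.stack([x, -config.lower_height * shape], axis=1)
    return np.vstack([upper, lower])


def simulate_blink(config: BlinkConfig) -> list[SubjectTrajectory]:
    """Two eye-trajectory classes with per-subject aperture-amplitude noise.

    The aperture factor follows f_c(t) = 1 + D_c * sin^2(pi t) with
    D_blink = blink_min_aperture - 1 and D_surprise = surprise_max_aperture - 1,
    so both classes start and end at the rest outline. Subject i's vertical
    coordinates are (1 + eps_i) * f_c(t) * y_rest, eps_i ~ N(0, noise_sd^2).
    """
    rng = np.random.default_rng(config.seed)
    rest = _eye_rest(config)
    t = np.linspace(0.0, 1.0, config.T)
    bump = np.sin(np.pi * t) ** 2
    deform = {
        "blink": config.blink_min_aperture - 1.0,
        "surprise": config.surprise_max_aperture - 1.0,
    }
    out: list[SubjectTrajectory] = []
    for group, D in deform.items():
        f = 1.0 + D * bump                       # (T,)
        for i in range(config.n_per_group):
            amp = 1.0 + rng.normal(0.0, config.noise_sd)
            frames = np.empty((config.T, rest.shape[0], 2))
            frames[:, :, 0] = rest[:, 0]
            frames[:, :, 1] = amp * f[:, None] * rest[None, :, 1]
            out.append(
                SubjectTrajectory(
                    subject_id=f"{group}{i:05d}",
                    group_id=group,
                    times=t.copy(),
                    landmarks=frames,
                )
            )
    return out


@dataclass
class SmileLikeConfig:
    """Synthetic 3D mouth-trajectory generator (smile-like stand-in)."""

    n_male: int = 31
    n_female: int = 29
    T: int = 60                   # analysis grid; raw frame counts are irregular
    frames_range: tuple[int, int] = (100, 250)
    mouth_half_width: float = 3.0
    lip_height: float = 1.0
    smile_widening: float = 0.15      # fractional corner widening at apex
    smile_retraction: float = 0.8     # backward (negative z) corner pull at apex
    curvature_sd: float = 0.25        # within-group upturn/downturn mode
    sex_effect: float = 0.05          # small between-sex widening offset
    amplitude_noise_sd: float = 0.03  # per-subject smile-amplitude noise
    time_jitter: float = 0.2          # fraction of a frame interval
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.frames_range
        if lo < 4 or hi < lo:
            raise ValueError("frames_range must satisfy 4 <= lo <= hi")


def _mouth_rest(config: SmileLikeConfig) -> np.ndarray:
    """12 landmarks on an elliptical lip outline in the z=0 plane."""
    ang = 2.0 * np.pi * np.arange(12) / 12.0
    x = config.mouth_half_width * np.cos(ang)
    y = config.lip_height * np.sin(ang)
    return np.stack([x, y, np.zeros(12)], axis=1)


def _smile_frames(
    config: SmileLikeConfig,
    t01: np.ndarray,
    curvature: float,
    widen_scale: float,
    amp: float,
) -> np.ndarray:
    rest = _mouth_rest(config)
    xn = rest[:, 0] / config.mouth_half_width        # -1..1 across the mouth
    corner_w = xn**2                                  # weight peaking at the corners
    frames = np.empty((t01.size, 12, 3))
    s = np.sin(np.pi * t01) ** 2                      # smile profile, 0 at rest
    for k, sk in enumerate(s):
        pull = amp * sk
        frames[k, :, 0] = rest[:, 0] * (1.0 + (config.smile_widening * widen_scale) * pull * corner_w)
        frames[k, :, 1] = rest[:, 1] + curvature * (xn**2 - 0.5)
        frames[k, :, 2] = rest[:, 2] - config.smile_retraction * pull * corner_w
    return frames


def simulate_smile_like(config: SmileLikeConfig) -> list[SubjectTrajectory]:
    """Irregularly sampled 3D smile-like trajectories for two sex groups."""
    rng = np.random.default_rng(config.seed)
    out: list[SubjectTrajectory] = []
    for group, n_subj, widen_scale in (
        ("male", config.n_male, 1.0 + config.sex_effect),
        ("female", config.n_female, 1.0),
    ):
        for i in range(n_subj):
            n_frames = int(rng.integers(*config.frames_range, endpoint=True))
            base = np.linspace(0.0, 1.0, n_frames)
            step = 1.0 / (n_frames - 1)
            jitter = rng.uniform(
                -config.time_jitter * step, config.time_jitter * step, n_frames - 2
            )
            times = base.copy()
            times[1:-1] += jitter
            times.sort()
            curvature = rng.normal(0.0, config.curvature_sd)
            amp = 1.0 + rng.normal(0.0, config.amplitude_noise_sd)
            frames = _smile_frames(config, times, curvature, widen_scale, amp)
            out.append(
                SubjectTrajectory(
                    subject_id=f"{group}{i:03d}",
                    group_id=group,
                    times=times,
                    landmarks=frames,
                )
            )
    return out


_SIMULATORS = {
    "sine": (SineWaveConfig, simulate_sine),
    "blink": (BlinkConfig, simulate_blink),
    "smile": (SmileLikeConfig, simulate_smile_like),
}


def simulate(name: str, **overrides) -> list[SubjectTrajectory]:
    """Run a named simulator ("sine", "blink", "smile") with overrides."""
    try:
        cfg_cls, fn = _SIMULATORS[name]
    except KeyError:
        raise ValueError(f"unknown simulator {name!r}; choose from {sorted(_SIMULATORS)}")
    return fn(cfg_cls(**overrides))


def write_simulated(name: str, out_csv, **overrides) -> Path:
    """Simulate and write trajectory CSV plus a YAML sidecar of the config."""
    cfg_cls, fn = _SIMULATORS[name]
    config = cfg_cls(**overrides)
    trajs = fn(config)
    out_csv = Path(out_csv)
    write_trajectories(trajs, out_csv)
    sidecar = out_csv.with_suffix(out_csv.suffix + ".config.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"simulator": name, **asdict(config)}, fh, sort_keys=True)
    return sidecar
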