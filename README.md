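# dynshape — multilevel PCA of dynamical landmark-shape trajectories

`dynshape` models *changes in biological shape over time* — an eye
blinking, a mouth smiling, a signal oscillating — when the subjects fall
into groups (expression classes, sexes, scanner cohorts). Each subject is
a sequence of frames of M landmarks in 1–3 dimensions with (possibly
irregular) time stamps. The package spline-resamples every subject onto T
regular time points, flattens the result into a feature vector of length
`Dim × M × T`, and decomposes the sample two ways:

* **single-level trajectory PCA** (`TrajectoryPCA`): eigendecompose

  `K = 1/(n−1) Σᵢ (Xᵢ − η)(Xᵢ − η)ᵀ`,  `η = mean(Xᵢ)`,

  giving modes of variation ψ_l with eigenvalues θ_l and component scores
  `a_l = (X − η)·ψ_l`, standardized as `a_l/√θ_l`;

* **two-level multilevel PCA / between-group PCA** (`MultilevelPCA`): a
  separate PCA of the *between-group* covariance of the p group means
  about the grand mean `η = 1/p Σⱼ ηʲ` (level 1, divisor p−1, rank ≤ p−1)
  and of the pooled *within-group* covariance
  `K² = 1/p Σⱼ K²ʲ` (level 2, per-group divisor nⱼ−1). A trajectory is
  expanded as `X ≈ η + Σ a_l¹ψ_l¹ + Σ a_l²ψ_l²` with the scores fitted
  jointly by least squares.

When n < L the covariance is never materialized: the snapshot
(inner-product) method recovers the identical nonzero spectrum from the
n × n Gram matrix. Seeded Monte Carlo generators (sine waves, an eye-blink
/ surprise dataset of 16 2D boundary points, and a smile-like 3D mouth
stand-in) provide end-to-end validation data, and a CLI
(`dynshape simulate|fit|report|run`) exports eigen spectra, score tables,
centroid separations, mode trajectories and residuals as delimited text.

## Worked example

```python
import numpy as np
from dynshape import (SineWaveConfig, TimeGrid, assemble_dataset,
                      fit_mpca, simulate_sine)

# two groups of sine trajectories: periods (2, 1.5), amplitudes (0.5, 0.4),
# per-subject amplitude noise sd 0.03, T = 101 regular time points
trajs = simulate_sine(SineWaveConfig(n_per_group=1000, seed=2))
ds = assemble_dataset(trajs, TimeGrid(101))
model = fit_mpca(ds)

print("nonzero eigenvalues, level 1:", model.rank_between_)
print("nonzero eigenvalues, level 2:", model.rank_within_)
print("leading eigenvalues:",
      round(model.eigenvalues_between_[0], 3),
      round(model.eigenvalues_within_[0], 4))
```

prints

```
nonzero eigenvalues, level 1: 1
nonzero eigenvalues, level 2: 2
leading eigenvalues: 6.896 0.031
```

With two groups the between-group covariance has a single nonzero
eigenvalue (rank ≤ p−1 = 1); its magnitude (≈6.9) exceeds the leading
within-group eigenvalue (≈0.03) by more than two orders of magnitude,
exactly mirroring how the generator was built: the group difference in
period/amplitude dwarfs the 0.03 amplitude noise. The two nonzero level-2
eigenvalues are the two groups' amplitude-noise directions.

The same workflow from the shell:

```sh
dynshape run --simulator sine --outdir runs/sine --t 101 --seed 2
```

writes `eigenvalues_mpca.csv`, `scores_mpca.csv` (raw + standardized, with
group labels), group centroids and separations, mode-trajectory frame
tables at c ∈ {−1.96, 0, +1.96}, per-subject residuals and a YAML
manifest that reproduces the run byte-for-byte.

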