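"""Two-level mPCA: covariance construction, score fitting, modes, report."""

import warnings

import numpy as np
import pytest

from dynshape import (
    DegenerateModeError,
    MultilevelPCA,
    centroid_separation,
    fit_mpca,
    mode_trajectory,
    mpca_fit_scores,
)


def brute_force_mpca(X, labels, weighting="equal"):
    """Independent oracle: explicit double-loop level-1/level-2 covariances."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    p = len(groups)
    L = X.shape[1]
    n = X.shape[0]
    means = {}
    K2 = np.zeros((L, L))
    for g in groups:
        Xg = X[labels == g]
        nj = Xg.shape[0]
        means[g] = Xg.mean(axis=0)
        Kg = np.zeros((L, L))
        for i in range(nj):
            d = Xg[i] - means[g]
            Kg += np.outer(d, d)
        Kg /= nj - 1
        K2 += Kg / p if weighting == "equal" else Kg * nj / n
    grand = sum(means.values()) / p
    K1 = np.zeros((L, L))
    for g in groups:
        d = means[g] - grand
        K1 += np.outer(d, d)
    K1 /= p - 1
    return grand, means, K1, K2


def model_cov(vals, comps):
    return (comps.T * vals) @ comps


class TestFit:
    def test_two_point_hand_computation(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        y = ["a", "a", "b", "b"]
        model = MultilevelPCA().fit(X, y)
        np.testing.assert_allclose(model.eigenvalues_within_, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.grand_mean_, [1.0, 0.0])
        np.testing.assert_allclose(model.eigenvalues_between_, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(model.components_between_[0], [1.0, 0.0], atol=1e-12)
        assert model.rank_between_ == 1 and model.rank_within_ == 0

    @pytest.mark.parametrize("weighting", ["equal", "size"])
    def test_matches_brute_force_oracle(self, rng, weighting):
        X = rng.normal(size=(17, 9))
        labels = np.array(["a"] * 4 + ["b"] * 6 + ["c"] * 7)
        grand, means, K1, K2 = brute_force_mpca(X, labels, weighting)
        model = MultilevelPCA(within_weighting=weighting).fit(X, labels)
        np.testing.assert_allclose(model.grand_mean_, grand, atol=1e-12)
        for j, g in enumerate(model.groups_):
            np.testing.assert_allclose(model.group_means_[j], means[g], atol=1e-12)
        np.testing.assert_allclose(
            model_cov(model.eigenvalues_between_, model.components_between_),
            K1,
            atol=1e-10,
        )
        np.testing.assert_allclose(
            model_cov(model.eigenvalues_within_, model.components_within_),
            K2,
            atol=1e-10,
        )

    def test_weighting_options_differ_on_unbalanced_groups(self, rng):
        X = rng.normal(size=(30, 4))
        X[20:] *= 3.0
        labels = np.array(["a"] * 20 + ["b"] * 10)
        eq = MultilevelPCA(within_weighting="equal").fit(X, labels)
        ml = MultilevelPCA(within_weighting="size").fit(X, labels)
        assert not np.allclose(
            eq.eigenvalues_within_[0], ml.eigenvalues_within_[0]
        )

    def test_level1_rank_bounded_by_p_minus_1(self, rng):
        for trial in range(5):
            p = int(rng.integers(2, 6))
            sizes = rng.integers(2, 6, size=p)
            X = rng.normal(size=(sizes.sum(), 12))
            labels = np.repeat([f"g{j}" for j in range(p)], sizes)
            model = MultilevelPCA().fit(X, labels)
            assert model.rank_between_ <= p - 1

    def test_grand_mean_is_unweighted_even_when_unbalanced(self, rng):
        X = rng.normal(size=(12, 3))
        labels = np.array(["a"] * 10 + ["b"] * 2)
        model = MultilevelPCA().fit(X, labels)
        expected = 0.5 * (X[:10].mean(axis=0) + X[10:].mean(axis=0))
        np.testing.assert_allclose(model.grand_mean_, expected, atol=1e-12)
        assert not np.allclose(model.grand_mean_, X.mean(axis=0))

    def test_label_permutation_leaves_spectra_unchanged(self, rng):
        X = rng.normal(size=(18, 6))
        labels = np.repeat(["a", "b", "c"], 6)
        base = MultilevelPCA().fit(X, labels)
        swapped = np.char.translate(labels, str.maketrans("abc", "bca"))
        perm = MultilevelPCA().fit(X, swapped)
        np.testing.assert_allclose(
            base.eigenvalues_between_, perm.eigenvalues_between_, atol=1e-10
        )
        np.testing.assert_allclose(
            base.eigenvalues_within_, perm.eigenvalues_within_, atol=1e-10
        )

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(14, 5))
        labels = np.repeat(["a", "b"], 7)
        base = MultilevelPCA().fit(X, labels)
        scaled = MultilevelPCA().fit(3.0 * X, labels)
        np.testing.assert_allclose(
            scaled.eigenvalues_between_, 9.0 * base.eigenvalues_between_, atol=1e-8
        )
        np.testing.assert_allclose(
            scaled.eigenvalues_within_, 9.0 * base.eigenvalues_within_, atol=1e-8
        )

    def test_identical_group_means_kill_level1(self, rng):
        A = rng.normal(size=(8, 4))
        B = rng.normal(size=(8, 4)) * 2.0
        A -= A.mean(axis=0)
        B -= B.mean(axis=0)
        model = MultilevelPCA().fit(
            np.vstack([A, B]), ["a"] * 8 + ["b"] * 8
        )
        np.testing.assert_allclose(model.eigenvalues_between_, 0.0, atol=1e-12)
        assert model.rank_within_ > 0

    def test_each_subject_its_own_group_runs(self, rng):
        # nested reading: singleton groups contribute no within variation
        X = rng.normal(size=(6, 4))
        labels = [f"s{i}" for i in range(6)]
        with pytest.warns(UserWarning, match="single subject"):
            model = MultilevelPCA().fit(X, labels)
        np.testing.assert_allclose(model.eigenvalues_within_, 0.0, atol=1e-12)
        assert model.rank_between_ <= 5

    def test_single_group_is_an_error(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            MultilevelPCA().fit(rng.normal(size=(5, 3)), ["only"] * 5)

    def test_orthonormal_within_each_level(self, rng):
        X = rng.normal(size=(20, 10))
        labels = np.repeat(["a", "b", "c", "d"], 5)
        model = MultilevelPCA().fit(X, labels)
        for comps, rank in (
            (model.components_between_, model.rank_between_),
            (model.components_within_, model.rank_within_),
        ):
            G = comps[:rank] @ comps[:rank].T
            np.testing.assert_allclose(G, np.eye(rank), atol=1e-8)


class TestScoreFitting:
    @pytest.fixture
    def model(self, rng):
        X = rng.normal(size=(20, 8))
        X[10:] += 4.0
        return MultilevelPCA().fit(X, ["a"] * 10 + ["b"] * 10)

    def test_grand_mean_gives_zero_scores(self, model):
        ss = mpca_fit_scores(model, model.grand_mean_)
        np.testing.assert_allclose(ss.between, 0.0, atol=1e-10)
        np.testing.assert_allclose(ss.within, 0.0, atol=1e-10)
        np.testing.assert_allclose(ss.residual_norm, 0.0, atol=1e-10)

    def test_recovers_constructed_scores(self, model):
        psi1 = model.components_between_[0]
        psi2 = model.components_within_[0]
        assert abs(psi1 @ psi2) < 0.99  # not parallel
        x = model.grand_mean_ + 2.0 * psi1 + 5.0 * psi2
        scores = model.transform(x)
        # normal-equations oracle on the concatenated mode matrix
        Psi = np.column_stack(
            [model.components_between_[: model.m1_].T, model.components_within_[: model.m2_].T]
        )
        oracle = np.linalg.solve(Psi.T @ Psi, Psi.T @ (x - model.grand_mean_))
        np.testing.assert_allclose(scores.ravel(), oracle, atol=1e-8)
        np.testing.assert_allclose(scores[0, 0], 2.0, atol=1e-8)
        np.testing.assert_allclose(scores[0, model.m1_], 5.0, atol=1e-8)

    def test_fit_is_residual_optimal(self, model, rng):
        x = rng.normal(size=8)
        ss = mpca_fit_scores(model, x)
        best = ss.residual_norm[0]
        Psi = np.column_stack(
            [model.components_between_[: model.m1_].T, model.components_within_[: model.m2_].T]
        )
        a0 = np.concatenate([ss.between[0], ss.within[0]])
        for _ in range(100):
            a = a0 + rng.normal(scale=0.1, size=a0.size)
            rival = np.linalg.norm(x - model.grand_mean_ - Psi @ a)
            assert best <= rival + 1e-12

    def test_length_mismatch(self, model):
        with pytest.raises(ValueError, match="length"):
            model.transform(np.ones(7))


class TestStandardizationAndSeparation:
    def test_unit_standardized_score(self, rng):
        X = rng.normal(size=(12, 5))
        X[6:] += 2.0
        model = MultilevelPCA().fit(X, ["a"] * 6 + ["b"] * 6)
        a = np.array([np.sqrt(model.eigenvalues_between_[0])])
        np.testing.assert_allclose(model.standardize(a, level=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            model.standardize(np.zeros(1), level=2), 0.0, atol=1e-12
        )

    def test_too_many_modes_requested(self, rng):
        X = rng.normal(size=(12, 5))
        X[6:] += 2.0
        model = MultilevelPCA().fit(X, ["a"] * 6 + ["b"] * 6)
        with pytest.raises(DegenerateModeError):
            model.standardize(np.ones(2), level=1)  # only p-1 = 1 nonzero

    def test_blink_separation_level1_exceeds_level2(self, blink_small):
        from dynshape import BlinkConfig, TimeGrid, assemble_dataset, simulate_blink

        model = fit_mpca(blink_small)
        test = assemble_dataset(
            simulate_blink(BlinkConfig(n_per_group=120, T=31, seed=8)), TimeGrid(31)
        )
        ss = model.fit_scores(test)
        _, sep1 = centroid_separation(ss, 1)
        _, sep2 = centroid_separation(ss, 2)
        s1 = sep1["separation"].iloc[0]
        s2 = sep2["separation"].iloc[0]
        assert 0.3 < s1 < 5.0  # of order one
        assert s1 > s2  # level-2 centroids congruent


class TestModes:
    @pytest.fixture
    def model(self, sine_small):
        return fit_mpca(sine_small)

    def test_c_zero_is_grand_mean(self, model):
        np.testing.assert_array_equal(
            mode_trajectory(model, 1, 0, 0.0), model.grand_mean_
        )

    def test_affine_in_c(self, model):
        t0 = mode_trajectory(model, 1, 0, 0.0)
        t1 = mode_trajectory(model, 1, 0, 1.0)
        t2 = mode_trajectory(model, 1, 0, 2.0)
        np.testing.assert_allclose(t2 - t1, t1 - t0, atol=1e-10)

    def test_degenerate_mode_error(self, model):
        with pytest.raises(DegenerateModeError):
            model.mode_trajectory(1, 1, 1.0)  # only one nonzero level-1 mode

    def test_mode_frames_shape(self, model):
        frames = model.mode_frames(2, 0, 1.96)
        assert frames.shape == (101, 1, 1)


class TestEigenReport:
    def test_blink_counts(self, blink_small):
        model = fit_mpca(blink_small)
        report = model.eigen_report()
        counts = report.groupby("level")["nonzero"].sum()
        assert counts[1] == 1
        assert counts[2] == 2

    def test_degenerate_dataset_counts_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (8, 1))
        model = MultilevelPCA().fit(X, ["a"] * 4 + ["b"] * 4)
        report = model.eigen_report()
        assert report["nonzero"].sum() == 0


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(12, 6))
        model = MultilevelPCA().fit(X, ["a"] * 6 + ["b"] * 6)
        path = tmp_path / "mpca.npz"
        model.save(path)
        back = MultilevelPCA.load(path)
        np.testing.assert_array_equal(back.grand_mean_, model.grand_mean_)
        np.testing.assert_array_equal(back.group_means_, model.group_means_)
        np.testing.assert_array_equal(
            back.eigenvalues_between_, model.eigenvalues_between_
        )
        np.testing.assert_array_equal(
            back.components_within_, model.components_within_
        )
        assert back.groups_ == model.groups_
        assert back.m1_ == model.m1_ and back.m2_ == model.m2_
        x = rng.normal(size=6)
        np.testing.assert_allclose(
            back.transform(x), model.transform(x), atol=1e-12
        )
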