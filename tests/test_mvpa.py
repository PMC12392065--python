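"""Crossnobis distances, decoding, permutation inference, combination."""

import numpy as np
import pytest
from scipy import stats

from mifind import mvpa
from mifind.datasets import DistanceMatrix, PatternDataset
from mifind.simulate import null_spec, simulate_pattern_dataset, simulate_pattern_study


def dataset_from_means(run_means, n_res=60, noise_sd=0.0, rng=None):
    """Dataset whose per-run condition means are given exactly.

    ``run_means``: (runs, conditions, voxels).  One trial per condition
    so condition means equal the supplied patterns when noise_sd = 0.
    """
    run_means = np.asarray(run_means, dtype=float)
    m, k, p = run_means.shape
    betas = run_means[:, :, None, :].copy()
    if noise_sd:
        betas = betas + rng.normal(0.0, noise_sd, size=betas.shape)
    residuals = (rng or np.random.default_rng(0)).normal(0.0, 1.0, size=(m, n_res, p))
    conditions = tuple(f"c{i}" for i in range(k))
    return PatternDataset(betas=betas, residuals=residuals, conditions=conditions)


class TestShrinkCovariance:
    def test_converges_to_identity_for_iid_noise(self, rng):
        X = rng.standard_normal((4000, 12))
        sigma, lam = mvpa.shrink_covariance(X)
        assert np.abs(sigma - np.eye(12)).max() < 0.12
        assert 0.0 <= lam <= 1.0

    def test_duplicate_samples_still_pd(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1))
        X[0, 0] += 1e-3  # not exactly constant, still rank-deficient
        sigma, _ = mvpa.shrink_covariance(X)
        np.linalg.cholesky(sigma)  # must not raise

    def test_recovers_known_covariance(self, rng):
        truth = np.array([[2.0, 0.8], [0.8, 1.0]])
        X = rng.multivariate_normal(np.zeros(2), truth, size=20000)
        sigma, _ = mvpa.shrink_covariance(X)
        assert np.abs(sigma - truth).max() < 0.08

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mvpa.shrink_covariance(np.ones((1, 3)))


def brute_force_crossnobis(w, i, j):
    """Literal double sum over ordered fold pairs on whitened patterns."""
    m, _, p = w.shape
    total = 0.0
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            total += float((w[a, i] - w[a, j]) @ (w[b, i] - w[b, j]))
    return total / (m * (m - 1) * p)


class TestCrossnobis:
    def test_identical_patterns_give_zero(self, rng):
        # every condition carries the same pattern in every run
        one = rng.standard_normal((4, 1, 8))
        pattern = np.repeat(one, 3, axis=1)
        ds = dataset_from_means(pattern, rng=rng)
        dm = mvpa.crossnobis(ds, sigma=np.eye(8))
        assert np.allclose(dm.values, 0.0, atol=1e-12)

    def test_hand_expansion_two_runs_two_voxels(self):
        # fully written-out computation on a 2-run, 2-voxel dataset with
        # identity noise: d = (w11-w21).(w12-w22) / (M(M-1)P), M=2, P=2
        run_means = np.array([
            [[1.0, 2.0], [0.0, 1.0]],    # run 1: cond A, cond B
            [[2.0, 1.0], [1.0, -1.0]],   # run 2
        ])
        ds = dataset_from_means(run_means)
        d = mvpa.crossnobis(ds, sigma=np.eye(2)).pair("c0", "c1")
        # delta run1 = (1,1), delta run2 = (1,2); sum over ordered pairs
        # = 2 * (1*1 + 1*2) = 6; denominator 2*1*2 = 4
        assert d == pytest.approx(6.0 / 4.0, abs=1e-12)

    def test_matches_brute_force_on_random_data(self, rng):
        run_means = rng.standard_normal((5, 3, 7))
        ds = dataset_from_means(run_means, rng=rng)
        sigma = np.eye(7)
        dm = mvpa.crossnobis(ds, sigma=sigma)
        for i in range(3):
            for j in range(i + 1, 3):
                assert dm.values[i, j] == pytest.approx(
                    brute_force_crossnobis(run_means, i, j), abs=1e-12)

    def test_noiseless_equals_scaled_mahalanobis(self, rng):
        # identical runs: crossnobis = squared Mahalanobis distance of the
        # generating means divided by the voxel count
        p = 6
        mu = rng.standard_normal((3, p))
        sigma = np.diag(rng.uniform(0.5, 2.0, size=p))
        ds = dataset_from_means(np.tile(mu[None], (4, 1, 1)), rng=rng)
        dm = mvpa.crossnobis(ds, sigma=sigma)
        inv = np.linalg.inv(sigma)
        for i in range(3):
            for j in range(i + 1, 3):
                diff = mu[i] - mu[j]
                assert dm.values[i, j] == pytest.approx(
                    float(diff @ inv @ diff) / p, rel=1e-9)

    def test_whitening_equivariance(self, rng):
        # an invertible linear voxel transform applied to betas and
        # residuals alike leaves the distances unchanged
        spec = null_spec(n_voxels=10, trials_per_finger_imagery=8,
                         residual_factor=20)
        ds, _ = simulate_pattern_dataset(spec, rng)
        A = rng.standard_normal((10, 10)) + 0.5 * np.eye(10)
        ds_rot = PatternDataset(betas=ds.betas @ A.T,
                                residuals=ds.residuals @ A.T,
                                conditions=ds.conditions)
        sigma, _ = mvpa.shrink_covariance(ds.pooled_residuals())
        d_orig = mvpa.crossnobis(ds, sigma=sigma).off_diagonal()
        d_rot = mvpa.crossnobis(
            ds_rot, sigma=A @ sigma @ A.T).off_diagonal()
        np.testing.assert_allclose(d_rot, d_orig, rtol=1e-8)

    def test_single_run_rejected(self, rng):
        ds = dataset_from_means(rng.standard_normal((1, 3, 4)), rng=rng)
        with pytest.raises(ValueError):
            mvpa.crossnobis(ds, sigma=np.eye(4))

    def test_signal_monotonicity(self):
        # mean distance grows with the generating signal scale
        means = []
        for scale in (0.0, 0.3, 0.6):
            spec = null_spec(n_voxels=20, trials_per_finger_imagery=16,
                             residual_factor=5)
            spec = type(spec)(**{**spec.__dict__, "signal_scale_pre": scale})
            vals = []
            for seed in range(30):
                ds, _ = simulate_pattern_dataset(spec, np.random.default_rng(seed))
                vals.append(mvpa.avg_interfinger(mvpa.crossnobis(ds)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAvgInterfinger:
    def test_mean_of_three_pairs(self):
        vals = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        dm = DistanceMatrix(conditions=("a", "b", "c"), values=vals)
        assert mvpa.avg_interfinger(dm) == pytest.approx(2.0)

    def test_all_zero(self):
        dm = DistanceMatrix(conditions=("a", "b", "c"), values=np.zeros((3, 3)))
        assert mvpa.avg_interfinger(dm) == 0.0


class TestScaling:
    def test_train_standardized_exactly(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 4))
        scaler = mvpa.zscale(X)
        Z = mvpa.apply_scaler(scaler, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_guard(self, rng):
        X = np.column_stack([np.full(20, 5.0), rng.standard_normal(20)])
        Z = mvpa.apply_scaler(mvpa.zscale(X), X)
        assert np.all(np.isfinite(Z))
        np.testing.assert_allclose(Z[:, 0], 0.0)

    def test_transform_uses_training_parameters(self, rng):
        train = rng.normal(0.0, 1.0, size=(30, 3))
        test = train + 10.0
        scaler = mvpa.zscale(train)
        Z = mvpa.apply_scaler(scaler, test)
        np.testing.assert_allclose(
            Z, mvpa.apply_scaler(scaler, train) + 10.0 / scaler.scale_)


def separable_xy(rng, n_per=10, runs=4, gap=8.0):
    """Linearly separable 3-class run-structured data."""
    centers = gap * np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    X, y = [], []
    for _r in range(runs):
        for c in range(3):
            X.append(centers[c] + rng.standard_normal((n_per, 3)))
            y += [f"c{c}"] * n_per
    runs_vec = np.repeat(np.arange(runs), 3 * n_per)
    return np.vstack(X), np.array(y), runs_vec


class TestDecoding:
    def test_separable_data_perfect_loro(self, rng):
        X, y, runs = separable_xy(rng)
        assert mvpa.loro_cv(X, y, runs) == 100.0

    def test_label_shuffle_collapses_to_chance(self, rng):
        X, y, runs = separable_xy(rng, n_per=12)
        accs = [mvpa.loro_cv(X, rng.permutation(y), runs) for _ in range(20)]
        assert abs(np.mean(accs) - 100.0 / 3.0) < 6.0

    def test_cross_task_transfer_depends_on_shared_component(self):
        def transfer(shared):
            spec = null_spec(n_voxels=20, trials_per_finger_imagery=16,
                             trials_per_finger_execution=12, residual_factor=5)
            spec = type(spec)(**{**spec.__dict__,
                                 "signal_scale_pre": 1.0,
                                 "signal_scale_post": 1.0,
                                 "shared_exec_imagery": shared})
            accs = []
            for seed in range(10):
                datasets, _ = simulate_pattern_study(spec, np.random.default_rng(seed))
                Xe, ye, _ = datasets[("execution", "pre")].trials_xy()
                Xi, yi, _ = datasets[("imagery", "pre")].trials_xy()
                accs.append(mvpa.cross_task(Xe, ye, Xi, yi))
            return np.mean(accs)

        assert transfer(1.0) > 80.0
        assert abs(transfer(0.0) - 100.0 / 3.0) < 8.0

    def test_cross_task_deterministic(self, rng):
        X, y, runs = separable_xy(rng)
        Xt, yt, _ = separable_xy(np.random.default_rng(1))
        a1 = mvpa.cross_task(X, y, Xt, yt)
        a2 = mvpa.cross_task(X, y, Xt, yt)
        assert a1 == a2


class TestPermutationInference:
    def test_null_preserves_class_counts(self, rng):
        y = np.array(["a"] * 5 + ["b"] * 3)
        pred = np.array(["a"] * 8)
        null = mvpa.permutation_null(pred, y, n_perm=50, rng=rng)
        # constant predictions + count-preserving shuffles: accuracy fixed
        np.testing.assert_allclose(null, 100.0 * 5 / 8)

    def test_empirical_p_formula(self, rng):
        null = np.linspace(0.0, 50.0, 1000)
        assert mvpa.empirical_p(60.0, null) == pytest.approx(1.0 / 1001.0)
        assert mvpa.empirical_p(-1.0, null) == 1.0

    def test_refit_scope_runs(self, rng):
        X, y, runs = separable_xy(rng, n_per=4, runs=3)
        null = mvpa.permutation_null_refit(X, y, runs, n_perm=5, rng=rng)
        assert null.shape == (5,)
        assert np.all((0.0 <= null) & (null <= 100.0))

    def test_bad_nperm_rejected(self, rng):
        with pytest.raises(ValueError):
            mvpa.permutation_null(np.array(["a"]), np.array(["a"]), n_perm=0)


class TestFisherAndFdr:
    def test_all_ones(self):
        stat, df, p = mvpa.fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and df == 6 and p == pytest.approx(1.0)

    def test_two_marginal_p_values(self):
        stat, df, p = mvpa.fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(11.983, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0175, abs=2e-4)

    def test_order_invariance_and_scipy_agreement(self, rng):
        ps = rng.uniform(0.01, 1.0, size=6)
        stat1, _, p1 = mvpa.fisher_combine(ps)
        stat2, _, p2 = mvpa.fisher_combine(ps[::-1])
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)
        ref_stat, ref_p = stats.combine_pvalues(ps, method="fisher")
        assert stat1 == pytest.approx(float(ref_stat))
        assert p1 == pytest.approx(float(ref_p))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mvpa.fisher_combine([0.0, 0.5])

    def test_bh_fdr_against_brute_force(self, rng):
        def brute(p):
            # literal step-up: sort, scale by n/rank, enforce monotone
            p = np.asarray(p, dtype=float)
            n = p.size
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * n / rank)
                adj[idx] = running
            return adj

        for _ in range(25):
            p = rng.uniform(0.0001, 1.0, size=int(rng.integers(1, 12)))
            np.testing.assert_allclose(mvpa.bh_fdr(p), brute(p), atol=1e-12)

    def test_single_and_equal_p(self):
        np.testing.assert_allclose(mvpa.bh_fdr([0.04]), [0.04])
        np.testing.assert_allclose(mvpa.bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)
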