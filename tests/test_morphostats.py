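"""PCA, multivariate regression, trajectory angles, PLS, age groups."""

import numpy as np
import pytest

from craniogrow.morphostats import (DEFAULT_AGE_GROUP_EDGES,
                                    assign_age_groups, form_matrix,
                                    group_means, multivariate_regression,
                                    pca, trajectory_angle_test,
                                    two_block_pls, warp_along_regression)


class TestPCA:
    def test_single_direction_pc1_is_everything(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        res = pca(X)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(20, 6))
        res = pca(X)
        assert np.abs(res.reconstruct() - X).max() < 1e-8

    def test_fractions_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 8)) * rng.uniform(0.5, 3, size=8)
        res = pca(X)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        evals = evals[:len(res.variance_fractions)]
        assert np.allclose(res.variance_fractions, evals / evals.sum(),
                           atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        res = pca(rng.normal(size=(15, 5)))
        eye = res.loadings.T @ res.loadings
        assert np.abs(eye - np.eye(len(eye))).max() < 1e-10

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((5, 3)))


class TestRegression:
    def test_exact_affine_r2_one(self, rng):
        x = rng.normal(size=25)
        Y = np.outer(x, [2.0, -1.0, 0.5]) + [1, 2, 3]
        res = multivariate_regression(Y, x, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_single_column_matches_pearson(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        res = multivariate_regression(y[:, None], x, n_perm=0)
        r = np.corrcoef(x, y)[0, 1]
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-10)

    def test_prediction_at_mean_is_mean(self, rng):
        Y = rng.normal(size=(20, 4))
        x = rng.normal(size=20)
        res = multivariate_regression(Y, x, n_perm=0)
        assert np.allclose(res.predict(x.mean()), Y.mean(axis=0),
                           atol=1e-10)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            multivariate_regression(rng.normal(size=(5, 2)), np.ones(5),
                                    n_perm=0)

    def test_permutation_p_reproducible_and_order_invariant(self, rng):
        Y = rng.normal(size=(30, 5))
        x = rng.normal(size=30)
        p1 = multivariate_regression(Y, x, n_perm=200, seed=7).p_value
        p2 = multivariate_regression(Y, x, n_perm=200, seed=7).p_value
        assert p1 == p2
        perm = rng.permutation(30)
        p3 = multivariate_regression(Y[perm], x[perm], n_perm=200,
                                     seed=7).p_value
        assert abs(p3 - p1) < 0.1  # same null distribution, same scale


class TestTrajectoryAngle:
    def test_identical_groups_zero_angle(self, rng):
        x = rng.normal(size=20)
        Y = np.outer(x, rng.normal(size=6)) + rng.normal(size=(20, 6)) * .01
        res = trajectory_angle_test(Y, x, Y.copy(), x.copy(), n_perm=50,
                                    seed=1)
        assert res.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_vectors_90_degrees(self, rng):
        x = rng.normal(size=40)
        Ya = np.outer(x, [1.0, 0.0])
        Yb = np.outer(x, [0.0, 1.0])
        res = trajectory_angle_test(Ya, x, Yb, x, n_perm=50, seed=1)
        assert res.angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_angle_bounds_and_p_range(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            Ya, Yb = r.normal(size=(15, 4)), r.normal(size=(15, 4))
            xa, xb = r.normal(size=15), r.normal(size=15)
            res = trajectory_angle_test(Ya, xa, Yb, xb, n_perm=99,
                                        seed=seed)
            assert 0 <= res.angle_deg <= 180
            assert 0 < res.p_value <= 1


class TestPLS:
    def test_noise_free_projection_r1(self, rng):
        # project block 1 on a principal direction of its own covariance,
        # so the PLS axis coincides with the projection direction exactly
        X = rng.normal(size=(30, 6))
        Xc = X - X.mean(axis=0)
        w = np.linalg.eigh(Xc.T @ Xc)[1][:, -1]
        Y = np.outer(X @ w, [1.0, 0.5])
        res = two_block_pls(X, Y, n_perm=0)
        assert res.score_correlations[0] == pytest.approx(1.0, abs=1e-9)

    def test_covariance_percent_sums_100(self, rng):
        res = two_block_pls(rng.normal(size=(25, 7)),
                            rng.normal(size=(25, 4)), n_perm=0)
        assert res.covariance_percent.sum() == pytest.approx(100.0,
                                                             abs=1e-9)

    def test_axis1_matches_brute_force_oracle(self, rng):
        """Axis-1 weights maximise score covariance; verified against a
        random-search optimiser over unit weight pairs on a 4x3 toy."""
        X = rng.normal(size=(12, 4))
        Y = rng.normal(size=(12, 3))
        res = two_block_pls(X, Y, n_perm=0)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)

        def cov(u, v):
            return abs((Xc @ u) @ (Yc @ v)) / (len(X) - 1)

        best = cov(res.x_weights[:, 0], res.y_weights[:, 0])
        r = np.random.default_rng(0)
        for _ in range(20000):
            u = r.normal(size=4)
            v = r.normal(size=3)
            c = cov(u / np.linalg.norm(u), v / np.linalg.norm(v))
            assert c <= best + 1e-9
        assert best == pytest.approx(res.singular_values[0], rel=1e-9)

    def test_permutation_p_significant_for_dependent_blocks(self, rng):
        X = rng.normal(size=(40, 5))
        Y = X[:, :2] + rng.normal(size=(40, 2)) * 0.1
        res = two_block_pls(X, Y, n_perm=199, seed=3)
        assert res.p_value <= 0.01

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            two_block_pls(np.ones((5, 2)), np.ones((5, 2)))


class TestAgeGroups:
    def test_default_scheme_has_9_bins(self):
        assert len(DEFAULT_AGE_GROUP_EDGES) - 1 == 9
        ages = np.linspace(0.01, 47.9, 300)
        assert len(np.unique(assign_age_groups(ages))) == 9

    def test_oldest_female_age_in_last_group(self):
        months = 1357 / 30.41  # ~44.62 months
        assert months == pytest.approx(44.62, abs=0.005)
        assert assign_age_groups([months])[0] == 8

    def test_edge_is_upper_inclusive(self):
        assert assign_age_groups([12.0])[0] == 4  # (9, 12]
        assert assign_age_groups([12.0001])[0] == 5
        assert assign_age_groups([0.0])[0] == 0

    def test_out_of_coverage_rejected(self):
        with pytest.raises(ValueError):
            assign_age_groups([49.0])

    def test_group_means_by_sex(self, rng):
        scores = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        sexes = np.where(rng.random(30) < 0.5, "F", "M")
        gm = group_means(scores, labels, sexes)
        lbl, sx = gm.index[0]
        mask = (labels == lbl) & (sexes == sx)
        assert np.allclose(gm.iloc[0].to_numpy(),
                           scores[mask].mean(axis=0))


class TestWarp:
    def test_mean_covariate_returns_scaled_mean_shape(self, rng):
        x = rng.normal(size=20) + 5
        Y = np.outer(x, rng.normal(size=9)) + rng.normal(size=(20, 9)) * .1
        reg = multivariate_regression(Y, x, n_perm=0)
        out = warp_along_regression(reg, float(x.mean()), ln_cs=0.0)
        assert np.allclose(out.reshape(-1), Y.mean(axis=0), atol=1e-9)

    def test_affine_in_covariate(self, rng):
        x = rng.normal(size=15)
        Y = rng.normal(size=(15, 6))
        reg = multivariate_regression(Y, x, n_perm=0)
        lo, hi = float(x.min()), float(x.max())
        mid = warp_along_regression(reg, (lo + hi) / 2, ln_cs=0.0)
        ends = (warp_along_regression(reg, lo, ln_cs=0.0)
                + warp_along_regression(reg, hi, ln_cs=0.0)) / 2
        assert np.abs(mid - ends).max() < 1e-10

    def test_extrapolation_warns(self, rng):
        x = rng.normal(size=10)
        reg = multivariate_regression(rng.normal(size=(10, 3)), x, n_perm=0)
        with pytest.warns(UserWarning, match="extrapolat"):
            warp_along_regression(reg, float(x.max()) + 10.0, ln_cs=0.0)


class TestFormSpace:
    def test_form_matrix_layout_and_dominance(self, params_noisy):
        from craniogrow.procrustes import gpa
        from craniogrow.synthetic import generate_cohort
        coh = generate_cohort(60, params=params_noisy, seed=21,
                              build_meshes=False)
        res = gpa(coh.landmark_sets())
        fm = form_matrix(res)
        assert fm.shape[1] == 3 * res.n_points + 1
        assert np.allclose(fm[:, -1], res.ln_cs)
        pc = pca(fm)
        # size dominates growth: PC1 loads overwhelmingly on Ln(CS)
        assert abs(pc.loadings[-1, 0]) > 0.9
        # and form is better explained by size than shape alone is
        r2_form = multivariate_regression(fm, res.ln_cs, n_perm=0).r_squared
        r2_shape = multivariate_regression(res.shape_coordinates,
                                           res.ln_cs, n_perm=0).r_squared
        assert r2_form > r2_shape
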