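import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qcindex import PCAModel, compute_qci, fit_pca, orient_pc1, score_qci, standardize
from qcindex.errors import DegenerateInputError, InsufficientDataError
from qcindex.ratios import RATIO_COLUMNS


def bruteforce_qci(ratios: pd.DataFrame) -> np.ndarray:
    """Independent reference: explicit covariance, numpy.linalg.eig, explicit
    orientation on the r_mi column, explicit min-max rescale."""
    X = ratios[RATIO_COLUMNS].to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    C = np.cov(Z.T, bias=True)
    vals, vecs = np.linalg.eig(C)
    w = np.real(vecs[:, np.argmax(np.real(vals))])
    s = Z @ w
    if np.corrcoef(s, Z[:, RATIO_COLUMNS.index("r_mi")])[0, 1] < 0:
        s = -s
    return 100.0 * (s.max() - s) / (s.max() - s.min())


def as_ratio_frame(X: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=RATIO_COLUMNS)
    df["location"] = [f"L{i}" for i in range(len(df))]
    df["year"] = 2000
    df["sex"] = "both"
    df["complete"] = True
    return df


class TestStandardize:
    def test_two_point_zscore(self):
        df = as_ratio_frame(np.column_stack([[1.0, 3.0]] * 4).reshape(2, 4))
        df.loc[:, RATIO_COLUMNS] = [[1, 1, 1, 1], [3, 2, 5, 9]]
        Z, means, sds, _ = standardize(df)
        np.testing.assert_allclose(Z[:, 0], [-1, 1])
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)

    def test_columns_have_unit_population_sd(self, small_ratio_pool):
        Z, _, sds, _ = standardize(small_ratio_pool)
        np.testing.assert_allclose(Z.std(axis=0, ddof=0), 1, atol=1e-9)
        np.testing.assert_allclose(np.abs(Z.mean(axis=0)), 0, atol=1e-9)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.lognormal(0, 1, (20, 4))
        Z, means, sds, _ = standardize(as_ratio_frame(X))
        expected = np.array(
            [
                [(X[i, j] - X[:, j].mean()) / X[:, j].std() for j in range(4)]
                for i in range(20)
            ]
        )
        np.testing.assert_allclose(Z, expected, atol=1e-12)

    def test_constant_column_named(self):
        X = np.random.default_rng(0).lognormal(0, 1, (10, 4))
        X[:, 2] = 3.3
        with pytest.raises(DegenerateInputError, match="r_dp"):
            standardize(as_ratio_frame(X))

    def test_needs_two_rows(self):
        with pytest.raises(InsufficientDataError):
            standardize(as_ratio_frame(np.ones((1, 4))))


class TestFitPca:
    def test_duplicated_pair_gets_equal_loadings(self):
        # two perfectly correlated columns + two independent noise columns:
        # PC1 of the correlation matrix is the analytic eigenvector of the
        # 2-block, weighting the duplicated pair equally.
        rng = np.random.default_rng(5)
        a = rng.normal(size=4000)
        X = np.column_stack([a, a, rng.normal(size=4000), rng.normal(size=4000)])
        Z = (X - X.mean(0)) / X.std(0)
        model = fit_pca(Z)
        w = model.pc1
        assert abs(abs(w[0]) - abs(w[1])) < 1e-6
        assert abs(w[0]) > abs(w[2]) and abs(w[0]) > abs(w[3])

    def test_isotropic_limit(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(200_00, 4))
        Z = (Z - Z.mean(0)) / Z.std(0)
        model = fit_pca(Z)
        np.testing.assert_allclose(model.explained_variance, 1, atol=0.05)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(0, 0.5, (50, 4)) @ np.diag([1, 2, 0.5, 1.5])
        Z = (X - X.mean(0)) / X.std(0)
        model = fit_pca(Z)
        C = Z.T @ Z / len(Z)
        v = np.ones(4) / 2.0
        for _ in range(10_000):
            v = C @ v
            v /= np.linalg.norm(v)
        assert min(np.linalg.norm(model.pc1 - v), np.linalg.norm(model.pc1 + v)) < 1e-8

    def test_loadings_orthonormal_and_variance_totals_four(self, small_ratio_pool):
        Z, *_ = standardize(small_ratio_pool)
        model = fit_pca(Z)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        assert model.explained_variance.sum() == pytest.approx(4.0, abs=1e-8)

    def test_agrees_with_sklearn(self, small_ratio_pool):
        from sklearn.decomposition import PCA

        Z, *_ = standardize(small_ratio_pool)
        model = fit_pca(Z)
        sk = PCA(n_components=4).fit(Z)
        for j in range(4):
            ours, theirs = model.loadings[:, j], sk.components_[j]
            assert min(np.linalg.norm(ours - theirs), np.linalg.norm(ours + theirs)) < 1e-8


class TestOrientation:
    def _oriented(self, Z):
        model = fit_pca(Z)
        return orient_pc1(model, Z)

    def test_sign_flips_when_pc1_anticorrelates_with_mortality(self, small_ratio_pool):
        Z, *_ = standardize(small_ratio_pool)
        model = self._oriented(Z)
        score = model.orientation_sign * (Z @ model.pc1)
        assert np.corrcoef(score, Z[:, 1])[0, 1] > 0
        # flipping the matrix flips the stored sign, not the oriented score
        model2 = self._oriented(-Z)
        score2 = model2.orientation_sign * ((-Z) @ model2.pc1)
        assert np.corrcoef(score2, -Z[:, 1])[0, 1] > 0

    def test_oriented_score_tracks_latent_badness(self, default_run):
        result, truth = default_run["result"], default_run["truth"]
        merged = result.scores.merge(truth, on=["location", "year", "sex"])
        rho = stats.spearmanr(merged["pc1_score"], 1 - merged["q"]).statistic
        assert rho > 0.9


class TestScoreQci:
    def test_linear_min_max_on_oriented_scores(self):
        # pool whose oriented scores are [2, 4, 6] -> QCI [100, 50, 0]
        model = PCAModel(
            means=np.zeros(4),
            sds=np.ones(4),
            loadings=np.eye(4),
            explained_variance=np.array([4.0, 0, 0, 0]),
            orientation_sign=1.0,
        )
        df = as_ratio_frame(np.column_stack([[2.0, 4.0, 6.0], np.zeros(3), np.zeros(3), np.zeros(3)]))
        res = score_qci(model, df, rescale_pool="fit_pool")
        np.testing.assert_allclose(res.scores["qci"], [100.0, 50.0, 0.0])

    def test_pool_extrema_hit_0_and_100(self, default_run):
        qci = default_run["result"].scores["qci"]
        assert qci.min() == pytest.approx(0.0)
        assert qci.max() == pytest.approx(100.0)
        assert ((qci >= 0) & (qci <= 100)).all()

    def test_row_equal_to_pooled_best_scores_100(self, default_run):
        result = default_run["result"]
        ratios = default_run["ratios"]
        best_idx = result.scores["qci"].idxmax()
        clone = ratios.loc[[best_idx]]
        res = score_qci(result.model, clone, rescale_pool="provided")
        assert res.scores["qci"].iloc[0] == pytest.approx(100.0)

    def test_out_of_pool_clamping(self, default_run):
        model = default_run["result"].model
        worst = np.array([1e3, 1e3, 1e3, 1e3])  # extreme ratios, worse than any pooled row
        df = as_ratio_frame(worst.reshape(1, 4))
        res = score_qci(model, df, rescale_pool="provided")
        assert res.scores["qci"].iloc[0] == 0.0

    def test_incomplete_rows_propagate_nan(self, default_run):
        model = default_run["result"].model
        df = as_ratio_frame(np.ones((2, 4)))
        df.loc[1, "r_mi"] = np.nan
        df.loc[1, "complete"] = False
        res = score_qci(model, df, rescale_pool="provided")
        assert np.isnan(res.scores["qci"].iloc[1])
        assert np.isfinite(res.scores["qci"].iloc[0])


class TestPipelineProperties:
    def test_matches_bruteforce_oracle(self, small_ratio_pool):
        got = compute_qci(small_ratio_pool).scores["qci"].to_numpy()
        expected = bruteforce_qci(small_ratio_pool)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_single_column_scale_invariance(self, small_ratio_pool):
        base = compute_qci(small_ratio_pool).scores["qci"].to_numpy()
        for col in RATIO_COLUMNS:
            scaled = small_ratio_pool.copy()
            scaled[col] = scaled[col] * 1000.0
            got = compute_qci(scaled).scores["qci"].to_numpy()
            np.testing.assert_allclose(got, base, atol=1e-8)

    def test_row_permutation_invariance(self, small_ratio_pool):
        rng = np.random.default_rng(13)
        perm = rng.permutation(len(small_ratio_pool))
        base = compute_qci(small_ratio_pool).scores.set_index("location")["qci"]
        shuffled = compute_qci(small_ratio_pool.iloc[perm].reset_index(drop=True))
        got = shuffled.scores.set_index("location")["qci"]
        pd.testing.assert_series_equal(got.sort_index(), base.sort_index(), atol=1e-10)

    def test_conditional_monotonicity(self, small_ratio_pool):
        result = compute_qci(small_ratio_pool)
        model = result.model
        oriented = model.orientation_sign * model.pc1
        assert np.all(oriented >= 0)  # precondition holds for this fixed pool
        row = small_ratio_pool.iloc[[10]].copy()
        base = score_qci(model, row, rescale_pool="provided").scores["qci"].iloc[0]
        row.loc[:, RATIO_COLUMNS] = row[RATIO_COLUMNS].to_numpy() * 1.5
        worse = score_qci(model, row, rescale_pool="provided").scores["qci"].iloc[0]
        assert worse <= base + 1e-10

    def test_model_json_round_trip_rescoring(self, tmp_path, small_ratio_pool):
        result = compute_qci(small_ratio_pool)
        path = tmp_path / "model.json"
        result.model.save(path)
        reloaded = PCAModel.load(path)
        res2 = score_qci(reloaded, small_ratio_pool, rescale_pool="provided")
        np.testing.assert_allclose(
            res2.scores["qci"], result.scores["qci"], atol=1e-12
        )
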