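import numpy as np
import pytest
from scipy import stats

from farmcpu import glm
from farmcpu.glm import RankDeficiencyError, build_fixed_design, scan_markers, scan_parallel

from .conftest import make_matrix


def ols_oracle(y, X_fixed, x_marker):
    """Naive full-design least-squares refit for one marker."""
    X = np.column_stack([X_fixed, x_marker])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta[-1], se[-1], t[-1], p[-1], df


class TestWorkedExample:
    """y=[1,2,3,4] on x=[0,1,1,2], intercept only; closed form by hand:
    b = Sxy/Sxx = 3/2, rss = 0.5, se = sqrt((rss/2)/Sxx)."""

    def setup_method(self):
        self.matrix = make_matrix(np.array([[0.0], [1.0], [1.0], [2.0]]))
        self.y = np.array([1.0, 2.0, 3.0, 4.0])
        fixed = build_fixed_design(self.y, None, (), self.matrix)
        self.res = scan_markers(self.matrix, fixed)

    def test_effect(self):
        assert self.res.effect[0] == pytest.approx(1.5, abs=1e-12)

    def test_se(self):
        assert self.res.se[0] == pytest.approx(np.sqrt(0.25 / 2), abs=1e-12)

    def test_t_and_p(self):
        assert self.res.t[0] == pytest.approx(4.242640687, abs=1e-8)
        assert self.res.p[0] == pytest.approx(2 * stats.t.sf(4.242640687, 2), abs=1e-9)
        assert self.res.p[0] == pytest.approx(0.05131, abs=1e-4)

    def test_df(self):
        assert self.res.df == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_instance_matches_full_refit(self, seed):
        rng = np.random.default_rng(seed)
        n, m, q, t = 30, 8, 2, 3
        g = rng.integers(0, 3, size=(n, m)).astype(float)
        matrix = make_matrix(g)
        cov = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        qtns = tuple(rng.choice(m, size=t, replace=False).tolist())
        fixed = build_fixed_design(y, cov, qtns, matrix)
        res = scan_markers(matrix, fixed)
        X_fixed = np.column_stack([np.ones(n), cov, g[:, list(qtns)]])
        for j in range(m):
            if j in qtns:
                assert np.isnan(res.effect[j])
                continue
            b, se, tv, p, df = ols_oracle(y, X_fixed, g[:, j])
            assert res.df == df
            np.testing.assert_allclose(res.effect[j], b, rtol=1e-8)
            np.testing.assert_allclose(res.se[j], se, rtol=1e-8)
            np.testing.assert_allclose(res.t[j], tv, rtol=1e-8)
            np.testing.assert_allclose(res.p[j], p, rtol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 50
        g = rng.integers(0, 3, size=(n, 4)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=n)
        fixed = build_fixed_design(y, None, (), matrix)
        res = scan_markers(matrix, fixed)
        for j in range(4):
            fit = sm.OLS(y, sm.add_constant(g[:, j])).fit()
            np.testing.assert_allclose(res.effect[j], fit.params[1], rtol=1e-10)
            np.testing.assert_allclose(res.se[j], fit.bse[1], rtol=1e-10)
            np.testing.assert_allclose(res.p[j], fit.pvalues[1], rtol=1e-10)


class TestMissingPhenotype:
    def test_n_eff_counts_complete_rows(self, rng):
        g = rng.integers(0, 3, size=(100, 10)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=100)
        y[[3, 50, 97]] = np.nan
        fixed = build_fixed_design(y, None, (), matrix)
        assert fixed.n_eff == 97

    def test_masking_equals_explicit_subset(self, rng):
        """Index-mask scanning must equal scanning a row-subsetted copy."""
        g = rng.integers(0, 3, size=(80, 40)).astype(float)
        y = rng.normal(size=80)
        y[rng.choice(80, 10, replace=False)] = np.nan
        matrix = make_matrix(g)
        fixed = build_fixed_design(y, None, (), matrix)
        res_masked = scan_markers(matrix, fixed)

        keep = np.isfinite(y)
        sub = make_matrix(g[keep])
        fixed_sub = build_fixed_design(y[keep], None, (), sub)
        res_sub = scan_markers(sub, fixed_sub)
        np.testing.assert_array_equal(res_masked.effect, res_sub.effect)
        np.testing.assert_array_equal(res_masked.p, res_sub.p)


class TestDesignValidation:
    def test_intercept_only_projector_is_mean(self, rng):
        g = rng.integers(0, 3, size=(20, 3)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=20)
        fixed = build_fixed_design(y, None, (), matrix)
        np.testing.assert_allclose(fixed.y_resid, y - y.mean(), atol=1e-10)
        assert fixed.k == 1

    def test_duplicate_covariate_rank_error(self, rng):
        g = rng.integers(0, 3, size=(30, 5)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=30)
        cov = g[:, [0]]  # same as pseudo-QTN 0
        with pytest.raises(RankDeficiencyError, match="pseudo_qtn_0"):
            build_fixed_design(y, cov, (0,), matrix)

    def test_constant_marker_gives_missing_result(self, rng):
        g = rng.integers(0, 3, size=(25, 3)).astype(float)
        g[:, 1] = 2.0
        matrix = make_matrix(g)
        fixed = build_fixed_design(rng.normal(size=25), None, (), matrix)
        res = scan_markers(matrix, fixed)
        assert np.isnan(res.effect[1]) and np.isnan(res.p[1])
        assert np.isfinite(res.p[[0, 2]]).all()
        assert res.n_used[1] == 0

    def test_df_drops_by_one_per_pseudo_qtn(self, rng):
        g = rng.integers(0, 3, size=(50, 10)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=50)
        df0 = build_fixed_design(y, None, (), matrix).residual_df
        df1 = build_fixed_design(y, None, (0,), matrix).residual_df
        df2 = build_fixed_design(y, None, (0, 1), matrix).residual_df
        assert df0 - df1 == 1 and df1 - df2 == 1

    def test_t_squared_equals_f(self, rng):
        g = rng.integers(0, 3, size=(40, 6)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=40)
        fixed = build_fixed_design(y, None, (), matrix)
        res = scan_markers(matrix, fixed)
        # F for 1 numerator df: (rss0 - rss1)/ (rss1/df)
        for j in range(6):
            X = np.column_stack([np.ones(40), g[:, j]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(np.sum((y - X @ beta) ** 2))
            rss0 = float(np.sum((y - y.mean()) ** 2))
            F = (rss0 - rss1) / (rss1 / res.df)
            np.testing.assert_allclose(res.t[j] ** 2, F, rtol=1e-8)


class TestParallelDeterminism:
    def test_workers_and_chunking_bitwise_identical(self, rng):
        g = rng.integers(0, 3, size=(120, 500)).astype(float)
        matrix = make_matrix(g)
        y = rng.normal(size=120)
        fixed = build_fixed_design(y, None, (3, 77), matrix)
        base = scan_markers(matrix, fixed)
        for workers, chunk in [(1, 1), (1, 97), (4, 97), (4, 500), (8, 64)]:
            alt = scan_parallel(matrix, fixed, n_workers=workers, chunk_size=chunk)
            np.testing.assert_array_equal(base.effect, alt.effect)
            np.testing.assert_array_equal(base.se, alt.se)
            np.testing.assert_array_equal(base.t, alt.t)
            np.testing.assert_array_equal(base.p, alt.p)

    def test_single_marker_many_workers(self, rng):
        matrix = make_matrix(rng.integers(0, 3, size=(30, 1)).astype(float))
        fixed = build_fixed_design(rng.normal(size=30), None, (), matrix)
        res = scan_parallel(matrix, fixed, n_workers=8)
        assert res.m == 1 and np.isfinite(res.p[0])

    def test_invalid_worker_count(self, rng):
        matrix = make_matrix(rng.integers(0, 3, size=(30, 2)).astype(float))
        fixed = build_fixed_design(rng.normal(size=30), None, (), matrix)
        with pytest.raises(ValueError, match="n_workers"):
            scan_parallel(matrix, fixed, n_workers=0)


def test_null_pvalues_uniform_small():
    rng = np.random.default_rng(11)
    g = rng.integers(0, 3, size=(200, 2000)).astype(float)
    matrix = make_matrix(g)
    y = rng.normal(size=200)
    fixed = build_fixed_design(y, None, (), matrix)
    res = scan_markers(matrix, fixed)
    p = res.p[np.isfinite(res.p)]
    assert stats.kstest(p, "uniform").pvalue > 0.01
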