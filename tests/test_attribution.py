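import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatsig.attribution import (BestSubsetAICc, correlated_errors_lr_test,
                                 exhaustive_aicc_regression,
                                 metric_correlation_pcoa, s_correlation)


class TestPCoA:
    def test_identical_metrics_collocated(self, rng):
        base = rng.standard_normal(30)
        prof = pd.DataFrame({"a": base, "b": 2 * base + 1,
                             "c": rng.standard_normal(30)})
        res = metric_correlation_pcoa(prof)
        assert res.distance.loc["a", "b"] == pytest.approx(0, abs=1e-7)
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-6)

    def test_uncorrelated_metrics_simplex_geometry(self, rng):
        # near-orthogonal columns: distances ~ sqrt(2), m-1 similar eigenvalues
        m = 5
        A = np.column_stack([np.ones(200), rng.standard_normal((200, m))])
        q = np.linalg.qr(A)[0][:, 1:]  # centered, mutually orthogonal
        prof = pd.DataFrame(q, columns=list("abcde"))
        res = metric_correlation_pcoa(prof)
        off = res.distance.to_numpy()[np.triu_indices(m, 1)]
        np.testing.assert_allclose(off, np.sqrt(2), atol=1e-8)
        np.testing.assert_allclose(res.eigenvalues[:m - 1], 1.0, atol=1e-8)

    def test_sqrt2_transform_is_euclidean(self, rng):
        # any correlation matrix: no meaningful negative eigenvalues
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = r.standard_normal((12, 6))
            prof = pd.DataFrame(X, columns=list("abcdef"))
            res = metric_correlation_pcoa(prof)
            assert res.eigenvalues.min() >= -1e-8

    def test_matches_skbio_pcoa(self, rng):
        skbio = pytest.importorskip("skbio")
        prof = pd.DataFrame(rng.standard_normal((40, 4)),
                            columns=list("abcd"))
        res = metric_correlation_pcoa(prof)
        dm = skbio.DistanceMatrix(res.distance.to_numpy(),
                                  ids=list(res.distance.index))
        ref = skbio.stats.ordination.pcoa(dm)
        np.testing.assert_allclose(
            np.sort(res.eigenvalues[res.eigenvalues > 1e-10])[::-1],
            np.sort(ref.eigvals[ref.eigvals > 1e-10].to_numpy())[::-1],
            atol=1e-8)

    def test_too_few_metrics_rejected(self, rng):
        with pytest.raises(ValueError):
            metric_correlation_pcoa(pd.DataFrame({"a": rng.normal(size=5),
                                                  "b": rng.normal(size=5)}))


def aicc_by_hand(n, k, rss):
    p = k + 2
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


class TestBestSubset:
    def test_exact_predictor_recovered(self, rng):
        x1 = rng.standard_normal(9)
        X = pd.DataFrame({"x1": x1, "x2": rng.standard_normal(9)})
        fit = exhaustive_aicc_regression(x1, X)
        assert fit.best_.predictors == ("x1",)
        assert fit.best_.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_aicc_formula(self, rng):
        X = pd.DataFrame(rng.standard_normal((9, 2)), columns=["x1", "x2"])
        y = rng.standard_normal(9)
        fit = BestSubsetAICc().fit(X, y)
        import statsmodels.api as sm
        for sub in fit.all_fits_:
            res = sm.OLS(y, sm.add_constant(
                X[list(sub.predictors)].to_numpy())).fit()
            assert sub.aicc == pytest.approx(
                aicc_by_hand(9, len(sub.predictors), res.ssr))

    def test_selection_consistency(self):
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            X = pd.DataFrame(r.standard_normal((9, 4)),
                             columns=["x1", "x2", "x3", "x4"])
            y = 0.6 * X["x1"] + 0.6 * X["x2"] + 0.05 * r.standard_normal(9)
            fit = exhaustive_aicc_regression(y, X)
            hits += set(fit.best_.predictors) == {"x1", "x2"}
        assert hits >= 90

    def test_nested_rss_bound_and_ranking(self, rng):
        X = pd.DataFrame(rng.standard_normal((9, 3)),
                         columns=["x1", "x2", "x3"])
        y = pd.Series(rng.standard_normal(9))
        fit = BestSubsetAICc().fit(X, y)
        assert fit.best_.aicc == min(f.aicc for f in fit.all_fits_)
        by_preds = {f.predictors: f for f in fit.all_fits_}
        # brute-force enumeration count: 2^3 - 1 subsets
        assert len(by_preds) == 7

    def test_matches_independent_enumeration(self, rng):
        import itertools
        import statsmodels.api as sm
        X = pd.DataFrame(rng.standard_normal((12, 4)),
                         columns=["a", "b", "c", "d"])
        y = rng.standard_normal(12)
        fit = BestSubsetAICc().fit(X, y)
        best, best_aicc = None, np.inf
        for k in range(1, 5):
            for sub in itertools.combinations(X.columns, k):
                res = sm.OLS(np.asarray(y), sm.add_constant(
                    X[list(sub)].to_numpy())).fit()
                a = aicc_by_hand(12, k, res.ssr)
                if a < best_aicc:
                    best, best_aicc = sub, a
        assert fit.best_.predictors == best
        assert fit.best_.aicc == pytest.approx(best_aicc)

    def test_degenerate_sample_size_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 3)),
                         columns=["x1", "x2", "x3"])
        with pytest.raises(ValueError):
            BestSubsetAICc().fit(X, rng.standard_normal(4))


class TestCorrelatedErrors:
    def test_identity_covariance_reduces_to_ols(self, rng):
        y = rng.standard_normal(9)
        x = rng.standard_normal(9)
        _, lr, p = correlated_errors_lr_test(y, x, np.eye(9))
        X1 = np.column_stack([np.ones(9), x])
        b1 = np.linalg.lstsq(X1, y, rcond=None)[0]
        rss1 = np.sum((y - X1 @ b1) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        assert lr == pytest.approx(9 * np.log(rss0 / rss1), abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(lr, 1))

    def test_affine_relation_is_overwhelming(self, rng):
        x = rng.standard_normal(9)
        slope, lr, p = correlated_errors_lr_test(-2 * x + 1 + 1e-8 * rng.standard_normal(9), x, np.eye(9))
        assert slope == pytest.approx(-2, abs=1e-4)
        assert p < 1e-10

    def test_null_calibration_with_correlated_errors(self):
        # errors drawn from N(0, C): LR test should reject ~5%
        base = np.random.default_rng(99)
        A = base.standard_normal((9, 9))
        C = A @ A.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        L = np.linalg.cholesky(C)
        hits = 0
        n_rep = 800
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            y = L @ r.standard_normal(9)
            x = L @ r.standard_normal(9)
            _, _, p = correlated_errors_lr_test(y, x, C)
            hits += p < 0.05
        rate = hits / n_rep
        # LR with chi2(1) reference at n=9 is moderately liberal; allow
        # the usual small-sample inflation band
        assert 0.02 < rate < 0.12

    def test_singular_covariance_gets_ridge(self, rng):
        C = np.ones((5, 5))  # rank 1
        y, x = rng.standard_normal(5), rng.standard_normal(5)
        slope, lr, p = correlated_errors_lr_test(y, x, C)
        assert np.isfinite(lr) and 0 <= p <= 1


class TestSCorrelation:
    def test_perfect_negative(self, rng):
        s_minus = rng.standard_normal(9)
        assert s_correlation(-s_minus + 3, s_minus) == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert s_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(9), rng.standard_normal(9)
        za, zb = a - a.mean(), b - b.mean()
        want = (za @ zb) / np.sqrt((za @ za) * (zb @ zb))
        assert s_correlation(a, b) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            s_correlation(np.ones(5), np.arange(5.0))
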