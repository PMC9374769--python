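import numpy as np
import pandas as pd
import pytest

from spatsig.datasets import load_andean_path_coefficients
from spatsig.plssem import (Block, MeasurementSpec, PLSPathModel,
                            bootstrap_paths, default_measurement_spec,
                            path_summary_stats, pls1_screening)


def single_indicator_spec(k):
    return MeasurementSpec(
        exogenous=[Block(f"f{i}", (f"x{i}",), "B") for i in range(k)],
        endogenous=Block("out", ("y",), "A"),
    )


def standardized(df):
    return (df - df.mean()) / df.std(ddof=1)


class TestPathModel:
    def test_two_single_indicator_blocks_give_pearson_r(self, rng):
        df = pd.DataFrame(rng.standard_normal((25, 2)), columns=["x0", "y"])
        fit = PLSPathModel(spec=single_indicator_spec(1)).fit(df)
        r = np.corrcoef(df["x0"], df["y"])[0, 1]
        assert fit.path_coefficients_["f0"] == pytest.approx(r, abs=1e-10)
        assert fit.r_squared_ == pytest.approx(r**2, abs=1e-10)

    def test_single_indicator_latents_are_standardized_indicators(self, rng):
        df = pd.DataFrame(rng.standard_normal((15, 3)),
                          columns=["x0", "x1", "y"])
        fit = PLSPathModel(spec=single_indicator_spec(2)).fit(df)
        z = standardized(df)
        np.testing.assert_allclose(fit.scores_["f0"], z["x0"], atol=1e-10)
        np.testing.assert_allclose(fit.scores_["out"], z["y"], atol=1e-10)

    def test_ols_equivalence_four_blocks(self, rng):
        for _ in range(10):
            X = rng.standard_normal((21, 4))
            y = X @ rng.uniform(-1, 1, 4) + rng.standard_normal(21)
            df = pd.DataFrame(np.column_stack([X, y]),
                              columns=["x0", "x1", "x2", "x3", "y"])
            fit = PLSPathModel(spec=single_indicator_spec(4)).fit(df)
            z = standardized(df)
            beta = np.linalg.lstsq(z[["x0", "x1", "x2", "x3"]], z["y"],
                                   rcond=None)[0]
            np.testing.assert_allclose(fit.path_coefficients_, beta,
                                       atol=1e-10)

    def test_centroid_and_factorial_agree_on_single_indicator(self, rng):
        df = pd.DataFrame(rng.standard_normal((18, 5)),
                          columns=["x0", "x1", "x2", "x3", "y"])
        spec = single_indicator_spec(4)
        a = PLSPathModel(spec=spec, scheme="centroid").fit(df)
        b = PLSPathModel(spec=spec, scheme="factorial").fit(df)
        np.testing.assert_allclose(a.path_coefficients_, b.path_coefficients_,
                                   atol=1e-9)

    def test_latent_scores_standardized(self, rng):
        cols = ["Dg", "CCe", "Ec", "BC", "wetland_size", "cooccurrence",
                "altitude", "slope", "MAWS", "SnowNDays", "NDVI", "dNDVI", "N0"]
        df = pd.DataFrame(rng.standard_normal((21, 13)), columns=cols)
        fit = PLSPathModel(spec=default_measurement_spec("N0")).fit(df)
        np.testing.assert_allclose(fit.scores_.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(fit.scores_.std(ddof=1), 1, atol=1e-8)
        assert fit.weight_change_ < 1e-7

    def test_anchor_sign_alignment(self, rng):
        cols = ["Dg", "CCe", "Ec", "BC", "wetland_size", "cooccurrence",
                "altitude", "slope", "MAWS", "SnowNDays", "NDVI", "dNDVI", "N0"]
        df = pd.DataFrame(rng.standard_normal((21, 13)), columns=cols)
        fit = PLSPathModel(spec=default_measurement_spec("N0")).fit(df)
        for name, anchor in [("connectivity", "Dg"), ("environment", "altitude"),
                             ("size", "wetland_size")]:
            assert fit.outer_loadings_[name][0] >= 0, (name, anchor)

    def test_missing_indicator_rejected(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 2)), columns=["x0", "y"])
        with pytest.raises(ValueError, match="missing indicator"):
            PLSPathModel(spec=single_indicator_spec(2)).fit(df)

    def test_singular_formative_block_rejected(self, rng):
        x = rng.standard_normal(15)
        df = pd.DataFrame({"a": x, "b": 2 * x, "y": rng.standard_normal(15)})
        spec = MeasurementSpec(exogenous=[Block("f", ("a", "b"), "B")],
                               endogenous=Block("out", ("y",), "A"))
        with pytest.raises(ValueError, match="singular"):
            PLSPathModel(spec=spec).fit(df)

    def test_sklearn_param_interface(self):
        est = PLSPathModel(tol=1e-6)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(scheme="factorial")
        assert est.scheme == "factorial"


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        df = pd.DataFrame(rng.standard_normal((21, 5)),
                          columns=["x0", "x1", "x2", "x3", "y"])
        spec = single_indicator_spec(4)
        a = bootstrap_paths(df, spec=spec, n_boot=99, seed=5)
        b = bootstrap_paths(df, spec=spec, n_boot=99, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_detects_strong_effect(self):
        hits = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            x = r.standard_normal(21)
            y = 0.8 * x + np.sqrt(1 - 0.64) * r.standard_normal(21)
            df = pd.DataFrame({"x0": x, "y": y})
            boot = bootstrap_paths(df, spec=single_indicator_spec(1),
                                   n_boot=199, seed=rep)
            hits += bool(boot.table.loc["f0", "significant"])
        assert hits >= 0.8 * 50

    def test_ci_bounds_ordered(self, rng):
        df = pd.DataFrame(rng.standard_normal((21, 5)),
                          columns=["x0", "x1", "x2", "x3", "y"])
        boot = bootstrap_paths(df, spec=single_indicator_spec(4),
                               n_boot=199, seed=0)
        assert (boot.table["ci_low"] <= boot.table["ci_high"]).all()
        assert (boot.table["se"] >= 0).all()


class TestScreening:
    def test_true_predictor_retained(self):
        kept = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            X = pd.DataFrame(r.standard_normal((21, 5)),
                             columns=[f"v{i}" for i in range(5)])
            y = X["v2"] + 0.2 * r.standard_normal(21)
            kept += "v2" in pls1_screening(X, y)
        assert kept >= 9

    def test_one_component_weights_match_closed_form(self, rng):
        # orthonormal predictors: the first PLS1 weight vector is X'y
        from sklearn.cross_decomposition import PLSRegression
        q, _ = np.linalg.qr(rng.standard_normal((20, 4)))
        y = rng.standard_normal(20)
        pls = PLSRegression(n_components=1, scale=False).fit(q, y)
        w = pls.x_weights_.ravel()
        expected = q.T @ (y - y.mean())
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(w), np.abs(expected), atol=1e-8)

    def test_noise_outcome_keeps_few_components(self):
        ones = 0
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            X = pd.DataFrame(r.standard_normal((21, 6)),
                             columns=[f"v{i}" for i in range(6)])
            y = r.standard_normal(21)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept = pls1_screening(X, y)
            ones += len(kept) <= 3
        assert ones >= 6  # noise rarely supports a large retained set


class TestScreenerEstimator:
    def test_fit_transform_subsets_columns(self):
        r = np.random.default_rng(3)
        X = pd.DataFrame(r.standard_normal((21, 5)),
                         columns=[f"v{i}" for i in range(5)])
        y = X["v1"] + 0.2 * r.standard_normal(21)
        from spatsig.plssem import PLS1Screener
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = PLS1Screener().fit(X, y)
        assert "v1" in sel.retained_
        out = sel.transform(X)
        assert list(out.columns) == sel.retained_
        assert sel.get_support(X.columns) == [c in sel.retained_
                                              for c in X.columns]


class TestSummaryStats:
    def test_published_table_reproduced(self):
        table = load_andean_path_coefficients()
        summary = path_summary_stats(table)
        np.testing.assert_allclose(
            summary.loc["mean_abs_path"].round(2), [0.35, 0.09, 0.11, 0.45])
        for factor, cv in [("connectivity", 46.68), ("cooccurrence", 832.69),
                           ("environment", 243.29)]:
            assert summary.loc["cv_percent", factor] == pytest.approx(
                cv, abs=0.01)

    def test_constant_column_has_zero_cv(self):
        df = pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.1, 0.2, 0.3]})
        summary = path_summary_stats(df)
        assert summary.loc["cv_percent", "a"] == 0.0
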