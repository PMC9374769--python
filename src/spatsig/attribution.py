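"""Linking ecological-factor effects to spatial autocorrelation components.

Three analyses operate on the 9 community metrics as observations:

1. a confound screen — the 9x9 Pearson correlation matrix of the metrics
   is turned into distances ``d = sqrt(2 (1 - r))`` (Euclidean-embeddable
   for any correlation matrix) and decomposed by principal coordinates;
   regressing S+/S- on the resulting axes checks whether autocorrelation
   levels are an artefact of the metrics' mutual redundancy;
2. an exhaustive best-subset OLS of S+ (and separately S-) on the four
   per-factor path-coefficient columns, ranked by AICc with the
   small-sample parameter count ``p = k + 2`` (intercept and residual
   variance included);
3. a correlated-errors test of S+ against S-: a GLS fit with error
   covariance proportional to the metric correlation matrix, compared to
   the intercept-only null by a likelihood-ratio chi-square with 1 df.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "MetricCorrelationPCoA",
    "metric_correlation_pcoa",
    "SubsetFit",
    "BestSubsetAICc",
    "exhaustive_aicc_regression",
    "correlated_errors_lr_test",
    "s_correlation",
]


@dataclass
class MetricCorrelationPCoA:
    correlation: pd.DataFrame        # metric x metric Pearson r
    distance: pd.DataFrame           # derived distances
    eigenvalues: np.ndarray          # all PCoA eigenvalues, descending
    coordinates: pd.DataFrame        # metric x retained axis scores


def metric_correlation_pcoa(profile: pd.DataFrame,
                            transform: str = "sqrt2") -> MetricCorrelationPCoA:
    """PCoA of the between-metric correlation structure.

    ``transform`` maps correlations to distances: "sqrt2" (default,
    ``sqrt(2(1-r))``), "one_minus" (``1-r``), or "one_minus_abs"
    (``1-|r|``). Metrics with missing values (e.g. Pielou's J at
    single-species sites) enter via pairwise-complete correlations, with a
    warning. Axes with positive eigenvalues are retained.
    """
    if profile.shape[1] < 3:
        raise ValueError("need at least 3 metrics")
    if profile.isna().any().any():
        logger.warning("missing metric values: using pairwise-complete correlations")
    r = profile.corr(method="pearson")  # pairwise-complete by construction
    if transform == "sqrt2":
        d = np.sqrt(np.maximum(2.0 * (1.0 - r.to_numpy()), 0.0))
    elif transform == "one_minus":
        d = 1.0 - r.to_numpy()
    elif transform == "one_minus_abs":
        d = 1.0 - np.abs(r.to_numpy())
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    m = d.shape[0]
    # Gower double centering of -1/2 d^2
    A = -0.5 * d**2
    H = np.eye(m) - np.ones((m, m)) / m
    G = H @ A @ H
    lam, V = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    if lam.min() < -1e-8 * max(abs(lam).max(), 1.0):
        logger.warning("PCoA has non-trivial negative eigenvalues (min %.3e)",
                       lam.min())
    keep = lam > 1e-10 * max(abs(lam).max(), 1.0)
    coords = V[:, keep] * np.sqrt(lam[keep])
    return MetricCorrelationPCoA(
        correlation=r,
        distance=pd.DataFrame(d, index=r.index, columns=r.columns),
        eigenvalues=lam,
        coordinates=pd.DataFrame(
            coords, index=r.index,
            columns=[f"axis{i + 1}" for i in range(coords.shape[1])],
        ),
    )


@dataclass
class SubsetFit:
    """One candidate OLS fit in the exhaustive search."""

    predictors: tuple
    aicc: float
    adj_r2: float
    fvalue: float
    df_num: int
    df_den: int
    model_p: float
    coefficients: pd.DataFrame      # beta, se, t, p per predictor
    shapiro_p: float


def _aicc(n: int, k: int, rss: float) -> float:
    """AICc with parameter count p = k + 2 (intercept + residual variance)."""
    p = k + 2
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


class BestSubsetAICc(BaseEstimator):
    """Exhaustive best-subset OLS ranked by small-sample AICc.

    Every nonempty predictor subset is fitted with an intercept; subsets
    whose residual degrees of freedom would be exhausted
    (``n - p - 1 <= 0``) are skipped. The fitted attributes describe the
    minimal-AICc model; ``all_fits_`` keeps the full ranking.
    """

    def fit(self, X: pd.DataFrame, y):
        yv = np.asarray(y, dtype=float)
        n = len(yv)
        fits = []
        for k in range(1, X.shape[1] + 1):
            for subset in itertools.combinations(X.columns, k):
                if n - (k + 2) - 1 <= 0:
                    logger.info("skipping subset %s: too few observations", subset)
                    continue
                Xs = sm.add_constant(X[list(subset)].to_numpy(dtype=float))
                res = sm.OLS(yv, Xs).fit()
                coef = pd.DataFrame({
                    "beta": res.params[1:],
                    "se": res.bse[1:],
                    "t": res.tvalues[1:],
                    "p": res.pvalues[1:],
                }, index=list(subset))
                fits.append(SubsetFit(
                    predictors=subset,
                    aicc=_aicc(n, k, float(res.ssr)),
                    adj_r2=float(res.rsquared_adj),
                    fvalue=float(res.fvalue),
                    df_num=int(res.df_model),
                    df_den=int(res.df_resid),
                    model_p=float(res.f_pvalue),
                    coefficients=coef,
                    shapiro_p=float(stats.shapiro(res.resid).pvalue),
                ))
        if not fits:
            raise ValueError("no fittable subset (too few observations)")
        fits.sort(key=lambda f: f.aicc)
        self.all_fits_ = fits
        self.best_ = fits[0]
        return self

    def summary(self) -> pd.DataFrame:
        best = self.best_
        head = {
            "adj_r2": best.adj_r2, "F": best.fvalue,
            "df_num": best.df_num, "df_den": best.df_den,
            "model_p": best.model_p, "aicc": best.aicc,
            "shapiro_p": best.shapiro_p,
        }
        out = best.coefficients.copy()
        for k, v in head.items():
            out.attrs[k] = v
        return out


def exhaustive_aicc_regression(y, X: pd.DataFrame) -> BestSubsetAICc:
    """Fit the exhaustive AICc subset search (thin wrapper)."""
    return BestSubsetAICc().fit(X, y)


def correlated_errors_lr_test(s_plus, s_minus, C,
                              ridge: float = 1e-8) -> tuple[float, float, float]:
    """Slope, LR statistic, and p-value of S+ ~ S- with correlated errors.

    The full model ``S+ = a + b S- + e`` and the intercept-only null are
    both fitted by maximum likelihood with ``e ~ N(0, sigma^2 C)``, C being
    the between-metric correlation matrix; because C is shared, the LR
    reduces to ``n ln(RSS0_w / RSS1_w)`` on whitened data. p is from
    chi-square with 1 df. A singular C gets a small ridge, logged.
    """
    y = np.asarray(s_plus, dtype=float)
    x = np.asarray(s_minus, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix: adding %g ridge", ridge)
        L = np.linalg.cholesky(C + ridge * np.eye(n))
    Li = np.linalg.inv(L)
    yw = Li @ y
    Xw1 = Li @ np.column_stack([np.ones(n), x])
    Xw0 = Li @ np.ones((n, 1))
    beta1, *_ = np.linalg.lstsq(Xw1, yw, rcond=None)
    beta0, *_ = np.linalg.lstsq(Xw0, yw, rcond=None)
    rss1 = float(np.sum((yw - Xw1 @ beta1) ** 2))
    rss0 = float(np.sum((yw - Xw0 @ beta0) ** 2))
    lr = n * np.log(rss0 / rss1)
    p = float(stats.chi2.sf(lr, df=1))
    return float(beta1[1]), float(lr), p


def s_correlation(s_plus, s_minus) -> float:
    """Pearson correlation between the S+ and S- vectors over metrics."""
    y = np.asarray(s_plus, dtype=float)
    x = np.asarray(s_minus, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 metrics")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("zero-variance component vector")
    return float(stats.pearsonr(y, x).statistic)
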