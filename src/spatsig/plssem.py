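"""PLS path modeling (PLS-SEM) of ecological factors on community metrics.

Four latent ecological factors are measured by 12 indicators:

* environmental variability — formative: altitude, slope, MAWS, SnowNDays,
  NDVI, dNDVI;
* wetland connectivity — formative: Dg, CCe, Ec, BC;
* wetland size — formative: wetland_size;
* species co-occurrence — reflective: the sign-flipped C-score.

One model is fitted per community metric, with the metric as the single
reflective indicator of the endogenous block. Latent scores are estimated
by the classic Lohmoller alternating algorithm: outer approximation (block
scores as weighted indicator sums), inner approximation (proxies from
adjacent latents under the centroid, factorial, or path scheme), then outer
weight update — mode A (reflective) weights are indicator-proxy
correlations, mode B (formative) weights are multiple-regression
coefficients of the proxy on the block. Iteration stops when the largest
outer-weight change falls below ``tol``. Path coefficients are then the OLS
coefficients of the endogenous latent on the exogenous latents (all scores
standardized, so the paths are standardized coefficients).

Each latent is sign-aligned so that its loading on the block's first-listed
("anchor") indicator is positive; this keeps bootstrap replicates
comparable to the original fit.

Inference is by site bootstrap: sites are resampled with replacement, the
model refitted, and percentile confidence intervals and standard errors
taken over replicates. A path is "significant" when its CI excludes zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "MeasurementSpec",
    "default_measurement_spec",
    "PLSPathModel",
    "BootstrapResult",
    "bootstrap_paths",
    "pls1_screening",
    "PLS1Screener",
    "path_summary_stats",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """The outer-weight iteration failed to converge."""


@dataclass(frozen=True)
class Block:
    """One measurement block: a latent variable and its indicators.

    ``mode`` is "A" (reflective: the latent causes the indicators, weights
    by correlation) or "B" (formative: the indicators form the latent,
    weights by multiple regression). The first indicator is the sign
    anchor.
    """

    name: str
    indicators: tuple
    mode: str = "B"

    def __post_init__(self):
        if self.mode not in ("A", "B"):
            raise ValueError("block mode must be 'A' or 'B'")
        if not self.indicators:
            raise ValueError(f"block {self.name!r} has no indicators")


@dataclass
class MeasurementSpec:
    """Exogenous blocks plus a single-indicator endogenous block."""

    exogenous: list = field(default_factory=list)
    endogenous: Block | None = None

    @property
    def blocks(self) -> list:
        return list(self.exogenous) + [self.endogenous]

    def all_indicators(self) -> list:
        out = []
        for b in self.blocks:
            out.extend(b.indicators)
        return out


def default_measurement_spec(metric: str) -> MeasurementSpec:
    """The 12-indicator, four-factor outer model for one community metric."""
    return MeasurementSpec(
        exogenous=[
            Block("connectivity", ("Dg", "CCe", "Ec", "BC"), mode="B"),
            Block("size", ("wetland_size",), mode="B"),
            Block("cooccurrence", ("cooccurrence",), mode="A"),
            Block("environment",
                  ("altitude", "slope", "MAWS", "SnowNDays", "NDVI", "dNDVI"),
                  mode="B"),
        ],
        endogenous=Block(metric, (metric,), mode="A"),
    )


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance indicator")
    return (X - X.mean(axis=0)) / sd


def _fit_core(Xb: list, modes: list, scheme: str, tol: float, max_iter: int):
    """Lohmoller iteration on pre-standardized block matrices.

    Returns (weights per block normalized to unit-variance scores,
    scores matrix (n, n_blocks), iterations, final weight change).
    The last block is the endogenous one; the inner model connects every
    exogenous block to it and nothing else. Mode-B weight updates reuse a
    pseudo-inverse computed once per block.
    """
    if scheme not in ("centroid", "factorial", "path"):
        raise ValueError(f"unknown inner scheme {scheme!r}")
    n = Xb[0].shape[0]
    nb = len(Xb)
    root = np.sqrt(n - 1.0)
    pinv = [np.linalg.pinv(b) if m == "B" else None
            for b, m in zip(Xb, modes)]
    w = []
    scores = np.empty((n, nb))
    for j in range(nb):
        wj = np.ones(Xb[j].shape[1])
        s = Xb[j] @ wj
        nrm = np.linalg.norm(s) / root
        if nrm == 0:
            raise ValueError("degenerate block score (zero variance)")
        w.append(wj / nrm)
        scores[:, j] = Xb[j] @ w[j]
    it, delta = 0, np.inf
    for it in range(1, max_iter + 1):
        # inner approximation: exogenous blocks adjacent only to the
        # endogenous (last) block and vice versa
        cov_out = scores[:, :-1].T @ scores[:, -1] / (n - 1)
        if scheme == "centroid":
            e = np.sign(cov_out)
            e[e == 0] = 1.0
        else:
            e = cov_out
        inner = np.empty_like(scores)
        if scheme == "path":
            coef, *_ = np.linalg.lstsq(scores[:, :-1], scores[:, -1], rcond=None)
            inner[:, -1] = scores[:, :-1] @ coef
        else:
            inner[:, -1] = scores[:, :-1] @ e
        inner[:, :-1] = scores[:, -1][:, None] * e[None, :]
        # outer update
        new_w = []
        for j in range(nb):
            z = inner[:, j]
            z_nrm = np.linalg.norm(z)
            if z_nrm == 0:
                raise ValueError("degenerate inner proxy (zero variance)")
            z = z * (root / z_nrm)
            if modes[j] == "A":
                wj = Xb[j].T @ z / (n - 1)
            else:
                wj = pinv[j] @ z
            s = Xb[j] @ wj
            s_nrm = np.linalg.norm(s) / root
            if s_nrm == 0:
                raise ValueError("degenerate block score (zero variance)")
            new_w.append(wj / s_nrm)
        delta = max(np.abs(nw - ow).max() for nw, ow in zip(new_w, w))
        w = new_w
        for j in range(nb):
            scores[:, j] = Xb[j] @ w[j]
        if delta < tol:
            break
    return w, scores, it, delta


class PLSPathModel(BaseEstimator):
    """PLS path model with formative/reflective blocks and one outcome.

    Parameters
    ----------
    spec : MeasurementSpec
        Exogenous blocks and the single-indicator endogenous block. If
        None, ``fit`` requires ``endogenous=`` and uses the default
        four-factor ecological spec.
    scheme : {"centroid", "factorial", "path"}, default "centroid"
        Inner weighting scheme.
    tol : float, default 1e-7
        Convergence threshold on the largest outer-weight change.
    max_iter : int, default 300

    Attributes
    ----------
    outer_weights_ : dict of block name -> ndarray
    outer_loadings_ : dict of block name -> ndarray (indicator-score r)
    scores_ : DataFrame of latent scores (mean 0, variance 1, ddof=1)
    path_coefficients_ : Series, one standardized beta per exogenous latent
    r_squared_ : float, R^2 of the endogenous latent
    n_iter_, weight_change_ : convergence diagnostics
    """

    def __init__(self, spec: MeasurementSpec | None = None,
                 scheme: str = "centroid", tol: float = 1e-7,
                 max_iter: int = 300):
        self.spec = spec
        self.scheme = scheme
        self.tol = tol
        self.max_iter = max_iter

    def _resolved_spec(self, endogenous=None) -> MeasurementSpec:
        if self.spec is not None:
            return self.spec
        if endogenous is None:
            raise ValueError("either spec or endogenous metric name required")
        return default_measurement_spec(endogenous)

    def fit(self, data: pd.DataFrame, endogenous: str | None = None):
        """Fit on a site x indicator table containing every indicator."""
        spec = self._resolved_spec(endogenous)
        missing = [c for c in spec.all_indicators() if c not in data.columns]
        if missing:
            raise ValueError(f"data missing indicator columns: {missing}")
        sub = data[spec.all_indicators()]
        if sub.isna().any().any():
            raise ValueError("missing values in indicators")
        blocks = spec.blocks
        Xb = []
        for b in blocks:
            Xraw = sub[list(b.indicators)].to_numpy(dtype=float)
            try:
                Xs = _standardize(Xraw)
            except ValueError as exc:
                raise ValueError(f"block {b.name!r}: {exc}") from exc
            if b.mode == "B" and np.linalg.matrix_rank(Xs) < Xs.shape[1]:
                raise ValueError(f"singular formative block {b.name!r}")
            Xb.append(Xs)
        modes = [b.mode for b in blocks]
        w, scores, it, delta = _fit_core(Xb, modes, self.scheme,
                                         self.tol, self.max_iter)
        if delta >= self.tol:
            raise ConvergenceError(
                f"outer weights did not converge in {it} iterations "
                f"(last change {delta:.3e})"
            )
        n = scores.shape[0]
        # sign alignment: anchor (first) indicator loading positive
        for j, b in enumerate(blocks):
            loading = (Xb[j][:, 0] @ scores[:, j]) / (n - 1)
            if loading < 0:
                w[j] = -w[j]
                scores[:, j] = -scores[:, j]
        coef, *_ = np.linalg.lstsq(scores[:, :-1], scores[:, -1], rcond=None)
        resid = scores[:, -1] - scores[:, :-1] @ coef
        self.spec_ = spec
        self.outer_weights_ = {b.name: w[j] for j, b in enumerate(blocks)}
        self.outer_loadings_ = {
            b.name: Xb[j].T @ scores[:, j] / (n - 1)
            for j, b in enumerate(blocks)
        }
        self.scores_ = pd.DataFrame(
            scores, index=data.index, columns=[b.name for b in blocks]
        )
        self.path_coefficients_ = pd.Series(
            coef, index=[b.name for b in blocks[:-1]], name="beta"
        )
        self.r_squared_ = float(1.0 - (resid @ resid) / (scores[:, -1] @ scores[:, -1]))
        self.n_iter_, self.weight_change_ = it, float(delta)
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Endogenous latent score predicted from the exogenous paths."""
        check_is_fitted(self, "path_coefficients_")
        scores = self.transform(data)
        return scores[:, :-1] @ self.path_coefficients_.to_numpy()

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Latent scores of (possibly new) sites under the fitted weights."""
        check_is_fitted(self, "outer_weights_")
        blocks = self.spec_.blocks
        out = np.empty((len(data), len(blocks)))
        for j, b in enumerate(blocks):
            X = _standardize(data[list(b.indicators)].to_numpy(dtype=float))
            out[:, j] = X @ self.outer_weights_[b.name]
        return out


def _paths_from_raw(Xraw: list, modes: list, scheme: str, tol: float,
                    max_iter: int) -> np.ndarray:
    """Standardize raw block matrices, fit, sign-align, return paths."""
    Xb = [_standardize(X) for X in Xraw]
    w, scores, it, delta = _fit_core(Xb, modes, scheme, tol, max_iter)
    if delta >= tol:
        raise ConvergenceError(f"no convergence in {it} iterations")
    n = scores.shape[0]
    for j in range(len(Xb)):
        if (Xb[j][:, 0] @ scores[:, j]) < 0:
            scores[:, j] = -scores[:, j]
    coef, *_ = np.linalg.lstsq(scores[:, :-1], scores[:, -1], rcond=None)
    return coef


@dataclass
class BootstrapResult:
    """Bootstrap inference for path coefficients (the per-metric table row)."""

    table: pd.DataFrame  # index: factor; beta, se, ci_low, ci_high, significant
    n_effective: int
    n_dropped: int


def bootstrap_paths(data: pd.DataFrame, spec: MeasurementSpec | None = None,
                    endogenous: str | None = None, n_boot: int = 10_000,
                    seed=None, scheme: str = "centroid", tol: float = 1e-7,
                    max_iter: int = 300, ci: float = 0.95) -> BootstrapResult:
    """Site bootstrap of the path coefficients.

    Sites are resampled with replacement ``n_boot`` times and the model
    refitted; replicates that fail (non-convergence or a degenerate block
    after resampling) are dropped, with a warning when more than 5% drop.
    SE is the bootstrap standard deviation; the CI is percentile; a path is
    significant when its CI excludes zero.
    """
    model = PLSPathModel(spec=spec, scheme=scheme, tol=tol, max_iter=max_iter)
    model.fit(data, endogenous=endogenous)
    rng = np.random.default_rng(seed)
    n = len(data)
    blocks = model.spec_.blocks
    modes = [b.mode for b in blocks]
    Xraw = [data[list(b.indicators)].to_numpy(dtype=float) for b in blocks]
    reps, dropped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps.append(_paths_from_raw([X[idx] for X in Xraw], modes,
                                        scheme, tol, max_iter))
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            dropped += 1
    if dropped > 0.05 * n_boot:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped",
                      stacklevel=2)
    reps = np.array(reps)
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    table = pd.DataFrame({
        "beta": model.path_coefficients_,
        "se": reps.std(axis=0, ddof=1),
        "ci_low": lo,
        "ci_high": hi,
    })
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return BootstrapResult(table=table, n_effective=len(reps), n_dropped=dropped)


def _vip(pls: PLSRegression) -> np.ndarray:
    """Variable importance in projection over the fitted components."""
    W = pls.x_weights_          # (p, a)
    T = pls.x_scores_           # (n, a)
    Q = pls.y_loadings_         # (1, a)
    p = W.shape[0]
    ssy = (Q.ravel() ** 2) * (T**2).sum(axis=0)
    wnorm2 = (W**2).sum(axis=0)
    return np.sqrt(p * ((W**2 / wnorm2) @ ssy) / ssy.sum())


def pls1_screening(env: pd.DataFrame, y, max_components: int | None = None,
                   vip_threshold: float = 1.0) -> list:
    """Screen environmental variables against one community metric.

    A PLS1 regression of the (standardized) metric on the standardized
    candidate variables is cross-validated leave-one-out; the component
    count is set at the first local minimum of the RMSEP curve (global
    minimum, with a warning, when the curve is monotone). Variables with
    VIP >= ``vip_threshold`` on the retained components are returned.
    """
    X = env.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("screening needs at least 5 sites")
    a_max = min(p, n - 2) if max_components is None else max_components
    rmsep = np.empty(a_max)
    for a in range(1, a_max + 1):
        errs = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            pls = PLSRegression(n_components=a, scale=True)
            pls.fit(X[mask], yv[mask])
            errs[i] = yv[i] - pls.predict(X[i][None, :]).ravel()[0]
        rmsep[a - 1] = np.sqrt(np.mean(errs**2))
    a_star = None
    for a in range(a_max - 1):
        if rmsep[a] < rmsep[a + 1]:
            a_star = a + 1
            break
    if a_star is None:
        a_star = int(np.argmin(rmsep)) + 1
        warnings.warn("no local RMSEP minimum; using global minimum",
                      stacklevel=2)
    pls = PLSRegression(n_components=a_star, scale=True)
    pls.fit(X, yv)
    vip = _vip(pls)
    return [c for c, v in zip(env.columns, vip) if v >= vip_threshold]


class PLS1Screener(BaseEstimator):
    """Variable screening as a fit/transform selector.

    ``fit(X, y)`` runs :func:`pls1_screening` (LOO-RMSEP component choice,
    VIP threshold); ``transform(X)`` subsets to the retained columns.
    """

    def __init__(self, max_components: int | None = None,
                 vip_threshold: float = 1.0):
        self.max_components = max_components
        self.vip_threshold = vip_threshold

    def fit(self, X: pd.DataFrame, y):
        self.retained_ = pls1_screening(
            X, y, max_components=self.max_components,
            vip_threshold=self.vip_threshold)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return X[self.retained_]

    def get_support(self, X_columns) -> list:
        check_is_fitted(self, "retained_")
        return [c in self.retained_ for c in X_columns]


def path_summary_stats(path_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-factor summary of a metrics x factors path-coefficient table.

    Returns two rows: the mean of absolute path coefficients, and the
    coefficient of variation 100 * sd / |mean| computed on the signed
    coefficients (sample sd, ddof=1).
    """
    b = path_matrix.to_numpy(dtype=float)
    mean_abs = np.abs(b).mean(axis=0)
    means = b.mean(axis=0)
    sds = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(sds == 0, 0.0, 100.0 * sds / np.abs(means))
    return pd.DataFrame(
        [mean_abs, cv],
        index=["mean_abs_path", "cv_percent"],
        columns=path_matrix.columns,
    )
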