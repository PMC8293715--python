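"""Statistical layer: Rapoport regressions, standardized single-predictor
OLS, simultaneous-autoregressive (SAR) error models, and repeated
random-forest permutation importance (%IncMSE).

The SAR variant is the *error* model ``y = X b + u, u = lambda W u + eps``
with a row-standardized symmetric k-nearest-neighbour weights matrix: the
standard choice when the goal is to absorb spatial autocorrelation in the
residuals rather than model a diffusion process. ``lambda`` is estimated
by maximum likelihood with the log-determinant evaluated through the
eigenvalues of W.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
import statsmodels.api as sm

__all__ = [
    "InferenceError",
    "RegressionResult",
    "ImportanceResult",
    "SpatialWeights",
    "standardize",
    "ols_single",
    "rapoport_regression",
    "build_weights",
    "sar_error_fit",
    "rf_importance",
    "significance_stars",
]

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    """One fitted relationship: coefficient of ``predictor`` on the response."""

    predictor: str
    coef: float
    se: float
    p_value: float
    adj_r2: float | None
    model_kind: str  # "OLS" or "SAR"
    lam: float | None = None
    aic: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class ImportanceResult:
    """Mean %IncMSE per predictor over repeated random-forest fits."""

    importances: pd.DataFrame      # predictor, mean_pct_inc_mse, sd_pct_inc_mse
    per_run: np.ndarray            # (n_runs, n_predictors)
    pct_var_explained: float       # mean over runs
    n_runs: int
    seed: int


@dataclass(frozen=True)
class SpatialWeights:
    """Row-standardized spatial weights from a symmetric neighbour graph."""

    matrix: np.ndarray             # row-standardized
    adjacency: np.ndarray          # binary symmetric graph
    neighbor_rule: str
    row_standardized: bool = True
    _eigs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized matrix.

        ``D^-1 A`` is similar to the symmetric ``D^-1/2 A D^-1/2``, so the
        spectrum is real and can be obtained with a symmetric solver.
        """
        if self._eigs is not None:
            return self._eigs
        deg = self.adjacency.sum(axis=1)
        if np.all(deg == 0):
            return np.zeros(self.n)
        d = np.where(deg > 0, deg, 1.0)
        sym = self.adjacency / np.sqrt(d[:, None] * d[None, :])
        return np.linalg.eigvalsh(sym)


def standardize(values) -> np.ndarray:
    """z-scores with sample (n-1) standard deviation; constant input errors."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InferenceError("standardize needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InferenceError("cannot standardize a constant variable (SD = 0)")
    return (x - x.mean()) / sd


def ols_single(y, x, predictor: str = "x", standardize_inputs: bool = True) -> RegressionResult:
    """Single-predictor OLS; on standardized variables the coefficient is
    the Pearson correlation."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise InferenceError(f"length mismatch: y has {y.size}, x has {x.size}")
    if standardize_inputs:
        y = standardize(y)
        x = standardize(x)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        predictor=predictor,
        coef=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        model_kind="OLS",
        n=int(y.size),
    )


def rapoport_regression(
    profile: pd.DataFrame,
    alpha: float = 0.05,
    require_significance: bool = True,
) -> tuple[RegressionResult, bool]:
    """OLS of the per-plot mean range size on plot elevation.

    The elevational range-size gradient is judged "supported" when the
    slope is positive (and, by default, significant at ``alpha``). Plots
    with a missing mean (no species of the group) are dropped.
    """
    sub = profile.dropna(subset=["mean_range_m"])
    if len(sub) < 3:
        raise InferenceError(
            f"Rapoport regression needs >= 3 plots with data, got {len(sub)}"
        )
    x = sub["elevation_m"].to_numpy(dtype=float)
    y = sub["mean_range_m"].to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    res = RegressionResult(
        predictor="elevation_m",
        coef=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        model_kind="OLS",
        n=int(len(sub)),
    )
    supported = res.coef > 0 and (not require_significance or res.p_value < alpha)
    return res, bool(supported)


def build_weights(coords, k: int = 5) -> SpatialWeights:
    """Symmetric k-nearest-neighbour weights, row-standardized.

    Uses the union rule (i ~ j if either is among the other's k nearest),
    which keeps the underlying graph symmetric before standardization.
    Distance ties are broken deterministically by input order.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < k + 1:
        raise InferenceError(f"need n >= k+1 plots for k={k} neighbours, got n={n}")
    d = cdist(pts, pts)
    if (d + np.eye(n) == 0).any():
        logger.warning("duplicate coordinates: neighbour ties broken by plot order")
    adj = np.zeros((n, n), dtype=float)
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        nearest = [j for j in order if j != i][:k]
        adj[i, nearest] = 1.0
    adj = np.maximum(adj, adj.T)  # union rule
    rowsum = adj.sum(axis=1)
    W = adj / np.where(rowsum > 0, rowsum, 1.0)[:, None]
    return SpatialWeights(matrix=W, adjacency=adj, neighbor_rule=f"knn(k={k}, union)")


def sar_error_fit(y, x, weights: SpatialWeights, predictor: str = "x") -> RegressionResult:
    """Maximum-likelihood SAR error model with a single predictor.

    Model: ``y = b0 + b1 x + u``, ``u = lambda W u + eps``. For a candidate
    ``lambda`` the spatial filter ``A = I - lambda W`` whitens both sides;
    the concentrated log-likelihood adds ``log|A|`` evaluated from the
    (real) eigenvalues of W, and ``lambda`` is found by bounded scalar
    search on ``(1/min(eig), 1)``. AIC counts the betas plus ``lambda``
    and ``sigma^2``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise InferenceError(f"length mismatch: y has {y.size}, x has {x.size}")
    n = y.size
    W = weights.matrix
    if W.shape != (n, n):
        raise InferenceError(f"weights are {W.shape}, expected ({n}, {n})")
    X = np.column_stack([np.ones(n), x])
    k_beta = X.shape[1]

    eigs = weights.eigenvalues()
    degenerate = np.allclose(W, 0.0)

    def neg_profile_loglik(lam: float) -> float:
        A = np.eye(n) - lam * W
        ys, Xs = A @ y, A @ X
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            return np.inf
        logdet = float(np.sum(np.log(1.0 - lam * eigs)))
        ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
        return -ll

    if degenerate:
        lam_hat = 0.0
    else:
        lam_min = 1.0 / eigs.min() if eigs.min() < 0 else -0.999
        lo, hi = lam_min + 1e-6, 1.0 - 1e-6
        opt = optimize.minimize_scalar(
            neg_profile_loglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if not opt.success:
            raise InferenceError(f"SAR lambda search failed: {opt.message}")
        lam_hat = float(opt.x)

    A = np.eye(n) - lam_hat * W
    ys, Xs = A @ y, A @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / n
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    logdet = float(np.sum(np.log(1.0 - lam_hat * eigs))) if not degenerate else 0.0
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
    k_total = k_beta + 2  # betas + lambda + sigma^2
    aic = 2.0 * k_total - 2.0 * loglik
    z = beta[1] / se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    return RegressionResult(
        predictor=predictor,
        coef=float(beta[1]),
        se=float(se[1]),
        p_value=float(p),
        adj_r2=None,
        model_kind="SAR",
        lam=lam_hat,
        aic=float(aic),
        n=int(n),
    )


# --------------------------------------------------------------------------
# random-forest permutation importance


def _oob_masks(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    """Out-of-bag sample masks per tree, regenerated from tree seeds.

    Each fitted tree carries the integer seed that drew its bootstrap
    sample (``randint(0, n, n, dtype=int32)``); replaying that draw
    recovers exactly which samples the tree never saw. Guarded by a test
    against the forest's own ``oob_score_``.
    """
    masks = []
    for est in forest.estimators_:
        rs = np.random.RandomState(est.random_state)
        sampled = rs.randint(0, n, n, dtype=np.int32)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def oob_predictions(forest: RandomForestRegressor, X: np.ndarray,
                    masks: list[np.ndarray] | None = None):
    """Aggregate per-sample OOB predictions; returns ``(pred, n_trees_per_sample)``."""
    n = X.shape[0]
    if masks is None:
        masks = _oob_masks(forest, n)
    total = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    for est, mask in zip(forest.estimators_, masks):
        if mask.any():
            total[mask] += est.predict(X[mask])
            cnt[mask] += 1
    with np.errstate(invalid="ignore"):
        pred = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return pred, cnt


def _oob_mse(forest, X, y, masks) -> float:
    pred, cnt = oob_predictions(forest, X, masks)
    ok = cnt > 0
    return float(np.mean((y[ok] - pred[ok]) ** 2))


def rf_importance(
    y,
    X: pd.DataFrame,
    n_runs: int = 1000,
    seed: int = 0,
    n_estimators: int = 100,
    method: str = "oob",
    holdout_fraction: float = 0.3,
) -> ImportanceResult:
    """Repeated random-forest permutation importance.

    Per run a fresh forest is fitted and, for each predictor, its column is
    permuted; %IncMSE is ``100 * (MSE_permuted - MSE_baseline) /
    MSE_baseline`` with the MSE taken out-of-bag (default) or on a held-out
    split (``method="holdout"``). Results are averaged over ``n_runs``
    independently seeded runs, alongside the mean percent variance
    explained ``100 * (1 - MSE_baseline / Var(y))``.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    n, p = Xv.shape
    if y.size != n:
        raise InferenceError("y and X length mismatch")
    if n < 20:
        raise InferenceError(f"rf_importance needs n >= 20, got {n}")
    if p < 2:
        raise InferenceError("rf_importance needs >= 2 predictors")
    if np.ptp(y) == 0:
        raise InferenceError("constant response")
    if n_runs < 1:
        raise InferenceError("n_runs must be >= 1")

    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_runs)]
    per_run = np.empty((n_runs, p))
    pve = np.empty(n_runs)
    var_y = float(np.var(y, ddof=1))
    for r, rseed in enumerate(run_seeds):
        rng = np.random.default_rng(rseed)
        if method == "oob":
            forest = RandomForestRegressor(
                n_estimators=n_estimators, random_state=rseed, bootstrap=True
            ).fit(Xv, y)
            masks = _oob_masks(forest, n)
            base = _oob_mse(forest, Xv, y, masks)
            for j in range(p):
                Xp = Xv.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                per_run[r, j] = 100.0 * (_oob_mse(forest, Xp, y, masks) - base) / base
        elif method == "holdout":
            idx = rng.permutation(n)
            n_test = max(1, int(round(holdout_fraction * n)))
            test, train = idx[:n_test], idx[n_test:]
            forest = RandomForestRegressor(
                n_estimators=n_estimators, random_state=rseed
            ).fit(Xv[train], y[train])
            base = float(np.mean((y[test] - forest.predict(Xv[test])) ** 2))
            for j in range(p):
                Xp = Xv[test].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                per_run[r, j] = 100.0 * (
                    float(np.mean((y[test] - forest.predict(Xp)) ** 2)) - base
                ) / base
        else:
            raise InferenceError(f"unknown method {method!r}")
        pve[r] = 100.0 * (1.0 - base / var_y)

    importances = pd.DataFrame(
        {
            "predictor": names,
            "mean_pct_inc_mse": per_run.mean(axis=0),
            "sd_pct_inc_mse": per_run.std(axis=0, ddof=1) if n_runs > 1 else 0.0,
        }
    )
    return ImportanceResult(
        importances=importances,
        per_run=per_run,
        pct_var_explained=float(pve.mean()),
        n_runs=int(n_runs),
        seed=int(seed),
    )


def significance_stars(p: float) -> str:
    """Conventional table stars: * p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
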