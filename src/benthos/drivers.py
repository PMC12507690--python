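"""Driver inference: Poisson GLMs, random-forest importance, dependence
surfaces, and thermal-threshold detection.

Richness per (latitude, depth) cell is modelled as Poisson with a log link
and an additive log-effort offset.  Model selection is all-subsets by AIC;
standard errors can be inflated for first-order autocorrelation of the
residuals along latitude, standing in for a serially corrected linear model.
Random-forest importance is the %IncMSE: the percentage increase in held-out
mean-squared error when one predictor's values are permuted, from a forest
trained on a 70:30 train:test split.  Partial-dependence (clamp-and-average)
curves over temperature feed a two-segment piecewise-linear fit
whose join estimates the thermal threshold below which richness collapses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Poisson GLMs
# --------------------------------------------------------------------------- #
@dataclass
class ModelSpec:
    response: str = "richness"
    predictors: tuple = ()
    offset: str | None = None          # column already on the log scale
    error_adjustment: str = "none"     # none | ar1
    order_by: str | None = "lat_bin"   # ordering for the AR(1) estimate


@dataclass
class FitResult:
    predictors: tuple
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    r2: float                          # squared corr of fitted vs observed
    converged: bool = True
    ar1_rho: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})


def fit_poisson(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood Poisson regression with log link and log-effort offset.

    With ``error_adjustment='ar1'`` the standard errors are inflated by
    sqrt((1 + rho) / (1 - rho)) where rho is the lag-1 autocorrelation of the
    Pearson residuals along ``order_by`` -- a first-order stand-in for
    serially correlated errors in latitudinal series.
    """
    cols = [spec.response, *spec.predictors] + ([spec.offset] if spec.offset else [])
    if table[cols].isna().any().any():
        raise ValueError("missing values in model columns")
    y = table[spec.response].to_numpy(float)
    X = sm.add_constant(table[list(spec.predictors)], has_constant="add")
    offset = table[spec.offset].to_numpy(float) if spec.offset else None
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    try:
        res = model.fit()
        converged = bool(res.converged)
    except Exception as exc:                     # separation / non-convergence
        log.warning("Poisson fit failed for %s: %s", spec.predictors, exc)
        nan = pd.Series(np.nan, index=X.columns)
        return FitResult(spec.predictors, nan, nan, nan, np.inf, np.nan, False)
    bse, pvals, rho = res.bse, res.pvalues, None
    if spec.error_adjustment == "ar1":
        order = (np.argsort(table[spec.order_by].to_numpy())
                 if spec.order_by and spec.order_by in table else slice(None))
        resid = np.asarray(res.resid_pearson)[order]
        if resid.size > 2 and resid.std() > 0:
            rho = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
            rho = float(np.clip(rho, -0.99, 0.99))
            infl = np.sqrt((1 + rho) / (1 - rho)) if rho > 0 else 1.0
            bse = bse * infl
            z = res.params / bse
            pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=bse.index)
    fitted = np.asarray(res.fittedvalues)
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return FitResult(spec.predictors, res.params, bse, pvals, float(res.aic),
                     r2, converged, rho)


def all_subsets_select(table: pd.DataFrame, predictors, spec: ModelSpec | None = None
                       ) -> pd.DataFrame:
    """Fit every predictor subset (including intercept-only); rank by AIC.

    Returns a frame with one row per subset, AIC-ascending, with delta-AIC
    relative to the best converged model.  Fits that fail are flagged and
    excluded from the ranking order (pushed to the bottom with infinite AIC).
    """
    predictors = list(predictors)
    if len(predictors) > 12:
        raise ValueError("all-subsets selection limited to 12 predictors")
    base = spec or ModelSpec()
    rows = []
    for k in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, k):
            fit = fit_poisson(table, ModelSpec(
                response=base.response, predictors=subset, offset=base.offset,
                error_adjustment=base.error_adjustment, order_by=base.order_by))
            rows.append({"predictors": subset, "k": k, "aic": fit.aic,
                         "r2": fit.r2, "converged": fit.converged, "fit": fit})
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best = out.loc[out["converged"], "aic"].min()
    out["delta_aic"] = out["aic"] - best
    return out


# --------------------------------------------------------------------------- #
# random forest importance
# --------------------------------------------------------------------------- #
@dataclass
class ForestResult:
    model: RandomForestRegressor
    predictors: list
    importance: pd.DataFrame           # index=predictor; inc_mse, rank
    mse_test: float
    X_train: pd.DataFrame = field(repr=False, default=None)
    X_test: pd.DataFrame = field(repr=False, default=None)


def random_forest_importance(table: pd.DataFrame, response: str, predictors,
                             n_trees: int = 1000, mtry: int = 3,
                             test_size: float = 0.30, seed: int = 0,
                             oob: bool = False) -> ForestResult:
    """Regression forest with permutation importance (%IncMSE).

    The forest is trained on the 70% split; %IncMSE for each predictor is
    ``100 * (MSE_permuted - MSE) / MSE`` on the held-out 30% (or out-of-bag
    style on the training data when ``oob=True``).  Deterministic under
    ``seed``.
    """
    predictors = list(predictors)
    if len(table) < 10:
        raise ValueError("need at least 10 rows for a forest fit")
    if mtry > len(predictors):
        log.warning("mtry=%d clamped to %d predictors", mtry, len(predictors))
        mtry = len(predictors)
    X = table[predictors]
    y = table[response].to_numpy(float)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_size,
                                              random_state=seed)
    model = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                  random_state=seed, oob_score=oob)
    model.fit(X_tr, y_tr)
    if oob:
        X_eval, y_eval = X_tr, y_tr
        base_pred = model.oob_prediction_
    else:
        X_eval, y_eval = X_te, y_te
        base_pred = model.predict(X_eval)
    mse0 = float(np.mean((y_eval - base_pred) ** 2))
    rng = np.random.default_rng(seed)
    inc = {}
    for c in predictors:
        Xp = X_eval.copy()
        Xp[c] = rng.permutation(Xp[c].to_numpy())
        msep = float(np.mean((y_eval - model.predict(Xp)) ** 2))
        inc[c] = 100.0 * (msep - mse0) / mse0 if mse0 > 0 else 0.0
    imp = pd.DataFrame({"inc_mse": pd.Series(inc)})
    imp["rank"] = imp["inc_mse"].rank(ascending=False, method="first").astype(int)
    return ForestResult(model, predictors, imp.sort_values("rank"),
                        mse0, X_tr, X_te)


# --------------------------------------------------------------------------- #
# dependence surfaces
# --------------------------------------------------------------------------- #
@dataclass
class DependenceSurface:
    variables: tuple
    grids: tuple                       # one or two 1-D grids
    values: np.ndarray                 # (n1,) or (n1, n2)
    extrapolated: bool = False


def _predict(model, X: pd.DataFrame) -> np.ndarray:
    fn = model if callable(model) else model.predict
    return np.asarray(fn(X), dtype=float)


def _default_grid(x: np.ndarray, step: float | None, n: int = 50) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if step is not None:
        # round-number grid clipped inside the observed range
        return np.arange(np.ceil(lo / step) * step, hi + step / 2, step)
    return np.linspace(lo, hi, n)


def partial_dependence(model, X: pd.DataFrame, variable: str,
                       grid=None, step: float | None = None,
                       sample_rows: int | None = None) -> DependenceSurface:
    """PD(v) = mean prediction over the data with ``variable`` clamped to v.

    ``sample_rows`` caps the number of background rows (an evenly spaced,
    deterministic subset) to bound prediction cost on large tables.
    """
    x = X[variable].to_numpy(float)
    grid = np.asarray(grid, float) if grid is not None else _default_grid(x, step)
    extrap = bool(grid.min() < x.min() - 1e-12 or grid.max() > x.max() + 1e-12)
    if extrap:
        log.warning("partial dependence grid extends beyond the data range")
    if sample_rows is not None and len(X) > sample_rows:
        X = X.iloc[np.unique(np.linspace(0, len(X) - 1, sample_rows).astype(int))]
    big = pd.concat([X] * grid.size, ignore_index=True)
    big[variable] = np.repeat(grid, len(X))
    vals = _predict(model, big).reshape(grid.size, len(X)).mean(axis=1)
    return DependenceSurface((variable,), (grid,), vals, extrap)


def pairwise_interaction(model, X: pd.DataFrame, var1: str, var2: str,
                         grid1=None, grid2=None, n: int = 20) -> DependenceSurface:
    """2-D partial dependence: both variables jointly clamped over a lattice."""
    g1 = (np.asarray(grid1, float) if grid1 is not None
          else _default_grid(X[var1].to_numpy(float), None, n))
    g2 = (np.asarray(grid2, float) if grid2 is not None
          else _default_grid(X[var2].to_numpy(float), None, n))
    vals = np.empty((g1.size, g2.size))
    for i, v1 in enumerate(g1):
        big = pd.concat([X] * g2.size, ignore_index=True)
        big[var1] = v1
        big[var2] = np.repeat(g2, len(X))
        vals[i] = _predict(model, big).reshape(g2.size, len(X)).mean(axis=1)
    return DependenceSurface((var1, var2), (g1, g2), vals)


# --------------------------------------------------------------------------- #
# thermal threshold
# --------------------------------------------------------------------------- #
@dataclass
class ThresholdFit:
    breakpoint: float | None
    identified: bool
    ci: tuple | None = None            # bootstrap percentile interval
    rss_line: float = np.nan
    rss_split: float = np.nan


def _line_rss(t: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


def _segmented_fit(t: np.ndarray, y: np.ndarray, candidates: np.ndarray
                   ) -> tuple[float, float]:
    """Best two-segment piecewise-linear fit; returns (breakpoint, rss).

    Each candidate join splits the curve into independent left/right linear
    fits (no continuity constraint), which locates the change point equally
    well for hinge-shaped and step-shaped dependence curves.
    """
    best_c, best_rss = np.nan, np.inf
    for c in candidates:
        left, right = t < c, t >= c
        if left.sum() < 2 or right.sum() < 2:
            continue
        rss = _line_rss(t[left], y[left]) + _line_rss(t[right], y[right])
        if rss < best_rss - 1e-15:
            best_rss, best_c = rss, float(c)
    return best_c, best_rss


def threshold_estimate(surface: DependenceSurface, n_boot: int = 200,
                       seed: int = 0, min_improvement: float = 0.05
                       ) -> ThresholdFit:
    """Estimate the temperature breakpoint of a 1-D dependence curve.

    Fits a two-segment piecewise-linear model for every candidate join on
    the PD grid (interior points only) and keeps the join minimising the
    residual sum of squares.  The breakpoint is flagged unidentified when
    the split improves on a single straight line by less than
    ``min_improvement`` (relative RSS), e.g. for a monotone linear curve.
    A bootstrap over the curve's points (``n_boot`` refits) gives a
    percentile interval.
    """
    (t,), y = surface.grids, np.asarray(surface.values, float)
    t = np.asarray(t, float)
    if t.size < 5:
        raise ValueError("need at least 5 grid points for a hinge fit")
    rss1 = _line_rss(t, y)
    candidates = t[2:-2]
    c, rss2 = _segmented_fit(t, y, candidates)
    scale = float(np.sum((y - y.mean()) ** 2))
    if scale <= 0 or rss1 <= 1e-12 * max(scale, 1.0):
        # flat or perfectly linear curve: no curvature to locate a join in
        return ThresholdFit(None, False, None, rss1, rss2)
    improvement = (rss1 - rss2) / rss1
    if not np.isfinite(c) or improvement < min_improvement:
        return ThresholdFit(None, False, None, rss1, rss2)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bps = []
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, t.size, t.size))
            if np.unique(t[idx]).size < 5:
                continue
            bc, _ = _segmented_fit(t[idx], y[idx], candidates)
            if np.isfinite(bc):
                bps.append(bc)
        if bps:
            ci = (float(np.percentile(bps, 2.5)), float(np.percentile(bps, 97.5)))
    return ThresholdFit(float(c), True, ci, rss1, rss2)
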