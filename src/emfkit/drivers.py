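"""Driver attribution: regressions and random-forest variable importance.

Three views of what drives ecosystem (multi)functionality across plots:

* per-function simple OLS of each ecosystem function on SR and on FRic,
  reported as a Table-1-style grid of R2 and p;
* a multivariate linear model of EMF on biotic (SR, FRic) and abiotic
  (MAT, MAP, soil pH) predictors with standardized coefficients, so
  effect sizes are comparable across units;
* permutation importance from a random-forest regression, which captures
  nonlinear and interactive contributions the linear model cannot.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from sklearn.ensemble import RandomForestRegressor

from .io import ValidationError

__all__ = [
    "RegressionResult",
    "ImportanceResult",
    "simple_ols",
    "standardized_multiregression",
    "rf_importance",
    "function_regressions",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit with raw and standardized coefficients.

    ``coefficients`` etc. cover the predictors only; the intercept is kept
    separately.  Standardized coefficients are beta * sd(x)/sd(y) —
    identical to refitting on z-scored variables.
    """

    response_name: str
    predictor_names: list[str]
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int
    intercept: float = 0.0

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.coefficients,
                "std_coef": self.standardized_coefficients,
                "se": self.se,
                "t": self.t_values,
                "p": self.p_values,
            },
            index=self.predictor_names,
        )
        return (
            f"OLS: {self.response_name} ~ {' + '.join(self.predictor_names)}\n"
            f"n = {self.n}, R2 = {self.r_squared:.4f}, "
            f"intercept = {self.intercept:.4g}\n" + rows.round(4).to_string()
        )


@dataclass(frozen=True)
class ImportanceResult:
    """Permutation importance of each predictor for a random-forest fit.

    ``importance`` is the mean increase in training MSE when the predictor
    is shuffled (floored at 0; the unfloored value is kept in
    ``raw_importance``).  ``rank`` is 1 for the most important predictor.
    """

    predictor_names: list[str]
    importance: np.ndarray
    rank: np.ndarray
    n_trees: int
    seed: int
    raw_importance: np.ndarray = field(default=None, repr=False)

    def summary(self) -> str:
        rows = pd.DataFrame(
            {"importance": self.importance, "rank": self.rank},
            index=self.predictor_names,
        ).sort_values("rank")
        return (
            f"Random-forest permutation importance "
            f"({self.n_trees} trees, seed {self.seed})\n" + rows.round(5).to_string()
        )

    def top_predictor(self) -> str:
        return self.predictor_names[int(np.argmin(self.rank))]


def simple_ols(x, y, x_name: str = "x", y_name: str = "y") -> RegressionResult:
    """Simple linear regression y ~ x with R2 and a two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValidationError("simple OLS needs at least 3 observations")
    if not x.std(ddof=1) > 0:
        raise ValidationError(f"predictor {x_name!r} has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    sd_y = y.std(ddof=1)
    std_coef = fit.params[1] * x.std(ddof=1) / sd_y if sd_y > 0 else np.nan
    return RegressionResult(
        response_name=y_name,
        predictor_names=[x_name],
        coefficients=fit.params[1:].copy(),
        standardized_coefficients=np.array([std_coef]),
        se=fit.bse[1:].copy(),
        t_values=fit.tvalues[1:].copy(),
        p_values=fit.pvalues[1:].copy(),
        r_squared=float(fit.rsquared),
        n=len(x),
        intercept=float(fit.params[0]),
    )


def standardized_multiregression(
    y: pd.Series, X: pd.DataFrame, response_name: str | None = None
) -> RegressionResult:
    """Multivariate OLS with standardized coefficients.

    Raises on rank deficiency, naming the aliased predictors (columns
    whose removal does not reduce the design rank).
    """
    X = pd.DataFrame(X)
    y = pd.Series(y)
    if response_name is None:
        response_name = str(y.name) if y.name else "y"
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p + 1:
        raise ValidationError(
            f"need more observations ({n}) than predictors + 1 ({p + 1})"
        )
    design = np.column_stack([np.ones(n), Xv])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        aliased = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValidationError(
            f"rank-deficient design; aliased predictor(s): {', '.join(aliased)}"
        )
    fit = sm.OLS(yv, design).fit()
    sd_y = yv.std(ddof=1)
    if not sd_y > 0:
        raise ValidationError("response has zero variance")
    std = fit.params[1:] * Xv.std(axis=0, ddof=1) / sd_y
    return RegressionResult(
        response_name=response_name,
        predictor_names=names,
        coefficients=fit.params[1:].copy(),
        standardized_coefficients=std,
        se=fit.bse[1:].copy(),
        t_values=fit.tvalues[1:].copy(),
        p_values=fit.pvalues[1:].copy(),
        r_squared=float(fit.rsquared),
        n=n,
        intercept=float(fit.params[0]),
    )


def _column_seed(seed: int, name: str) -> list[int]:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return [int(seed) % (2**31), int.from_bytes(digest[:4], "big")]


def rf_importance(
    y,
    X: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    n_repeats: int = 10,
) -> ImportanceResult:
    """Permutation importance from a random-forest regression.

    Predictors are canonicalised by sorted name before fitting, and each
    column's shuffles use an RNG derived from (seed, hash of its name), so
    results are byte-identical across runs and invariant to the order the
    predictor columns are supplied in.  Importances are reported in the
    supplied column order.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValidationError("random forest needs at least 10 observations")
    if n_trees < 100:
        raise ValidationError("n_trees must be >= 100")
    if not y.std(ddof=1) > 0:
        raise ValidationError("response has zero variance")
    names = [str(c) for c in X.columns]
    order = sorted(range(len(names)), key=lambda j: names[j])
    Xs = X.iloc[:, order].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=int(n_trees), random_state=int(seed) % (2**31), n_jobs=1
    ).fit(Xs, y)
    base_mse = float(np.mean((y - rf.predict(Xs)) ** 2))
    raw = np.empty(len(names))
    for pos, j in enumerate(order):
        rng = np.random.default_rng(_column_seed(seed, names[j]))
        deltas = []
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[:, pos] = Xp[rng.permutation(len(y)), pos]
            deltas.append(np.mean((y - rf.predict(Xp)) ** 2) - base_mse)
        raw[j] = float(np.mean(deltas))
    importance = np.maximum(raw, 0.0)
    # rank 1 = most important; ties broken by predictor name for determinism
    order_desc = sorted(range(len(names)), key=lambda j: (-raw[j], names[j]))
    rank = np.empty(len(names), dtype=int)
    for r, j in enumerate(order_desc, start=1):
        rank[j] = r
    return ImportanceResult(
        predictor_names=names,
        importance=importance,
        rank=rank,
        n_trees=int(n_trees),
        seed=int(seed),
        raw_importance=raw,
    )


def function_regressions(
    functions, diversity: pd.DataFrame, metrics: tuple[str, ...] = ("SR", "FRic")
) -> pd.DataFrame:
    """Per-function simple OLS against each diversity metric.

    Returns one row per ecosystem function with Pearson r, R2 and p for
    every metric, plus Holm-adjusted p-values across the function family.
    Plots where a metric is undefined (NaN FRic) are dropped for that
    metric only.
    """
    out = pd.DataFrame(index=functions.data.columns)
    for metric in metrics:
        m = diversity[metric]
        ok = m.notna().to_numpy()
        x = m.to_numpy(dtype=float)[ok]
        pvals = []
        for col in functions.data.columns:
            yv = functions.data[col].to_numpy()[ok]
            res = simple_ols(x, yv, x_name=metric, y_name=col)
            r = np.sign(res.coefficients[0]) * np.sqrt(res.r_squared)
            out.loc[col, f"r_{metric}"] = r
            out.loc[col, f"R2_{metric}"] = res.r_squared
            out.loc[col, f"p_{metric}"] = res.p_values[0]
            pvals.append(res.p_values[0])
        out[f"p_holm_{metric}"] = multipletests(pvals, method="holm")[1]
    return out
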