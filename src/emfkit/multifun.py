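"""Ecosystem-multifunctionality indices.

Two complementary constructions over a plot x function matrix:

* the *averaging* index — z-score every function across plots, then
  average the z-scores within each plot;
* the *multiple-threshold* analysis — for every threshold t in 1..99 % of
  each function's maximum (the maximum itself being the mean of a
  function's top five observed values, to blunt outliers), count the
  functions each plot pushes past the threshold and regress that count on
  a diversity metric.  The slope-versus-threshold curve is summarized by
  five indices: T_min, T_max, T_mde, R_mde and P_mde.

``ThresholdAnalysis`` is the model object for the latter; its ``fit()``
returns a :class:`ThresholdResults` carrying the per-threshold curve, the
summary indices and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FunctionMatrix, ValidationError

__all__ = [
    "zscore_columns",
    "averaging_emf",
    "function_maxima",
    "threshold_counts",
    "count_matrix",
    "ThresholdIndices",
    "threshold_indices",
    "ThresholdAnalysis",
    "ThresholdResults",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = np.arange(1, 100)  # integer percents 1..99
ALPHA = 0.05


def zscore_columns(functions: FunctionMatrix) -> FunctionMatrix:
    """Standardize every function column to mean 0, sample sd 1 (ddof=1)."""
    df = functions.data
    if len(df) < 2:
        raise ValidationError("z-scores need at least 2 plots")
    sd = df.std(ddof=1)
    zero = [c for c in df.columns if not sd[c] > 0]
    if zero:
        raise ValidationError(
            f"zero-variance function column(s): {', '.join(zero)}"
        )
    return FunctionMatrix((df - df.mean()) / sd)


def averaging_emf(functions: FunctionMatrix) -> pd.Series:
    """Averaging multifunctionality index: per-plot mean of function z-scores."""
    z = zscore_columns(functions)
    return z.data.mean(axis=1).rename("EMF")


def function_maxima(functions: FunctionMatrix, k: int = 5) -> pd.Series:
    """Per-function maximum: mean of the k largest observed values.

    Values tied with the k-th largest are all included; with fewer than k
    plots the mean of all values is used.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    df = functions.data
    out = {}
    for col in df.columns:
        vals = np.sort(df[col].to_numpy())[::-1]
        if len(vals) <= k:
            out[col] = float(vals.mean())
        else:
            cutoff = vals[k - 1]
            out[col] = float(vals[vals >= cutoff].mean())
    return pd.Series(out, name="maximum")


def _usable_functions(maxima: pd.Series) -> pd.Index:
    bad = maxima.index[maxima <= 0]
    if len(bad):
        warnings.warn(
            "function(s) with non-positive maximum excluded from threshold "
            f"counts: {', '.join(bad)}"
        )
    return maxima.index[maxima > 0]


def threshold_counts(
    functions: FunctionMatrix, maxima: pd.Series | None = None, t: int = 50
) -> pd.Series:
    """Number of functions per plot meeting or exceeding t % of their maximum.

    "Exceed" is >=, so ties with the threshold count.  Functions whose
    maximum is non-positive (no meaningful percent-of-maximum) are
    excluded with a warning.
    """
    if not 1 <= t <= 99:
        raise ValidationError("threshold percent must be in [1, 99]")
    if maxima is None:
        maxima = function_maxima(functions)
    usable = _usable_functions(maxima)
    V = functions.data[usable].to_numpy()
    thr = (t / 100.0) * maxima[usable].to_numpy()
    counts = (V >= thr).sum(axis=1)
    return pd.Series(counts, index=functions.data.index, name=f"count_{t}")


def count_matrix(
    functions: FunctionMatrix,
    maxima: pd.Series | None = None,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, pd.Index]:
    """Counts for all thresholds at once: (T, P) array plus the usable functions."""
    if maxima is None:
        maxima = function_maxima(functions)
    usable = _usable_functions(maxima)
    V = functions.data[usable].to_numpy()  # P x F
    M = maxima[usable].to_numpy()
    thr = np.asarray(thresholds, dtype=float)[:, None, None] / 100.0 * M[None, None, :]
    counts = (V[None, :, :] >= thr).sum(axis=2)
    return counts, usable


@dataclass(frozen=True)
class ThresholdIndices:
    """Summary of a slope-versus-threshold curve.

    All fields are None when no threshold shows a significant positive
    diversity effect.

    T_min / T_max
        Smallest threshold (%) with a significantly positive slope, and
        the first threshold past T_mde where the slope is no longer
        significantly different from zero (or the largest significant
        threshold when significance persists to 99 %).
    T_mde
        Threshold (%) of the maximum diversity effect (argmax slope).
    R_mde
        Realized maximum effect: the slope at T_mde, in functions gained
        per unit diversity.
    P_mde
        R_mde as a percentage of the steepest slope possible — the slope
        that would carry the count from 0 to all F functions across the
        observed diversity range.
    """

    T_min: float | None
    T_max: float | None
    T_mde: float | None
    R_mde: float | None
    P_mde: float | None
    n_funcs: int
    diversity_range: float

    def is_defined(self) -> bool:
        return self.T_mde is not None


def threshold_indices(
    curve: pd.DataFrame, diversity_range: float, n_funcs: int
) -> ThresholdIndices:
    """Extract T_min/T_max/T_mde/R_mde/P_mde from a fitted threshold curve.

    ``curve`` must have columns threshold, slope, p (as produced by
    :meth:`ThresholdAnalysis.fit`).
    """
    t = curve["threshold"].to_numpy()
    slope = curve["slope"].to_numpy()
    p = curve["p"].to_numpy()
    sig_pos = (p < ALPHA) & (slope > 0)
    if not sig_pos.any():
        return ThresholdIndices(None, None, None, None, None, n_funcs, diversity_range)
    i_mde = int(np.argmax(slope))
    t_mde = float(t[i_mde])
    r_mde = float(slope[i_mde])
    t_min = float(t[sig_pos][0])
    past = (t > t_mde) & (p >= ALPHA)
    if past.any():
        t_max = float(t[past][0])
    else:
        t_max = float(t[sig_pos][-1])
    max_slope = n_funcs / diversity_range
    p_mde = 100.0 * r_mde / max_slope
    return ThresholdIndices(t_min, t_max, t_mde, r_mde, p_mde, n_funcs, diversity_range)


class ThresholdAnalysis:
    """Multiple-threshold diversity-multifunctionality model.

    Parameters
    ----------
    functions
        Plot x function matrix.
    diversity
        Per-plot diversity metric (SR or FRic), aligned with the function
        matrix's plots.  Plots with undefined diversity (NaN) are dropped
        with a warning.
    diversity_name
        Label used in output ("SR" or "FRic", typically).
    top_k
        Number of top values averaged into each function's maximum.
    thresholds
        Integer percents to scan (default 1..99).
    """

    def __init__(
        self,
        functions: FunctionMatrix,
        diversity: pd.Series,
        diversity_name: str | None = None,
        top_k: int = 5,
        thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    ):
        diversity = pd.Series(diversity)
        if diversity_name is None:
            diversity_name = str(diversity.name) if diversity.name else "diversity"
        if list(diversity.index) != list(functions.data.index):
            if not set(functions.data.index) <= set(diversity.index):
                raise ValidationError(
                    "diversity is not defined for every plot in the function matrix"
                )
            diversity = diversity.loc[functions.data.index]
        keep = diversity.notna().to_numpy()
        if not keep.all():
            dropped = list(diversity.index[~keep])
            warnings.warn(
                f"dropping {len(dropped)} plot(s) with undefined "
                f"{diversity_name}: {', '.join(dropped)}"
            )
            functions = FunctionMatrix(functions.data.loc[keep])
            diversity = diversity.loc[keep]
        if len(diversity) < 3:
            raise ValidationError("threshold regression needs at least 3 plots")
        if not diversity.std(ddof=1) > 0:
            raise ValidationError("diversity metric has no variance across plots")
        self.functions = functions
        self.diversity = diversity.astype(float)
        self.diversity_name = diversity_name
        self.top_k = int(top_k)
        self.thresholds = np.asarray(thresholds, dtype=int)

    def fit(self) -> "ThresholdResults":
        """OLS of function count on diversity at every threshold."""
        maxima = function_maxima(self.functions, self.top_k)
        counts, usable = count_matrix(self.functions, maxima, self.thresholds)
        x = self.diversity.to_numpy()
        n = len(x)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        Y = counts.astype(float)
        slope = (Y @ xc) / sxx
        intercept = Y.mean(axis=1) - slope * x.mean()
        resid = Y - (intercept[:, None] + slope[:, None] * x[None, :])
        rss = (resid**2).sum(axis=1)
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        # exact special cases: a constant count row has slope 0 and carries no
        # evidence (p = 1); a perfect non-constant fit has se = 0 and p = 0
        const = np.ptp(Y, axis=1) == 0
        slope[const] = 0.0
        se[const] = 0.0
        perfect = (~const) & (rss <= 1e-12 * np.maximum(1.0, (Y**2).sum(axis=1)))
        se[perfect] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        pvals[const] = 1.0
        pvals[perfect] = 0.0
        tcrit = stats.t.ppf(0.975, df)
        ci_low = slope - tcrit * se
        ci_high = slope + tcrit * se
        curve = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "slope": slope,
                "se": se,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p": pvals,
                "n_plots": n,
            }
        )
        div_range = float(x.max() - x.min())
        indices = threshold_indices(curve, div_range, len(usable))
        return ThresholdResults(
            curve=curve,
            indices=indices,
            diversity_name=self.diversity_name,
            n_plots=n,
            n_funcs=len(usable),
            diversity_range=div_range,
            maxima=maxima,
        )


@dataclass(frozen=True)
class ThresholdResults:
    """Fitted multiple-threshold analysis: per-threshold curve + indices."""

    curve: pd.DataFrame
    indices: ThresholdIndices
    diversity_name: str
    n_plots: int
    n_funcs: int
    diversity_range: float
    maxima: pd.Series

    def summary(self) -> str:
        ix = self.indices
        fmt = lambda v, u="": "undefined" if v is None else f"{v:.4g}{u}"
        lines = [
            "Multiple-threshold multifunctionality analysis",
            f"  diversity metric : {self.diversity_name}",
            f"  plots            : {self.n_plots}",
            f"  functions        : {self.n_funcs}",
            f"  diversity range  : {self.diversity_range:.4g}",
            f"  T_min            : {fmt(ix.T_min, '%')}",
            f"  T_max            : {fmt(ix.T_max, '%')}",
            f"  T_mde            : {fmt(ix.T_mde, '%')}",
            f"  R_mde            : {fmt(ix.R_mde)} functions per unit {self.diversity_name}",
            f"  P_mde            : {fmt(ix.P_mde, '%')}",
        ]
        return "\n".join(lines)
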