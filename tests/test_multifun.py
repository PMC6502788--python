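"""Averaging EMF index and the multiple-threshold analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from emfkit import (
    FunctionMatrix,
    ThresholdAnalysis,
    ValidationError,
    averaging_emf,
    function_maxima,
    threshold_counts,
    threshold_indices,
    zscore_columns,
)
from emfkit.multifun import count_matrix
from helpers import linear_count_fixture, make_functions


def test_zscore_columns_contract():
    fm = make_functions({"p1": [1.0], "p2": [2.0], "p3": [3.0]}, ["f"])
    z = zscore_columns(fm)
    assert z.data["f"].tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_zscore_rejects_constant_column():
    fm = make_functions({"p1": [1.0, 5.0], "p2": [2.0, 5.0]}, ["ok", "flat"])
    with pytest.raises(ValidationError, match="flat"):
        zscore_columns(fm)


@given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_emf_affine_invariance(a, b):
    rng = np.random.default_rng(17)
    vals = rng.normal(size=(10, 4))
    plots = [f"p{i}" for i in range(10)]
    fm = FunctionMatrix(pd.DataFrame(vals, index=plots, columns=list("wxyz")))
    scaled = vals.copy()
    scaled[:, 2] = a * scaled[:, 2] + b
    fm2 = FunctionMatrix(pd.DataFrame(scaled, index=plots, columns=list("wxyz")))
    assert averaging_emf(fm).to_numpy() == pytest.approx(
        averaging_emf(fm2).to_numpy(), abs=1e-10
    )


def test_averaging_emf_two_plot_hand_computation():
    fm = make_functions({"p1": [0.0, 0.0], "p2": [2.0, 2.0]}, ["f1", "f2"])
    emf = averaging_emf(fm)
    assert emf.tolist() == pytest.approx([-0.70710678, 0.70710678])


def test_averaging_emf_single_function_equals_zscores():
    fm = make_functions({"p1": [3.0], "p2": [5.0], "p3": [10.0]}, ["f"])
    emf = averaging_emf(fm)
    assert emf.to_numpy() == pytest.approx(zscore_columns(fm).data["f"].to_numpy())


def test_averaging_emf_column_permutation_invariant():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(6, 5))
    plots = [f"p{i}" for i in range(6)]
    cols = list("abcde")
    fm = FunctionMatrix(pd.DataFrame(vals, index=plots, columns=cols))
    fm2 = FunctionMatrix(pd.DataFrame(vals[:, ::-1], index=plots, columns=cols[::-1]))
    assert averaging_emf(fm).to_numpy() == pytest.approx(averaging_emf(fm2).to_numpy())


def test_function_maxima_top_five_mean():
    fm = make_functions(
        {f"p{i}": [v] for i, v in enumerate([10.0, 8.0, 6.0, 4.0, 2.0, 0.0])}, ["f"]
    )
    assert function_maxima(fm, k=5)["f"] == pytest.approx(6.0)


def test_function_maxima_fewer_plots_than_k():
    fm = make_functions({"p1": [1.0], "p2": [2.0], "p3": [3.0]}, ["f"])
    assert function_maxima(fm, k=5)["f"] == pytest.approx(2.0)


def test_function_maxima_constant_column_and_ties():
    fm = make_functions({f"p{i}": [7.0] for i in range(8)}, ["f"])
    assert function_maxima(fm, k=5)["f"] == pytest.approx(7.0)
    # values tied with the k-th largest are all included
    fm2 = make_functions(
        {f"p{i}": [v] for i, v in enumerate([9.0, 5.0, 5.0, 5.0, 5.0, 5.0, 1.0])}, ["f"]
    )
    # top-5 cutoff is 5; all six values >= 5 enter the mean
    assert function_maxima(fm2, k=5)["f"] == pytest.approx((9 + 5 * 5) / 6)


def test_threshold_counts_examples():
    fm = make_functions(
        {"p1": [10.0, 0.0], "p2": [10.0, 10.0], "p3": [1.0, 1.0]}, ["f1", "f2"]
    )
    maxima = pd.Series({"f1": 10.0, "f2": 10.0})
    counts = threshold_counts(fm, maxima, t=50)
    assert counts.tolist() == [1, 2, 0]
    # at t=1 every strictly positive value clears its function
    all_pos = make_functions(
        {"p1": [10.0, 3.0], "p2": [10.0, 10.0], "p3": [1.0, 1.0]}, ["f1", "f2"]
    )
    assert threshold_counts(all_pos, maxima, t=1).tolist() == [2, 2, 2]


def test_threshold_counts_nonpositive_maximum_excluded():
    fm = make_functions({"p1": [5.0, -1.0], "p2": [1.0, -2.0]}, ["ok", "neg"])
    with pytest.warns(UserWarning, match="neg"):
        counts = threshold_counts(fm, t=50)
    assert counts.max() <= 1


@given(st.integers(0, 5_000))
def test_counts_non_increasing_in_threshold(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(loc=5.0, size=(7, 4))
    fm = FunctionMatrix(
        pd.DataFrame(vals, index=[f"p{i}" for i in range(7)], columns=list("abcd"))
    )
    counts, _ = count_matrix(fm)
    assert (np.diff(counts, axis=0) <= 0).all()


def test_curve_matches_statsmodels_at_single_threshold(paper_data):
    div = pd.Series(
        np.arange(len(paper_data.functions.plot_ids), dtype=float),
        index=paper_data.functions.plot_ids,
    )
    res = ThresholdAnalysis(paper_data.functions, div, "ix").fit()
    row = res.curve[res.curve["threshold"] == 40].iloc[0]
    counts = threshold_counts(paper_data.functions, t=40).to_numpy(dtype=float)
    fit = sm.OLS(counts, sm.add_constant(div.to_numpy())).fit()
    assert row["slope"] == pytest.approx(fit.params[1], rel=1e-10)
    assert row["se"] == pytest.approx(fit.bse[1], rel=1e-10)
    assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)
    lo, hi = fit.conf_int()[1]
    assert row["ci_low"] == pytest.approx(lo, rel=1e-8)
    assert row["ci_high"] == pytest.approx(hi, rel=1e-8)


def test_perfect_fit_has_zero_ci_width():
    fm, div = linear_count_fixture()
    res = ThresholdAnalysis(fm, div).fit()
    row = res.curve[res.curve["threshold"] == 50].iloc[0]
    assert row["slope"] == 1.0
    assert row["se"] == 0.0
    assert row["ci_low"] == row["ci_high"] == 1.0
    assert row["p"] == 0.0


def test_constant_counts_give_zero_slope_and_p_one():
    # every plot clears every function at every threshold
    fm = make_functions({f"p{i}": [5.0, 5.0] for i in range(5)}, ["f1", "f2"])
    div = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"p{i}" for i in range(5)])
    res = ThresholdAnalysis(fm, div).fit()
    assert (res.curve["slope"] == 0.0).all()
    assert (res.curve["p"] == 1.0).all()
    assert not res.indices.is_defined()


def test_plot_permutation_equivariance(paper_data):
    fm = paper_data.functions
    counts = threshold_counts(fm, t=60)
    perm = np.random.default_rng(1).permutation(len(fm.plot_ids))
    shuffled = FunctionMatrix(fm.data.iloc[perm])
    counts2 = threshold_counts(shuffled, t=60)
    assert counts2.to_numpy().tolist() == counts.to_numpy()[perm].tolist()
    emf, emf2 = averaging_emf(fm), averaging_emf(shuffled)
    assert emf2.to_numpy() == pytest.approx(emf.to_numpy()[perm])


def test_threshold_indices_flat_curve_undefined():
    curve = pd.DataFrame(
        {"threshold": np.arange(1, 100), "slope": 0.0, "p": 1.0}
    )
    ix = threshold_indices(curve, diversity_range=10.0, n_funcs=8)
    assert not ix.is_defined()
    assert ix.T_min is ix.T_max is ix.T_mde is ix.R_mde is ix.P_mde is None


def test_threshold_indices_single_peak():
    t = np.arange(1, 100)
    slope = np.where(np.abs(t - 55) <= 20, 0.5 - 0.01 * np.abs(t - 55), 0.0)
    p = np.where(slope > 0.1, 0.01, 0.5)
    curve = pd.DataFrame({"threshold": t, "slope": slope, "p": p})
    ix = threshold_indices(curve, diversity_range=10.0, n_funcs=8)
    assert ix.T_mde == 55
    assert ix.R_mde == pytest.approx(0.5)
    assert ix.T_min == 35  # first threshold with positive slope and p < 0.05
    assert ix.T_max == 76  # first threshold past the peak where p >= 0.05
    assert ix.P_mde == pytest.approx(100 * 0.5 / (8 / 10.0))


def test_threshold_analysis_input_guards(paper_data):
    div = pd.Series(
        np.ones(len(paper_data.functions.plot_ids)),
        index=paper_data.functions.plot_ids,
    )
    with pytest.raises(ValidationError, match="variance"):
        ThresholdAnalysis(paper_data.functions, div)
    small = make_functions({"p1": [1.0], "p2": [2.0]}, ["f"])
    with pytest.raises(ValidationError, match="3 plots"):
        ThresholdAnalysis(small, pd.Series([1.0, 2.0], index=["p1", "p2"]))
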