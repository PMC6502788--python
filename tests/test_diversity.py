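"""Species richness, convex-hull FRic and trait-derivation formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from emfkit import (
    FRicOptions,
    ValidationError,
    diversity_table,
    fric,
    needle_leaf_area,
    sla,
    species_richness,
    wood_density,
)
from helpers import hull_volume_bruteforce, make_community, make_traits

RAW = FRicOptions(standardize="none")


def test_species_richness_counts_positive_abundances():
    cm = make_community({"p1": [2, 0, 1], "p2": [1, 1, 1]}, ["a", "b", "c"])
    sr = species_richness(cm)
    assert sr.tolist() == [2, 3]


def test_presence_matrix_gives_full_richness():
    cm = make_community({f"p{i}": [1] * 4 for i in range(3)}, list("abcd"))
    assert species_richness(cm).tolist() == [4, 4, 4]


def test_fric_one_trait_is_range():
    cm = make_community({"p1": [1, 1, 1]}, ["a", "b", "c"])
    tt = make_traits({"a": [1.0], "b": [3.0], "c": [7.0]}, ["t1"])
    out = fric(cm, tt, RAW)
    assert out.loc["p1", "FRic"] == pytest.approx(6.0)
    assert bool(out.loc["p1", "FRic_defined"])


def test_fric_triangle_area_and_interior_point():
    species = ["a", "b", "c", "d"]
    tt = make_traits(
        {"a": [0.0, 0.0], "b": [1.0, 0.0], "c": [0.0, 1.0], "d": [0.2, 0.2]},
        ["t1", "t2"],
    )
    cm3 = make_community({"p1": [1, 1, 1, 0]}, species)
    cm4 = make_community({"p1": [1, 1, 1, 1]}, species)
    assert fric(cm3, tt, RAW).loc["p1", "FRic"] == pytest.approx(0.5)
    # a point inside the hull changes nothing
    assert fric(cm4, tt, RAW).loc["p1", "FRic"] == pytest.approx(0.5)


def test_fric_undefined_below_margin_not_zero():
    tt = make_traits({"a": [0.0, 0.0], "b": [1.0, 1.0]}, ["t1", "t2"])
    cm = make_community({"p1": [1, 1]}, ["a", "b"])
    out = fric(cm, tt, RAW)
    assert np.isnan(out.loc["p1", "FRic"])
    assert not bool(out.loc["p1", "FRic_defined"])
    zeroed = fric(cm, tt, FRicOptions(standardize="none", min_species_margin="zero"))
    assert zeroed.loc["p1", "FRic"] == 0.0


def test_fric_degenerate_collinear_flagged():
    tt = make_traits(
        {"a": [0.0, 0.0], "b": [1.0, 1.0], "c": [2.0, 2.0]}, ["t1", "t2"]
    )
    cm = make_community({"p1": [1, 1, 1]}, ["a", "b", "c"])
    out = fric(cm, tt, RAW)
    assert not bool(out.loc["p1", "FRic_defined"])


def test_fric_missing_species_named():
    tt = make_traits({"a": [1.0]}, ["t1"])
    cm = make_community({"p1": [1, 1]}, ["a", "zz"])
    with pytest.raises(ValidationError, match="zz"):
        fric(cm, tt, RAW)


def test_fric_invariant_to_species_order_and_duplicate_points():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(6, 3))
    species = [f"s{i}" for i in range(6)]
    tt = make_traits({s: pts[i].tolist() for i, s in enumerate(species)}, ["x", "y", "z"])
    cm = make_community({"p1": [1] * 6}, species)
    base = fric(cm, tt, RAW).loc["p1", "FRic"]
    # shuffled species order
    order = [3, 1, 5, 0, 4, 2]
    tt2 = make_traits({species[i]: pts[i].tolist() for i in order}, ["x", "y", "z"])
    cm2 = make_community({"p1": [1] * 6}, [species[i] for i in order])
    assert fric(cm2, tt2, RAW).loc["p1", "FRic"] == pytest.approx(base, rel=1e-12)
    # a duplicated trait row adds nothing
    species7 = species + ["dup"]
    tt3 = make_traits(
        {**{s: pts[i].tolist() for i, s in enumerate(species)}, "dup": pts[0].tolist()},
        ["x", "y", "z"],
    )
    cm3 = make_community({"p1": [1] * 7}, species7)
    assert fric(cm3, tt3, RAW).loc["p1", "FRic"] == pytest.approx(base, rel=1e-12)


@given(st.integers(0, 10_000))
def test_fric_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    d = int(rng.integers(1, 4))
    n = int(rng.integers(d + 1, 11))
    pts = rng.normal(size=(n, d))
    species = [f"s{i}" for i in range(n)]
    tt = make_traits({s: pts[i].tolist() for i, s in enumerate(species)},
                     [f"t{j}" for j in range(d)])
    cm = make_community({"p1": [1] * n}, species)
    got = fric(cm, tt, RAW).loc["p1", "FRic"]
    expected = hull_volume_bruteforce(pts)
    assert got == pytest.approx(expected, rel=1e-9)


@given(st.integers(0, 10_000))
def test_fric_monotone_under_species_addition(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 2))
    species = [f"s{i}" for i in range(8)]
    tt = make_traits({s: pts[i].tolist() for i, s in enumerate(species)}, ["x", "y"])
    sub = make_community({"p1": [1] * 6 + [0, 0]}, species)
    full = make_community({"p1": [1] * 8}, species)
    v_sub = fric(sub, tt, RAW).loc["p1", "FRic"]
    v_full = fric(full, tt, RAW).loc["p1", "FRic"]
    assert v_full >= v_sub - 1e-12


def test_fric_ignores_abundance():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(5, 2))
    species = [f"s{i}" for i in range(5)]
    tt = make_traits({s: pts[i].tolist() for i, s in enumerate(species)}, ["x", "y"])
    ones = make_community({"p1": [1] * 5}, species)
    heavy = make_community({"p1": [9, 1, 4, 7, 2]}, species)
    assert fric(ones, tt, RAW).loc["p1", "FRic"] == pytest.approx(
        fric(heavy, tt, RAW).loc["p1", "FRic"]
    )


def test_diversity_table_combines_sr_and_fric(tiny_data):
    div = diversity_table(tiny_data.community, tiny_data.traits)
    assert list(div.columns) == ["SR", "FRic", "FRic_defined"]
    assert (div["SR"] >= 1).all()
    # wherever FRic is defined, at least dims+1 species are present
    dims = len(tiny_data.traits.trait_names)
    assert (div.loc[div["FRic_defined"], "SR"] >= dims + 1).all()


def test_needle_leaf_area_formula():
    assert needle_leaf_area(1.0, 1.0) == pytest.approx(2 * math.pi * math.sqrt(3) / 9)
    assert needle_leaf_area(1.0, 1.0) == pytest.approx(1.2092, abs=1e-4)
    # bilinear in both arguments
    assert needle_leaf_area(2.0, 3.0) == pytest.approx(2 * needle_leaf_area(1.0, 3.0))
    with pytest.raises(ValidationError):
        needle_leaf_area(0.0, 1.0)


def test_sla_and_wood_density_ratios():
    assert sla(100.0, 10.0) == pytest.approx(10.0)
    assert sla(3.0 * 7.0, 3.0 * 2.0) == pytest.approx(sla(7.0, 2.0))
    assert wood_density(0.5, 1.0) == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        sla(100.0, 0.0)
    with pytest.raises(ValidationError):
        wood_density(0.5, -1.0)
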