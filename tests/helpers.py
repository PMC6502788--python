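"""Shared test utilities: table builders and an independent hull-volume oracle."""

from itertools import combinations

import numpy as np
import pandas as pd

from emfkit import CommunityMatrix, FunctionMatrix, TraitTable


def make_community(rows: dict[str, list[float]], species: list[str]) -> CommunityMatrix:
    return CommunityMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=species))


def make_traits(values: dict[str, list[float]], names: list[str]) -> TraitTable:
    return TraitTable(pd.DataFrame.from_dict(values, orient="index", columns=names))


def make_functions(rows: dict[str, list[float]], names: list[str]) -> FunctionMatrix:
    return FunctionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=names))


def hull_volume_bruteforce(points: np.ndarray) -> float:
    """Convex-hull volume by brute-force facet enumeration (d <= 3).

    A subset of d points spans a facet iff every other point lies strictly
    on one side of its hyperplane; the volume is assembled from simplices
    joining each facet to the point centroid.  Assumes points in general
    position (no d+1 points affinely dependent on a facet), which holds
    almost surely for the random continuous points used in tests.
    Independent of any hull library.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    if d == 1:
        return float(pts.max() - pts.min())
    centroid = pts.mean(axis=0)
    volume = 0.0
    if d == 2:
        for i, j in combinations(range(n), 2):
            a, b = pts[i], pts[j]
            normal = np.array([b[1] - a[1], a[0] - b[0]])
            sides = (pts - a) @ normal
            others = np.delete(sides, [i, j])
            if np.all(others > 0) or np.all(others < 0):
                u, v = a - centroid, b - centroid
                volume += abs(u[0] * v[1] - u[1] * v[0]) / 2.0
        return volume
    if d == 3:
        for i, j, k in combinations(range(n), 3):
            a, b, c = pts[i], pts[j], pts[k]
            normal = np.cross(b - a, c - a)
            sides = (pts - a) @ normal
            others = np.delete(sides, [i, j, k])
            if np.all(others > 0) or np.all(others < 0):
                volume += abs(
                    np.linalg.det(
                        np.stack([a - centroid, b - centroid, c - centroid])
                    )
                ) / 6.0
        return volume
    raise ValueError("oracle supports at most 3 dimensions")


def linear_count_fixture():
    """Function matrix whose threshold counts rise 0..8 linearly at t = 50 %.

    Nine plots with diversity 1..9 and eight functions.  Each column's
    top-five mean is exactly 100 by construction (and no column has ties
    at the top-five cutoff), so the t % threshold is simply t.  Values of
    50 meet the threshold up to exactly t = 50; values of 49 only up to
    t = 49; the column maxima (>= 300) always pass.  Plot i (1-based,
    i = 1..7) holds 50s in exactly i columns — spread so that no column
    carries more than four 50s — and the last plot holds every column's
    maximum, so at t = 50 the counts are exactly (0, 1, ..., 8): slope 1
    = F / diversity range, a perfect fit.  Below 50 the first plot gains
    four extra near-misses (49s), flattening the slope to 44/60; above 50
    only the last plot scores (slope 32/60).  The slope curve therefore
    peaks uniquely at t = 50 with P_mde = 100 %.
    """
    # columns f0..f3: top five = {300, 50, 50, 50, 50} -> mean 100
    # columns f4..f7: top five = {301, 50, 50, 50, 49} -> mean 100
    tops = [300.0, 300.0, 300.0, 300.0, 301.0, 301.0, 301.0, 301.0]
    passes = {
        7: [0, 1, 2, 3, 4, 5, 6],
        6: [0, 1, 2, 3, 4, 7],
        5: [0, 1, 5, 6, 7],
        4: [2, 3, 4, 5],
        3: [0, 6, 7],
        2: [1, 2],
        1: [3],
    }
    V = np.zeros((9, 8))
    for i, cols in passes.items():
        V[i, cols] = 50.0
    V[0, 4:] = 49.0
    V[8, :] = tops
    plots = [f"p{i}" for i in range(1, 10)]
    fm = FunctionMatrix(
        pd.DataFrame(V, index=plots, columns=[f"f{j}" for j in range(1, 9)])
    )
    diversity = pd.Series(np.arange(1.0, 10.0), index=plots, name="SR")
    return fm, diversity
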