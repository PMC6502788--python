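"""Biodiversity metrics: species richness and convex-hull functional richness.

Functional richness (FRic) of a plot is the volume of the convex hull
spanned by the trait vectors of the species present.  It is presence-based
(abundances are ignored) and needs at least ``dims + 1`` affinely
independent trait points; plots below that margin are flagged undefined
rather than set to zero, since a zero volume and an undefinable volume mean
different things.

Also included are the field formulas used to derive the traits themselves:
needle leaf area from calliper measurements (the needle cross-section is
treated as one-third of a cylinder surface), specific leaf area, and wood
density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import CommunityMatrix, TraitTable, ValidationError

__all__ = [
    "FRicOptions",
    "species_richness",
    "fric",
    "diversity_table",
    "needle_leaf_area",
    "sla",
    "wood_density",
]

#: Coefficient of the needle leaf-area formula LA = (2*pi*sqrt(3)/9) * d * L.
NEEDLE_COEF = 2.0 * math.pi * math.sqrt(3.0) / 9.0


def needle_leaf_area(d, L):
    """One-sided needle leaf area (mm2) from diameter and length (mm).

    Conifer needles are approximated as cylinders; the projected leaf area
    is ``(2*pi*sqrt(3)/9) * d * L``.
    """
    d = np.asarray(d, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(d <= 0) or np.any(L <= 0):
        raise ValidationError("needle diameter and length must be positive")
    out = NEEDLE_COEF * d * L
    return float(out) if out.ndim == 0 else out


def sla(leaf_area, dry_weight):
    """Specific leaf area (mm2/mg): leaf area divided by leaf dry mass."""
    leaf_area = np.asarray(leaf_area, dtype=float)
    dry_weight = np.asarray(dry_weight, dtype=float)
    if np.any(dry_weight <= 0):
        raise ValidationError("leaf dry weight must be positive")
    out = leaf_area / dry_weight
    return float(out) if out.ndim == 0 else out


def wood_density(dry_weight, volume):
    """Wood density (g/cm3): branch/core dry mass over fresh volume."""
    dry_weight = np.asarray(dry_weight, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValidationError("wood volume must be positive")
    out = dry_weight / volume
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FRicOptions:
    """Options controlling the functional-richness computation.

    standardize
        Per-trait transform applied across the species pool before the
        hull: ``"zscore"`` (default; each trait to mean 0, sd 1),
        ``"range"`` (each trait to [0, 1]) or ``"none"``.
    min_species_margin
        Policy for plots whose distinct trait points cannot span the trait
        space (< dims + 1 points, or degenerate geometry):
        ``"undefined"`` (default; FRic = NaN, flagged) or ``"zero"``.
    reduce_dims
        Optional target dimensionality; the standardized trait matrix is
        projected onto its leading principal components.  Escape hatch for
        trait sets too large for the species counts at hand.
    """

    standardize: str = "zscore"
    min_species_margin: str = "undefined"
    reduce_dims: int | None = None

    def __post_init__(self):
        if self.standardize not in ("zscore", "range", "none"):
            raise ValueError("standardize must be 'zscore', 'range' or 'none'")
        if self.min_species_margin not in ("undefined", "zero"):
            raise ValueError("min_species_margin must be 'undefined' or 'zero'")


def species_richness(community: CommunityMatrix) -> pd.Series:
    """Number of species with abundance > 0 per plot."""
    sr = (community.data.to_numpy() > 0).sum(axis=1)
    return pd.Series(sr, index=community.data.index, name="SR")


def _standardized_points(
    traits: TraitTable, species: list[str], options: FRicOptions
) -> np.ndarray:
    X = traits.data.loc[species].to_numpy(dtype=float)
    if options.standardize == "zscore":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [t for t, s in zip(traits.trait_names, sd) if s == 0]
            raise ValidationError(
                f"trait(s) constant across the species pool: {', '.join(bad)}"
            )
        X = (X - X.mean(axis=0)) / sd
    elif options.standardize == "range":
        span = X.max(axis=0) - X.min(axis=0)
        if np.any(span == 0):
            bad = [t for t, s in zip(traits.trait_names, span) if s == 0]
            raise ValidationError(
                f"trait(s) constant across the species pool: {', '.join(bad)}"
            )
        X = (X - X.min(axis=0)) / span
    if options.reduce_dims is not None:
        k = int(options.reduce_dims)
        if not 1 <= k <= X.shape[1]:
            raise ValidationError("reduce_dims must be in [1, n_traits]")
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        X = Xc @ vt[:k].T
    return X


def hull_volume(points: np.ndarray) -> float | None:
    """Convex-hull volume of a point set, or None if the hull is undefined.

    Exact duplicates are removed first (hull libraries reject degenerate
    input).  In one dimension the hull volume is the range.  Point sets
    with fewer than dims + 1 distinct points, or affinely dependent ones,
    have no full-dimensional hull and return None.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n, d = pts.shape
    if d == 1:
        if n < 2:
            return None
        return float(pts.max() - pts.min())
    if n < d + 1:
        return None
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return None


def fric(
    community: CommunityMatrix,
    traits: TraitTable,
    options: FRicOptions | None = None,
) -> pd.DataFrame:
    """Per-plot functional richness.

    Returns a DataFrame indexed by plot id with columns ``FRic`` (hull
    volume in standardized trait units; NaN where undefined) and
    ``FRic_defined`` (bool).

    Every species present in the community must appear in the trait table.
    """
    options = options or FRicOptions()
    pool = community.species_ids
    missing = [s for s in pool if s not in traits.data.index]
    if missing:
        raise ValidationError(
            f"species missing from trait table: {', '.join(missing)}"
        )
    X = _standardized_points(traits, pool, options)
    presence = community.presence()
    vols = np.full(len(community.plot_ids), np.nan)
    defined = np.zeros(len(community.plot_ids), dtype=bool)
    for i, row in enumerate(presence):
        v = hull_volume(X[row])
        if v is not None:
            vols[i] = v
            defined[i] = True
        elif options.min_species_margin == "zero":
            vols[i] = 0.0
    return pd.DataFrame(
        {"FRic": vols, "FRic_defined": defined},
        index=community.data.index,
    )


def diversity_table(
    community: CommunityMatrix,
    traits: TraitTable,
    options: FRicOptions | None = None,
) -> pd.DataFrame:
    """SR and FRic side by side: columns SR, FRic, FRic_defined."""
    sr = species_richness(community)
    fr = fric(community, traits, options)
    out = fr.copy()
    out.insert(0, "SR", sr)
    return out
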