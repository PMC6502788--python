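"""Typed tables and delimited-text I/O.

The pipeline works on four aligned tables: a plot x species abundance
matrix, a species x trait table, a plot x ecosystem-function matrix and an
optional plot x environment table.  Each is a thin immutable wrapper around
a :class:`pandas.DataFrame` whose structural invariants are checked at
construction time, so that downstream code can assume clean input.

Identifiers are opaque strings and matched exactly (case-sensitive); the
canonical plot order for a joined analysis is the order of the community
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CommunityMatrix",
    "TraitTable",
    "FunctionMatrix",
    "EnvironmentTable",
    "AlignedTables",
    "read_matrix",
    "write_matrix",
    "align_tables",
    "ENV_COLUMNS",
    "POSITIVE_TRAITS",
]

#: Required columns of an environment table (mean annual temperature in
#: deg C, mean annual precipitation in mm, soil pH).
ENV_COLUMNS = ("MAT", "MAP", "soil_pH")

#: Trait columns that must be strictly positive when present
#: (specific leaf area mm2/mg, wood density g/cm3, leaf area mm2).
POSITIVE_TRAITS = ("SLA", "WD", "LA")


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


def _as_str_index(idx: pd.Index) -> pd.Index:
    return pd.Index([str(v) for v in idx], name=idx.name)


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()].astype(str)))
        raise ValidationError(f"duplicate {what} ids: {', '.join(dupes)}")


def _check_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Coerce to float, raising on the first non-numeric or missing cell."""
    out = {}
    for col in df.columns:
        series = df[col]
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna() & series.notna()
        if bad.any():
            row = series.index[bad][0]
            raise ValidationError(
                f"{what}: non-numeric value {series[row]!r} at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = series.index[coerced.isna()][0]
            raise ValidationError(
                f"{what}: missing value at row {row!r}, column {col!r} "
                "(pass missing='drop' to drop incomplete rows)"
            )
        if np.isinf(coerced.to_numpy(dtype=float)).any():
            raise ValidationError(f"{what}: non-finite value in column {col!r}")
        out[col] = coerced.astype(float)
    return pd.DataFrame(out, index=df.index)


def _prepare(df: pd.DataFrame, what: str) -> pd.DataFrame:
    df = df.copy()
    df.index = _as_str_index(df.index)
    df.columns = _as_str_index(df.columns)
    _check_unique(df.index, f"{what} row")
    _check_unique(df.columns, f"{what} column")
    return _check_numeric(df, what)


@dataclass(frozen=True)
class CommunityMatrix:
    """Plot x species abundance matrix (stem counts or presence)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = _prepare(self.data, "community")
        vals = df.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"community: negative abundance at plot {df.index[r]!r}, "
                f"species {df.columns[c]!r}"
            )
        empty = df.index[(vals > 0).sum(axis=1) == 0]
        if len(empty):
            raise ValidationError(
                f"community: plots with no species present: {', '.join(empty)}"
            )
        object.__setattr__(self, "data", df)

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    def presence(self) -> np.ndarray:
        """Boolean plots x species presence matrix."""
        return self.data.to_numpy() > 0


@dataclass(frozen=True)
class TraitTable:
    """Species x trait table; SLA/WD/LA columns must be strictly positive."""

    data: pd.DataFrame

    def __post_init__(self):
        df = _prepare(self.data, "traits")
        for col in df.columns:
            if col in POSITIVE_TRAITS and (df[col].to_numpy() <= 0).any():
                row = df.index[df[col].to_numpy() <= 0][0]
                raise ValidationError(
                    f"traits: non-positive {col} for species {row!r}"
                )
        object.__setattr__(self, "data", df)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class FunctionMatrix:
    """Plot x ecosystem-function matrix; complete (no missing cells)."""

    data: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "data", _prepare(self.data, "functions"))

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def function_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class EnvironmentTable:
    """Plot x abiotic-covariate table with MAT, MAP and soil_pH columns."""

    data: pd.DataFrame

    def __post_init__(self):
        df = _prepare(self.data, "environment")
        missing = [c for c in ENV_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(
                f"environment: missing required column(s): {', '.join(missing)}"
            )
        object.__setattr__(self, "data", df)

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)


_KIND_TO_TYPE = {
    "community": CommunityMatrix,
    "traits": TraitTable,
    "functions": FunctionMatrix,
    "environment": EnvironmentTable,
}


def read_matrix(path, kind: str, missing: str = "error"):
    """Read a delimited-text table and validate it as the given kind.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, '.' decimal) with a header row; the
        first column holds row identifiers.
    kind
        One of ``community``, ``traits``, ``functions``, ``environment``.
    missing
        ``"error"`` (default) rejects tables with empty cells;
        ``"drop"`` drops incomplete rows with a warning.  Imputation is
        deliberately not offered.
    """
    if kind not in _KIND_TO_TYPE:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_KIND_TO_TYPE)}")
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if missing == "drop":
        incomplete = df.index[df.isna().any(axis=1)]
        if len(incomplete):
            warnings.warn(
                f"{path.name}: dropping {len(incomplete)} row(s) with missing "
                f"values: {', '.join(str(i) for i in incomplete)}"
            )
            df = df.dropna(axis=0)
    elif missing != "error":
        raise ValueError("missing policy must be 'error' or 'drop'")
    return _KIND_TO_TYPE[kind](df)


def write_matrix(table, path) -> None:
    """Write a typed table back to CSV (round-trips exactly)."""
    table.data.to_csv(path, float_format="%.17g")


@dataclass(frozen=True)
class AlignedTables:
    """Tables restricted to a common, canonically ordered set of plots."""

    community: CommunityMatrix
    functions: FunctionMatrix
    environment: EnvironmentTable | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def plot_ids(self) -> list[str]:
        return self.community.plot_ids


def align_tables(
    community: CommunityMatrix,
    functions: FunctionMatrix,
    environment: EnvironmentTable | None = None,
) -> AlignedTables:
    """Restrict tables to the intersection of their plot ids.

    The canonical order is the community table's order.  Plots missing
    from any table are dropped and reported in ``AlignedTables.dropped``.
    """
    keep = set(functions.plot_ids)
    if environment is not None:
        keep &= set(environment.plot_ids)
    common = [p for p in community.plot_ids if p in keep]
    if not common:
        raise ValidationError("tables share no plot ids")
    dropped = {
        "community": [p for p in community.plot_ids if p not in common],
        "functions": [p for p in functions.plot_ids if p not in common],
    }
    env = None
    if environment is not None:
        dropped["environment"] = [p for p in environment.plot_ids if p not in common]
        env = EnvironmentTable(environment.data.loc[common])
    return AlignedTables(
        community=CommunityMatrix(community.data.loc[common]),
        functions=FunctionMatrix(functions.data.loc[common]),
        environment=env,
        dropped=dropped,
    )
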