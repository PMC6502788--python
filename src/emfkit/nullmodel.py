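"""Richness-controlled null models and standardized effect sizes (SES).

The null model shuffles whole trait rows (multivariate trait vectors)
across species labels while leaving community composition untouched.
Every plot therefore keeps its species richness, and every trait keeps its
multiset of values; only the mapping of trait syndromes to species — and
hence any trait-mediated diversity-function association — is destroyed.

For a statistic s computed on (community, traits, functions),

    SES = (s_observed - mean(s_null)) / sd(s_null)

over an ensemble of trait shuffles.  Positive SES indicates divergence
from random; near zero, consistency with it.

``SESAnalysis`` builds the full metric x target SES table (community-mean
SLA/WD/LA and FRic against each ecosystem function and the averaging EMF
index), sharing one null ensemble across all cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import FRicOptions, _standardized_points, hull_volume
from .io import CommunityMatrix, FunctionMatrix, TraitTable, ValidationError
from .multifun import averaging_emf

__all__ = ["SESResult", "shuffle_traits", "ses", "SESAnalysis", "SESResults"]

#: Default size of the null ensemble.
DEFAULT_N_NULL = 999


def shuffle_traits(traits: TraitTable, rng) -> TraitTable:
    """Permute whole trait rows across species labels.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`.  Row
    vectors travel together, preserving trait covariance; each trait's
    multiset of values is conserved exactly.
    """
    rng = np.random.default_rng(rng)
    X = traits.data.to_numpy()
    perm = rng.permutation(len(X))
    return TraitTable(
        pd.DataFrame(X[perm], index=traits.data.index, columns=traits.data.columns)
    )


@dataclass(frozen=True)
class SESResult:
    """One standardized effect size with its null-ensemble moments."""

    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined (null sd = 0)
    n_null: int
    seed: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ses)


def ses(
    statistic,
    community: CommunityMatrix,
    traits: TraitTable,
    functions: FunctionMatrix,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    name: str = "statistic",
) -> SESResult:
    """SES of an arbitrary statistic under the trait-shuffling null.

    ``statistic`` is a deterministic callable
    ``(community, traits, functions) -> float``.  The observed value is
    computed on the real traits; the null ensemble re-evaluates it on
    ``n_null`` independent row shuffles drawn from ``seed``.  A null
    ensemble with zero spread yields an undefined (NaN) SES rather than a
    division by zero.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    observed = float(statistic(community, traits, functions))
    rng = np.random.default_rng(seed)
    nulls = np.array(
        [
            float(statistic(community, shuffle_traits(traits, rng), functions))
            for _ in range(n_null)
        ]
    )
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    value = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    return SESResult(name, observed, null_mean, null_sd, value, n_null, seed)


def _pearson(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``a`` with every column of ``B``."""
    a = a - a.mean()
    B = B - B.mean(axis=0)
    denom = np.sqrt((a @ a) * (B**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a @ B) / denom


class SESAnalysis:
    """SES table of trait/diversity metrics against functions and EMF.

    Rows are the per-plot metrics: the community mean of each trait over
    the species present (presence-based, matching FRic's presence basis)
    and FRic itself.  Columns are each ecosystem function plus the
    averaging EMF index.  The statistic standardized in every cell is the
    Pearson correlation between metric and target across plots.
    """

    def __init__(
        self,
        community: CommunityMatrix,
        traits: TraitTable,
        functions: FunctionMatrix,
        fric_options: FRicOptions | None = None,
    ):
        if list(community.plot_ids) != list(functions.plot_ids):
            raise ValidationError(
                "community and function matrices must be aligned (same plots, "
                "same order); use align_tables first"
            )
        missing = [s for s in community.species_ids if s not in traits.data.index]
        if missing:
            raise ValidationError(
                f"species missing from trait table: {', '.join(missing)}"
            )
        self.community = community
        self.traits = traits
        self.functions = functions
        self.fric_options = fric_options or FRicOptions()

    def _metric_matrix(self, X_raw: np.ndarray, X_std: np.ndarray) -> np.ndarray:
        """Plots x (traits + FRic) metric matrix for one trait assignment."""
        P = self.community.presence().astype(float)
        sr = P.sum(axis=1)
        means = (P @ X_raw) / sr[:, None]
        fricv = np.array(
            [
                v if (v := hull_volume(X_std[row.astype(bool)])) is not None else np.nan
                for row in P
            ]
        )
        return np.column_stack([means, fricv])

    def fit(self, n_null: int = DEFAULT_N_NULL, seed: int = 0) -> "SESResults":
        """Compute observed, null-ensemble and SES values for every cell."""
        if n_null < 2:
            raise ValidationError("n_null must be >= 2")
        pool = self.community.species_ids
        X_raw = self.traits.data.loc[pool].to_numpy(dtype=float)
        X_std = _standardized_points(self.traits, pool, self.fric_options)

        targets = self.functions.data.copy()
        targets["EMF"] = averaging_emf(self.functions)
        Y = targets.to_numpy(dtype=float)

        obs = self._corr_table(self._metric_matrix(X_raw, X_std), Y)
        rng = np.random.default_rng(seed)
        null = np.empty((n_null,) + obs.shape)
        for k in range(n_null):
            perm = rng.permutation(len(X_raw))
            null[k] = self._corr_table(
                self._metric_matrix(X_raw[perm], X_std[perm]), Y
            )
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ses_vals = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)

        rows = list(self.traits.trait_names) + ["FRic"]
        cols = list(targets.columns)
        mk = lambda a: pd.DataFrame(a, index=rows, columns=cols)
        return SESResults(
            observed=mk(obs),
            null_mean=mk(null_mean),
            null_sd=mk(null_sd),
            ses=mk(ses_vals),
            n_null=n_null,
            seed=seed,
            statistic="pearson_r",
        )

    def _corr_table(self, metrics: np.ndarray, Y: np.ndarray) -> np.ndarray:
        out = np.empty((metrics.shape[1], Y.shape[1]))
        for j in range(metrics.shape[1]):
            m = metrics[:, j]
            ok = np.isfinite(m)
            out[j] = _pearson(m[ok], Y[ok])
        return out


@dataclass(frozen=True)
class SESResults:
    """SES table shaped metrics x (functions + EMF), with ensemble moments."""

    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    ses: pd.DataFrame
    n_null: int
    seed: int
    statistic: str

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: metric, target, observed, null moments, SES, 95% CI."""
        records = []
        for metric in self.ses.index:
            for target in self.ses.columns:
                s = self.ses.loc[metric, target]
                records.append(
                    {
                        "metric": metric,
                        "target": target,
                        "observed": self.observed.loc[metric, target],
                        "null_mean": self.null_mean.loc[metric, target],
                        "null_sd": self.null_sd.loc[metric, target],
                        "ses": s,
                        "ses_ci_low": s - 1.96,
                        "ses_ci_high": s + 1.96,
                        "n_null": self.n_null,
                    }
                )
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        lines = [
            f"Standardized effect sizes ({self.statistic}; "
            f"{self.n_null} trait shuffles, seed {self.seed})",
            self.ses.round(4).to_string(),
        ]
        return "\n".join(lines)
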