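"""Synthetic plot-community generator.

Emulates the structure of a subtropical secondary-forest survey: a set of
fixed-area plots spanning a richness gradient, a species pool with three
correlated functional traits (SLA, WD, LA), eight plot-level ecosystem
functions, and plot-level climate/soil covariates.  One species plays the
role of the monodominant canopy pine, holding a configurable fraction of
every plot's stems.

Functions are generated directly on the diversity metrics,

    f_p = base_f + effect_sr[f] * SR_p + effect_fric[f] * FRic_p
          + env terms + N(0, noise_sd[f]),

so the planted effects are exactly the quantities the analysis chain is
asked to recover; the generator makes no attempt at mechanistic forest
biogeochemistry.  All randomness flows from a single seed through one
named generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import FRicOptions, diversity_table
from .io import (
    CommunityMatrix,
    EnvironmentTable,
    FunctionMatrix,
    TraitTable,
    ValidationError,
)

__all__ = ["SimConfig", "SimulatedDataset", "gen_dataset", "gen_fixture", "FIXTURES"]

#: Ecosystem-function labels: plant N and P, soil hydrolysable N, soil
#: available P, soil total N/P/C, woody plant biomass.
FUNCTION_NAMES = ("PN", "PP", "SHN", "SAP", "STN", "STP", "STC", "WPB")
TRAIT_NAMES = ("SLA", "WD", "LA")

# log-scale trait distribution for the pool: medians ~10 mm2/mg (SLA),
# 0.55 g/cm3 (WD), 1500 mm2 (LA); modest spread and an acquisitive-
# conservative axis (SLA up, WD down).
_LOG_TRAIT_MEAN = np.array([np.log(10.0), np.log(0.55), np.log(1500.0)])
_LOG_TRAIT_SD = np.array([0.30, 0.15, 0.60])
_LOG_TRAIT_CORR = np.array(
    [
        [1.0, -0.4, 0.3],
        [-0.4, 1.0, -0.1],
        [0.3, -0.1, 1.0],
    ]
)

# realistic plot-level means for the eight functions (plant N/P mg/g, soil
# N pools mg/kg or g/kg, biomass t/ha); absolute level is irrelevant to the
# z-scored analyses but keeps printed tables plausible.
_FUNCTION_BASE = np.array([15.0, 1.2, 120.0, 10.0, 1.5, 0.6, 25.0, 150.0])

# climate envelope of the study region (MAT deg C, MAP mm) and a typical
# subtropical forest soil pH range.
_MAT_RANGE = (15.7, 18.2)
_MAP_RANGE = (954.0, 1202.0)
_PH_RANGE = (5.5, 7.0)


def _default_effect_fric(n_functions: int) -> np.ndarray:
    """Moderate diversity effect on the nutrient-related functions only
    (plant P, soil available P, soil total N), mirroring the study system
    where biomass is dominated by one species and insensitive to richness."""
    eff = np.zeros(n_functions)
    for name, value in (("PP", 0.3), ("SAP", 0.3), ("STN", 0.3)):
        try:
            eff[FUNCTION_NAMES.index(name)] = value
        except (ValueError, IndexError):
            pass
    return eff


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic dataset.

    Defaults reproduce the shape of the motivating survey: 58 plots,
    a 54-species woody pool, 3 traits, 8 functions, a richness gradient,
    and a single dominant holding 90 % of the stems.
    """

    n_plots: int = 58
    n_species_pool: int = 54
    n_traits: int = 3
    n_functions: int = 8
    richness_range: tuple[int, int] = (4, 18)
    trait_covariance: np.ndarray | None = None  # log-scale, traits x traits
    effect_fric: np.ndarray | float | None = None  # per-function, functions per FRic unit
    effect_sr: np.ndarray | float = 0.0  # per-function, functions per species
    env_effects: np.ndarray | float = 0.0  # functions x (MAT, MAP, soil_pH)
    noise_sd: np.ndarray | float = 1.0
    dominance: float = 0.9  # share of stems held by species 1
    stems_per_plot: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 3:
            raise ValidationError("n_plots must be >= 3")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.n_species_pool):
            raise ValidationError(
                f"richness_range {self.richness_range} must lie within "
                f"[1, {self.n_species_pool}]"
            )
        if not 0.0 <= self.dominance < 1.0:
            raise ValidationError("dominance must be in [0, 1)")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValidationError("noise_sd must be > 0")

    def _vec(self, value, default=None) -> np.ndarray:
        if value is None:
            value = default
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_functions, float(arr))
        if arr.shape != (self.n_functions,):
            raise ValidationError(f"expected {self.n_functions} per-function values")
        return arr

    @property
    def effect_fric_vector(self) -> np.ndarray:
        return self._vec(self.effect_fric, _default_effect_fric(self.n_functions))

    @property
    def effect_sr_vector(self) -> np.ndarray:
        return self._vec(self.effect_sr)

    @property
    def noise_sd_vector(self) -> np.ndarray:
        return self._vec(self.noise_sd)

    @property
    def env_effects_matrix(self) -> np.ndarray:
        arr = np.asarray(self.env_effects, dtype=float)
        if arr.ndim == 0:
            arr = np.full((self.n_functions, 3), float(arr))
        if arr.shape != (self.n_functions, 3):
            raise ValidationError("env_effects must be n_functions x 3")
        return arr

    @property
    def trait_cov(self) -> np.ndarray:
        if self.trait_covariance is not None:
            cov = np.asarray(self.trait_covariance, dtype=float)
            if cov.shape != (self.n_traits, self.n_traits):
                raise ValidationError("trait_covariance must be n_traits x n_traits")
            return cov
        t = self.n_traits
        sd = np.resize(_LOG_TRAIT_SD, t)
        corr = np.eye(t)
        k = min(t, 3)
        corr[:k, :k] = _LOG_TRAIT_CORR[:k, :k]
        return corr * np.outer(sd, sd)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "richness_range" in d:
            d["richness_range"] = tuple(d["richness_range"])
        return cls(**d)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset plus the planted ground truth."""

    community: CommunityMatrix
    traits: TraitTable
    functions: FunctionMatrix
    environment: EnvironmentTable
    truth: dict


def _function_names(n: int) -> list[str]:
    names = list(FUNCTION_NAMES[:n])
    names += [f"F{i + 1}" for i in range(len(names), n)]
    return names


def _trait_names(n: int) -> list[str]:
    names = list(TRAIT_NAMES[:n])
    names += [f"trait{i + 1}" for i in range(len(names), n)]
    return names


def gen_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Draw one synthetic dataset from the configured study design.

    ``seed`` overrides ``config.seed`` when given.  Returns the four
    typed tables plus a truth record holding every planted parameter and
    the per-plot SR/FRic actually realised.
    """
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)

    species = [f"sp{i + 1:02d}" for i in range(config.n_species_pool)]
    plots = [f"p{i + 1:02d}" for i in range(config.n_plots)]

    # species pool traits: correlated lognormal so SLA/WD/LA stay positive
    tnames = _trait_names(config.n_traits)
    log_mean = np.resize(_LOG_TRAIT_MEAN, config.n_traits)
    log_traits = rng.multivariate_normal(log_mean, config.trait_cov, size=config.n_species_pool)
    traits = TraitTable(pd.DataFrame(np.exp(log_traits), index=species, columns=tnames))

    # community assembly: uniform richness gradient, geometric-series
    # rank-abundance, species 1 as the fixed dominant
    lo, hi = config.richness_range
    abund = np.zeros((config.n_plots, config.n_species_pool), dtype=int)
    n_stems = config.stems_per_plot
    for i in range(config.n_plots):
        sr = int(rng.integers(lo, hi + 1))
        if config.dominance > 0:
            # species 1 is the fixed dominant; subordinates share the rest
            rest = sorted((1 + rng.permutation(config.n_species_pool - 1)[: sr - 1]).tolist())
            # subordinate stem total: the nominal share of the plot, but at
            # least one stem per sampled species; the dominant's count is
            # scaled so its share of the plot stays at `dominance`
            n_other = max(len(rest), round((1.0 - config.dominance) * n_stems))
            n_dom = round(config.dominance / (1.0 - config.dominance) * n_other)
            abund[i, 0] = max(1, n_dom) if sr > 1 else n_stems
            remaining = n_other
        else:
            rest = sorted(rng.permutation(config.n_species_pool)[:sr].tolist())
            remaining = n_stems
        if rest:
            abund[i, rest] = 1  # every sampled species gets at least one stem
            remaining -= len(rest)
            if remaining > 0:
                w = 0.5 ** np.arange(len(rest))
                extra = rng.multinomial(remaining, w / w.sum())
                abund[i, rest] += extra
    community = CommunityMatrix(pd.DataFrame(abund, index=plots, columns=species))

    # plot covariates
    mat = rng.uniform(*_MAT_RANGE, size=config.n_plots)
    mapp = rng.uniform(*_MAP_RANGE, size=config.n_plots)
    ph = rng.uniform(*_PH_RANGE, size=config.n_plots)
    environment = EnvironmentTable(
        pd.DataFrame({"MAT": mat, "MAP": mapp, "soil_pH": ph}, index=plots)
    )

    # realised diversity; undefined FRic (possible when richness_range
    # dips below n_traits + 1) contributes 0 to the linear predictor
    div = diversity_table(community, traits, FRicOptions())
    sr_vec = div["SR"].to_numpy(dtype=float)
    fric_vec = np.nan_to_num(div["FRic"].to_numpy(dtype=float), nan=0.0)

    fnames = _function_names(config.n_functions)
    base = np.resize(_FUNCTION_BASE, config.n_functions)
    env_mat = np.column_stack([mat, mapp, ph])
    env_centered = env_mat - env_mat.mean(axis=0)
    signal = (
        base[None, :]
        + np.outer(sr_vec, config.effect_sr_vector)
        + np.outer(fric_vec, config.effect_fric_vector)
        + env_centered @ config.env_effects_matrix.T
    )
    noise = rng.normal(0.0, config.noise_sd_vector, size=(config.n_plots, config.n_functions))
    functions = FunctionMatrix(pd.DataFrame(signal + noise, index=plots, columns=fnames))

    truth = {
        "config": json.loads(config.to_json()),
        "sr": {p: int(v) for p, v in div["SR"].items()},
        "fric": {p: (float(v) if d else None) for p, v, d in
                 zip(plots, div["FRic"], div["FRic_defined"])},
        "effect_fric": config.effect_fric_vector.tolist(),
        "effect_sr": config.effect_sr_vector.tolist(),
        "env_effects": config.env_effects_matrix.tolist(),
        "noise_sd": config.noise_sd_vector.tolist(),
    }
    return SimulatedDataset(community, traits, functions, environment, truth)


#: Canned fixture configurations.
FIXTURES = {
    # 4 plots x 5 species smoke-test dataset
    "tiny": SimConfig(
        n_plots=4, n_species_pool=5, richness_range=(4, 5), seed=101
    ),
    # the survey's shape with the default moderate diversity effects
    "paper_shape": SimConfig(seed=202),
    # no planted diversity effect at all: drives the SES calibration suite
    "null": SimConfig(effect_fric=0.0, effect_sr=0.0, seed=303),
    # strong FRic effect on every function, zero direct SR effect
    "strong_fric": SimConfig(effect_fric=0.5, effect_sr=0.0, seed=404),
}


def gen_fixture(name: str, seed: int | None = None) -> SimulatedDataset:
    """Generate one of the named canned datasets (tiny, paper_shape, null,
    strong_fric), optionally overriding the canned seed."""
    if name not in FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    return gen_dataset(FIXTURES[name], seed=seed)
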