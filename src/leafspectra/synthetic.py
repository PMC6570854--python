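"""Synthetic paired-plot invasion survey generator.

Emulates the field design behind the analysis — 22 sampling locations,
each with 3 sites (66 sites = 66 invader populations); 51 sites carry
five pairs of invaded/uninvaded 1 × 1 m plots and 15 sites carry three
pairs, giving 300 plot pairs — together with a *known* linear
trait–environment effect structure, so every downstream stage (indices,
regressions, multimodel inference) can be validated against ground truth
without any external data.

Generation proceeds in three stages, each on its own child random
stream of a single integer seed:

1. uninvaded-plot values of the ten measured drivers (climate, diversity,
   soil) are drawn from a multivariate Gaussian with configurable means,
   SDs and correlation, then clamped to admissible ranges;
2. invaded-plot values of the six paired variables are the uninvaded
   values plus a per-variable invasion shift and pair-level noise, and
   the six Δ (relative change) variables are computed from the pairs;
3. each leaf trait is its baseline plus the standardized 16-column driver
   matrix times the trait's effect column, plus Gaussian noise, with
   nonpositive draws resampled (traits are physically positive).  Leaf
   C:N is derived as leaf C / leaf N so the table is internally
   consistent; its effect-matrix column is therefore ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import TRAIT_COLUMNS, relative_change

#: The ten drivers measured directly (uninvaded-plot / station values).
BASE_DRIVERS = (
    "mat", "map", "richness", "evenness",
    "ph", "texture", "nutrients", "bacteria", "fungi", "fb_ratio",
)
#: The six variables measured in both members of a plot pair; their
#: relative changes form the invader–community interaction drivers.
PAIRED_VARIABLES = ("richness", "ph", "nutrients", "bacteria", "fungi", "fb_ratio")
DELTA_DRIVERS = tuple(f"d_{v}" for v in PAIRED_VARIABLES)
#: Full 16-driver column order of an environment table.
DRIVER_COLUMNS = BASE_DRIVERS + DELTA_DRIVERS

KEY_COLUMNS = ("unit_id", "location", "site", "pair")


class DesignError(ValueError):
    """Raised when survey-design counts are mutually inconsistent."""


class ModelError(ValueError):
    """Raised when an effect model is invalid (e.g. non-PSD correlation)."""


@dataclass(frozen=True)
class SurveyDesign:
    """Geometry of the paired-plot survey.

    Defaults reproduce the study layout: 22 locations × 3 sites = 66
    sites, 51 of which hold five plot pairs and 15 three pairs
    (5×51 + 3×15 = 300 pairs).  Five-pair status is assigned to the
    first ``n_five_pair_sites`` sites in location/site order.
    """

    n_locations: int = 22
    sites_per_location: int = 3
    n_five_pair_sites: int = 51
    n_three_pair_sites: int = 15
    pairs_per_site_major: int = 5
    pairs_per_site_minor: int = 3

    def __post_init__(self) -> None:
        counts = (
            self.n_locations, self.sites_per_location,
            self.n_five_pair_sites + self.n_three_pair_sites,
            self.pairs_per_site_major, self.pairs_per_site_minor,
        )
        if any(c <= 0 for c in counts) or min(self.n_five_pair_sites, self.n_three_pair_sites) < 0:
            raise DesignError("all survey counts must be positive")
        if self.n_locations * self.sites_per_location != self.n_sites:
            raise DesignError(
                f"{self.n_locations} locations x {self.sites_per_location} sites != "
                f"{self.n_five_pair_sites} five-pair + {self.n_three_pair_sites} three-pair sites"
            )

    @property
    def n_sites(self) -> int:
        return self.n_five_pair_sites + self.n_three_pair_sites

    @property
    def n_pairs(self) -> int:
        return (
            self.n_five_pair_sites * self.pairs_per_site_major
            + self.n_three_pair_sites * self.pairs_per_site_minor
        )


def generate_design(design: SurveyDesign | None = None) -> pd.DataFrame:
    """Enumerate plot pairs: one row per pair with location/site/pair labels.

    Under the default design this yields 300 rows over 66 distinct sites.
    """
    design = design or SurveyDesign()
    records = []
    site_index = 0
    for loc in range(1, design.n_locations + 1):
        for s in range(1, design.sites_per_location + 1):
            n_pairs = (
                design.pairs_per_site_major
                if site_index < design.n_five_pair_sites
                else design.pairs_per_site_minor
            )
            site_id = f"L{loc:02d}S{s}"
            for p in range(1, n_pairs + 1):
                records.append(
                    {
                        "unit_id": f"{site_id}P{p}",
                        "location": f"L{loc:02d}",
                        "site": site_id,
                        "pair": p,
                    }
                )
            site_index += 1
    return pd.DataFrame.from_records(records)


def _series(values: dict[str, float], index: tuple[str, ...], what: str) -> pd.Series:
    missing = set(index) - set(values)
    if missing:
        raise ModelError(f"{what} missing entries for {sorted(missing)}")
    return pd.Series({k: float(values[k]) for k in index}, index=list(index))


def default_driver_means() -> dict[str, float]:
    """Typical values for a subtropical lowland invasion survey."""
    return {
        "mat": 16.5,      # deg C
        "map": 1400.0,    # mm yr^-1
        "richness": 8.0,  # native species per m^2 plot
        "evenness": 0.6,  # Pielou index
        "ph": 6.0,
        "texture": 40.0,  # sand fraction, %
        "nutrients": 50.0,  # available P + NH4-N + NO3-N, mg kg^-1
        "bacteria": 60.0,   # bacterial PLFA, nmol g^-1
        "fungi": 12.0,      # fungal PLFA, nmol g^-1
        "fb_ratio": 0.20,
    }


def default_driver_sds() -> dict[str, float]:
    return {
        "mat": 1.5, "map": 250.0, "richness": 3.0, "evenness": 0.12,
        "ph": 0.7, "texture": 12.0, "nutrients": 15.0, "bacteria": 18.0,
        "fungi": 4.0, "fb_ratio": 0.05,
    }


#: Admissible ranges the Gaussian draws are clamped to.
DRIVER_BOUNDS: dict[str, tuple[float, float]] = {
    "richness": (0.0, np.inf),
    "ph": (0.0, 14.0),
    "evenness": (0.0, 1.0),
    "texture": (0.0, 100.0),
    "nutrients": (0.0, np.inf),
    "bacteria": (0.0, np.inf),
    "fungi": (0.0, np.inf),
    "fb_ratio": (0.0, np.inf),
}


def default_effect_matrix() -> pd.DataFrame:
    """Sparse ground-truth slopes (trait units per SD of driver).

    A plausible structure for a fast-growing clonal invader: water and
    nutrient supply push leaves toward the acquisitive end (larger,
    thinner, N-rich), while warm dry conditions favour dense,
    carbon-rich tissue.  The ``leaf_cn`` column stays zero because C:N is
    derived from leaf C and leaf N.
    """
    eff = pd.DataFrame(0.0, index=list(DRIVER_COLUMNS), columns=list(TRAIT_COLUMNS))
    eff.loc["mat", "ldmc"] = 12.0
    eff.loc["evenness", "ldmc"] = -10.0
    eff.loc["nutrients", "ldmc"] = -8.0
    eff.loc["d_nutrients", "ldmc"] = -6.0
    eff.loc["richness", "leaf_area"] = 3.0
    eff.loc["nutrients", "leaf_area"] = 2.5
    eff.loc["map", "leaf_area"] = 2.0
    eff.loc["nutrients", "sla"] = 10.0
    eff.loc["d_nutrients", "sla"] = 6.0
    eff.loc["map", "sla"] = 5.0
    eff.loc["ph", "chlorophyll"] = -2.0
    eff.loc["d_bacteria", "chlorophyll"] = 1.5
    eff.loc["map", "leaf_n"] = 0.12
    eff.loc["nutrients", "leaf_n"] = 0.15
    eff.loc["evenness", "leaf_n"] = 0.08
    eff.loc["mat", "leaf_c"] = 0.8
    eff.loc["map", "leaf_c"] = -0.6
    return eff


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth generative model for the synthetic survey.

    Attributes
    ----------
    effect_matrix
        16 drivers × 7 traits; slope of each trait on each *standardized*
        driver, in trait units per driver SD.
    trait_baselines, noise_sd
        Per-trait intercepts and residual SDs, trait units.
    driver_means, driver_sds, driver_correlation
        Gaussian parameters of the ten measured drivers (correlation has
        unit diagonal and must be positive semi-definite).
    invasion_shift, pair_noise_sd
        Mean invaded-minus-uninvaded shift and pair-level noise SD for
        the six paired variables; these create the Δ drivers.
    """

    effect_matrix: pd.DataFrame = field(default_factory=default_effect_matrix)
    trait_baselines: pd.Series = field(
        default_factory=lambda: _series(
            {"leaf_area": 30.0, "sla": 150.0, "ldmc": 250.0, "chlorophyll": 35.0,
             "leaf_c": 42.0, "leaf_n": 2.0, "leaf_cn": 21.0},
            TRAIT_COLUMNS, "trait_baselines")
    )
    noise_sd: pd.Series = field(
        default_factory=lambda: _series(
            {"leaf_area": 5.0, "sla": 18.0, "ldmc": 22.0, "chlorophyll": 3.5,
             "leaf_c": 1.2, "leaf_n": 0.22, "leaf_cn": 1.0},
            TRAIT_COLUMNS, "noise_sd")
    )
    driver_means: pd.Series = field(
        default_factory=lambda: _series(default_driver_means(), BASE_DRIVERS, "driver_means")
    )
    driver_sds: pd.Series = field(
        default_factory=lambda: _series(default_driver_sds(), BASE_DRIVERS, "driver_sds")
    )
    driver_correlation: np.ndarray = field(
        default_factory=lambda: np.eye(len(BASE_DRIVERS))
    )
    invasion_shift: pd.Series = field(
        default_factory=lambda: _series(
            {"richness": -2.0, "ph": -0.2, "nutrients": 5.0,
             "bacteria": 6.0, "fungi": 2.0, "fb_ratio": 0.01},
            PAIRED_VARIABLES, "invasion_shift")
    )
    pair_noise_sd: pd.Series = field(
        default_factory=lambda: _series(
            {"richness": 1.0, "ph": 0.15, "nutrients": 4.0,
             "bacteria": 5.0, "fungi": 1.5, "fb_ratio": 0.015},
            PAIRED_VARIABLES, "pair_noise_sd")
    )

    def __post_init__(self) -> None:
        eff = self.effect_matrix
        if list(eff.index) != list(DRIVER_COLUMNS) or list(eff.columns) != list(TRAIT_COLUMNS):
            raise ModelError("effect_matrix must be indexed by the 16 drivers x 7 traits")
        if not np.isfinite(eff.to_numpy()).all():
            raise ModelError("effect_matrix must be finite")
        if (self.noise_sd.to_numpy() <= 0).any():
            raise ModelError("noise_sd must be strictly positive")
        if (self.driver_sds.to_numpy() <= 0).any():
            raise ModelError("driver_sds must be strictly positive")
        corr = np.asarray(self.driver_correlation, dtype=float)
        if corr.shape != (len(BASE_DRIVERS),) * 2:
            raise ModelError(f"driver_correlation must be {len(BASE_DRIVERS)}x{len(BASE_DRIVERS)}")
        if not np.allclose(corr, corr.T):
            raise ModelError("driver_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ModelError("driver_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ModelError("driver_correlation must be positive semi-definite")

    def with_effects(self, effect_matrix: pd.DataFrame) -> "EffectModel":
        return replace(self, effect_matrix=effect_matrix)


@dataclass(frozen=True)
class SurveyBundle:
    """One synthetic survey realisation with its generating ground truth."""

    trait_table: pd.DataFrame
    environment_table: pd.DataFrame
    paired_table: pd.DataFrame
    ground_truth: EffectModel
    seed: int

    def __post_init__(self) -> None:
        if not self.trait_table["unit_id"].equals(self.environment_table["unit_id"]):
            raise ValueError("trait and environment tables must share unit ids and order")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _clamp(frame: pd.DataFrame) -> pd.DataFrame:
    for col, (lo, hi) in DRIVER_BOUNDS.items():
        if col in frame.columns:
            frame[col] = frame[col].clip(lo, hi)
    return frame


def generate_environment(
    design: SurveyDesign | None = None,
    model: EffectModel | None = None,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the 16-driver environment table and the per-pair paired table.

    Returns ``(environment_table, paired_table)``.  The environment table
    holds, per plot pair, the uninvaded-plot values of the ten measured
    drivers plus the six Δ variables; the paired table holds the raw
    invaded (``vi_*``) and uninvaded (``vu_*``) values behind each Δ.
    """
    design = design or SurveyDesign()
    model = model or EffectModel()
    rng = _rng(seed)
    units = generate_design(design)
    n = len(units)

    cov = np.outer(model.driver_sds, model.driver_sds) * np.asarray(
        model.driver_correlation, dtype=float
    )
    base = rng.multivariate_normal(model.driver_means.to_numpy(), cov, size=n, method="svd")
    env = units.copy()
    env[list(BASE_DRIVERS)] = base
    env = _clamp(env)

    paired = units.copy()
    for var in PAIRED_VARIABLES:
        vu = env[var].to_numpy()
        noise = rng.normal(0.0, model.pair_noise_sd[var], size=n)
        vi = vu + model.invasion_shift[var] + noise
        lo, hi = DRIVER_BOUNDS.get(var, (-np.inf, np.inf))
        vi = np.clip(vi, lo, hi)
        paired[f"vu_{var}"] = vu
        paired[f"vi_{var}"] = vi
        # a variable absent from both members of a pair (e.g. zero native
        # richness) counts as unchanged: Delta = 0
        total = vi + vu
        delta = np.zeros(n)
        ok = total > 0
        delta[ok] = relative_change(vi[ok], vu[ok])
        env[f"d_{var}"] = delta
    return env, paired


def generate_traits(env: pd.DataFrame, model: EffectModel | None = None, seed=0) -> pd.DataFrame:
    """Generate the 7-trait table from an environment table and effect model.

    Each trait is baseline + (column-standardized drivers) · effect column
    + Gaussian noise; noise draws that would make a trait nonpositive are
    resampled (at most 100 attempts per cell).  Leaf C:N is computed as
    leaf C / leaf N.
    """
    model = model or EffectModel()
    rng = _rng(seed)
    missing = [c for c in DRIVER_COLUMNS if c not in env.columns]
    if missing:
        raise KeyError(f"environment table missing driver columns {missing}")

    x = env.loc[:, list(DRIVER_COLUMNS)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # a constant driver contributes nothing
    z = (x - x.mean(axis=0)) / sd

    traits = env.loc[:, [c for c in KEY_COLUMNS if c in env.columns]].copy()
    generated = [t for t in TRAIT_COLUMNS if t != "leaf_cn"]
    linpred = z @ model.effect_matrix.loc[:, generated].to_numpy()
    for j, trait in enumerate(generated):
        mean = model.trait_baselines[trait] + linpred[:, j]
        values = mean + rng.normal(0.0, model.noise_sd[trait], size=len(env))
        for _ in range(100):
            bad = values <= 0
            if not bad.any():
                break
            values[bad] = mean[bad] + rng.normal(0.0, model.noise_sd[trait], size=int(bad.sum()))
        else:
            raise ModelError(
                f"could not draw positive values for {trait}; baseline/effects too close to zero"
            )
        traits[trait] = values
    traits["leaf_cn"] = traits["leaf_c"] / traits["leaf_n"]
    return traits.loc[:, [c for c in KEY_COLUMNS if c in traits.columns] + list(TRAIT_COLUMNS)]


def simulate_survey(
    design: SurveyDesign | None = None,
    model: EffectModel | None = None,
    seed: int = 0,
) -> SurveyBundle:
    """Run the full generator: design → environment → pairs → traits.

    A single integer seed feeds a hierarchical stream so the environment
    and trait stages are independently reproducible.
    """
    design = design or SurveyDesign()
    model = model or EffectModel()
    env_ss, trait_ss = np.random.SeedSequence(seed).spawn(2)
    env, paired = generate_environment(design, model, np.random.default_rng(env_ss))
    traits = generate_traits(env, model, np.random.default_rng(trait_ss))
    return SurveyBundle(
        trait_table=traits,
        environment_table=env,
        paired_table=paired,
        ground_truth=model,
        seed=seed,
    )


def aggregate_to_populations(bundle_table: pd.DataFrame) -> pd.DataFrame:
    """Average plot-pair rows up to site level (one row per population).

    Numeric columns are averaged within ``site``; key columns collapse to
    the site identity with ``unit_id = site``.
    """
    numeric = [
        c for c in bundle_table.columns
        if c not in KEY_COLUMNS and pd.api.types.is_numeric_dtype(bundle_table[c])
    ]
    grouped = bundle_table.groupby("site", sort=True)
    out = grouped[numeric].mean()
    out.insert(0, "pair", 0)
    out.insert(0, "site", out.index)
    out.insert(0, "location", grouped["location"].first())
    out.insert(0, "unit_id", out.index)
    return out.reset_index(drop=True)[["unit_id", "location", "site", "pair"] + numeric]
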