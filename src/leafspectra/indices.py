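"""Leaf trait indices.

Implements the measured-trait transforms (specific leaf area, leaf dry
matter content), the paired-plot relative-change metric Δ, and the
composite indices used to describe trait variation and the leaf
production / stress-tolerance spectrum:

* **PVI** (phenotypic variation index): per-unit min–max normalised trait
  score, ``(max(T) - T_i) / (max(T) - min(T))`` — 0 at the sample maximum,
  1 at the sample minimum.
* **LPI** (leaf production index): per-unit sum over the four production
  traits (leaf area, SLA, chlorophyll, leaf N) of the trait value divided
  by its cross-unit maximum; range (0, 4].
* **LTI** (leaf stress-tolerance index): analogous sum over the three
  tolerance traits (LDMC, leaf C, leaf C:N); range (0, 3].
* **spectrum ratio**: LTI / LPI, a per-unit position on the
  production–tolerance trade-off.

All composite indices use the observed sample extremes of the supplied
table (no trimming, no theoretical bounds).  The set of units that
defines the extremes can be narrowed with ``extremes_from`` because the
survey has two natural unit scopes (plots and populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait column order for a trait table.
TRAIT_COLUMNS = (
    "leaf_area",    # cm^2
    "sla",          # cm^2 g^-1
    "ldmc",         # mg g^-1
    "chlorophyll",  # SPAD index, dimensionless
    "leaf_c",       # % dry mass
    "leaf_n",       # % dry mass
    "leaf_cn",      # dimensionless C:N ratio
)

PRODUCTION_TRAITS = ("leaf_area", "sla", "chlorophyll", "leaf_n")
TOLERANCE_TRAITS = ("ldmc", "leaf_c", "leaf_cn")


class DomainError(ValueError):
    """Raised when an input lies outside an operation's mathematical domain."""


class SchemaError(KeyError):
    """Raised when a required column is absent from a table."""


class DegenerateRangeError(DomainError):
    """Raised when a trait vector is constant so min–max scaling is undefined."""


@dataclass(frozen=True)
class TraitCategoryMap:
    """Partition of the seven leaf traits into production and tolerance sets.

    Production traits capture carbon-fixation capacity (large, thin,
    chlorophyll- and nitrogen-rich leaves); tolerance traits capture
    persistence under stress (dense, carbon-rich tissue).
    """

    production_traits: tuple[str, ...] = PRODUCTION_TRAITS
    tolerance_traits: tuple[str, ...] = TOLERANCE_TRAITS

    def __post_init__(self) -> None:
        prod, tol = set(self.production_traits), set(self.tolerance_traits)
        if prod & tol:
            raise ValueError(f"production and tolerance sets overlap: {prod & tol}")
        if prod | tol != set(TRAIT_COLUMNS):
            raise ValueError("production and tolerance sets must jointly cover the seven traits")
        if len(prod) != 4 or len(tol) != 3:
            raise ValueError("expected 4 production and 3 tolerance traits")


def compute_sla(leaf_area, dry_mass):
    """Specific leaf area: leaf area (cm^2) per unit dry mass (g).

    Both arguments must be strictly positive; accepts scalars or arrays.
    """
    leaf_area = np.asarray(leaf_area, dtype=float)
    dry_mass = np.asarray(dry_mass, dtype=float)
    if np.any(leaf_area <= 0) or np.any(dry_mass <= 0):
        raise DomainError("compute_sla requires strictly positive leaf area and dry mass")
    out = leaf_area / dry_mass
    return out.item() if out.ndim == 0 else out


def compute_ldmc(dry_mass, fresh_mass):
    """Leaf dry matter content in mg g^-1: 1000 × dry mass / water-saturated fresh mass.

    Requires ``0 < dry_mass <= fresh_mass`` (a leaf cannot weigh more dry
    than fully hydrated).
    """
    dry_mass = np.asarray(dry_mass, dtype=float)
    fresh_mass = np.asarray(fresh_mass, dtype=float)
    if np.any(dry_mass <= 0) or np.any(fresh_mass <= 0):
        raise DomainError("compute_ldmc requires strictly positive masses")
    if np.any(dry_mass > fresh_mass):
        raise DomainError("dry mass cannot exceed fresh mass")
    out = 1000.0 * dry_mass / fresh_mass
    return out.item() if out.ndim == 0 else out


def relative_change(vi, vu):
    """Paired-plot relative change Δ = (Vi − Vu) / (Vi + Vu).

    ``vi`` is the invaded-plot value and ``vu`` the paired uninvaded-plot
    value; both must be nonnegative with a positive sum.  Δ is
    antisymmetric under swapping the pair and bounded in [−1, 1].
    """
    vi = np.asarray(vi, dtype=float)
    vu = np.asarray(vu, dtype=float)
    if np.any(vi < 0) or np.any(vu < 0):
        raise DomainError("relative_change requires nonnegative paired values")
    total = vi + vu
    if np.any(total <= 0):
        raise DomainError("relative_change undefined when vi + vu = 0")
    out = (vi - vu) / total
    return out.item() if out.ndim == 0 else out


def compute_pvi(values, extremes_from=None):
    """Phenotypic variation index: (max(T) − T_i) / (max(T) − min(T)).

    Parameters
    ----------
    values
        Trait values of the units to score (length ≥ 2 unless
        ``extremes_from`` is given).
    extremes_from
        Optional vector whose observed min/max define the scaling range
        (e.g. population means while scoring individual plots).  Defaults
        to ``values`` itself.

    The unit at the sample maximum scores 0 and the one at the minimum
    scores 1; the index is invariant under positive affine transforms of
    the trait.
    """
    values = np.asarray(values, dtype=float)
    ref = values if extremes_from is None else np.asarray(extremes_from, dtype=float)
    if ref.size < 2:
        raise DomainError("compute_pvi needs at least 2 reference units")
    hi, lo = np.max(ref), np.min(ref)
    if hi == lo:
        raise DegenerateRangeError("trait vector is constant; min-max range is zero")
    return (hi - values) / (hi - lo)


def _max_normalised_sum(traits: pd.DataFrame, columns: tuple[str, ...], label: str) -> pd.Series:
    missing = [c for c in columns if c not in traits.columns]
    if missing:
        raise SchemaError(f"{label} requires trait columns {missing}")
    sub = traits.loc[:, list(columns)].astype(float)
    if (sub <= 0).to_numpy().any() or not np.isfinite(sub.to_numpy()).all():
        raise DomainError(f"{label} requires strictly positive finite trait values")
    return (sub / sub.max(axis=0)).sum(axis=1)


def compute_lpi(traits: pd.DataFrame, category_map: TraitCategoryMap | None = None) -> pd.Series:
    """Leaf production index: Σ_j T_ij / max_i(T_ij) over the four production traits."""
    category_map = category_map or TraitCategoryMap()
    out = _max_normalised_sum(traits, category_map.production_traits, "compute_lpi")
    return out.rename("lpi")


def compute_lti(traits: pd.DataFrame, category_map: TraitCategoryMap | None = None) -> pd.Series:
    """Leaf stress-tolerance index: Σ_j T_ij / max_i(T_ij) over the three tolerance traits."""
    category_map = category_map or TraitCategoryMap()
    out = _max_normalised_sum(traits, category_map.tolerance_traits, "compute_lti")
    return out.rename("lti")


def spectrum_ratio(lti, lpi):
    """Per-unit trait-spectrum position: LTI / LPI.  Both must be positive."""
    lti_a = np.asarray(lti, dtype=float)
    lpi_a = np.asarray(lpi, dtype=float)
    if np.any(lti_a <= 0) or np.any(lpi_a <= 0):
        raise DomainError("spectrum_ratio requires strictly positive LTI and LPI")
    out = lti_a / lpi_a
    if isinstance(lti, pd.Series):
        return pd.Series(out, index=lti.index, name="spectrum_ratio")
    return out.item() if out.ndim == 0 else out


def validate_trait_table(traits: pd.DataFrame, rel_tol: float = 1e-6) -> pd.DataFrame:
    """Check a trait table against the expected schema and return a clean copy.

    * all seven trait columns present (``leaf_cn`` recomputed from leaf C
      and leaf N when absent);
    * all values strictly positive and finite;
    * if a supplied ``leaf_cn`` disagrees with ``leaf_c / leaf_n`` beyond
      ``rel_tol`` relative, the supplied column wins and a warning is logged.
    """
    traits = traits.copy()
    required = [c for c in TRAIT_COLUMNS if c != "leaf_cn"]
    missing = [c for c in required if c not in traits.columns]
    if missing:
        raise SchemaError(f"trait table is missing columns {missing}")
    implied_cn = traits["leaf_c"].astype(float) / traits["leaf_n"].astype(float)
    if "leaf_cn" not in traits.columns:
        traits["leaf_cn"] = implied_cn
    else:
        rel = np.abs(traits["leaf_cn"].astype(float) - implied_cn) / np.abs(implied_cn)
        if np.any(rel.to_numpy() > rel_tol):
            logger.warning(
                "supplied leaf_cn disagrees with leaf_c/leaf_n by up to %.3g relative; "
                "keeping the supplied column",
                float(np.max(rel.to_numpy())),
            )
    values = traits.loc[:, list(TRAIT_COLUMNS)].astype(float)
    if not np.isfinite(values.to_numpy()).all() or (values.to_numpy() <= 0).any():
        raise DomainError("trait values must be strictly positive and finite")
    traits.loc[:, list(TRAIT_COLUMNS)] = values
    return traits


def build_index_table(
    traits: pd.DataFrame,
    category_map: TraitCategoryMap | None = None,
    extremes_from: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the full per-unit index table from a validated trait table.

    Returns a DataFrame aligned with ``traits`` containing one
    ``pvi_<trait>`` column per trait plus ``lpi``, ``lti`` and
    ``spectrum_ratio``.
    """
    category_map = category_map or TraitCategoryMap()
    traits = validate_trait_table(traits)
    out = pd.DataFrame(index=traits.index)
    for col in TRAIT_COLUMNS:
        ref = None if extremes_from is None else extremes_from[col].to_numpy(dtype=float)
        out[f"pvi_{col}"] = compute_pvi(traits[col].to_numpy(dtype=float), extremes_from=ref)
    out["lpi"] = compute_lpi(traits, category_map)
    out["lti"] = compute_lti(traits, category_map)
    out["spectrum_ratio"] = spectrum_ratio(out["lti"], out["lpi"])
    return out
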