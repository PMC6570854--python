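"""Exhaustive all-subsets multimodel inference.

Given a response and p standardized predictors, every one of the 2^p
candidate OLS models (always including an intercept) is fitted and
ranked by the small-sample Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

with k = (subset size) + 2 counting the intercept and the residual
variance.  Akaike weights over the full set give each model a
probability; the analysis then derives

* a **95% confidence set** — the smallest AICc-ordered prefix of models
  whose cumulative weight reaches the level;
* **model-averaged coefficients** over that set (full, zero-substituted
  averaging by default), with unconditional standard errors combining
  within-model variance and between-model spread;
* per-predictor **importance** = the summed weight of all models that
  contain the predictor;
* the **relative contribution** decomposition — importance as a share of
  total importance, with category totals, per-capita (per-member)
  contributions, and a biotic/abiotic split.

The fit sweep is vectorised: candidate subsets of equal size share one
batched Cholesky solve on gathered sub-blocks of the (p+1)×(p+1) Gram
matrix, which keeps the full 2^16 enumeration at n = 300 in the
seconds range.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES: dict[str, str] = {
    "mat": "climate", "map": "climate",
    "richness": "diversity", "evenness": "diversity",
    "ph": "soil", "texture": "soil", "nutrients": "soil",
    "bacteria": "soil", "fungi": "soil", "fb_ratio": "soil",
    "d_richness": "interactions", "d_ph": "interactions",
    "d_nutrients": "interactions", "d_bacteria": "interactions",
    "d_fungi": "interactions", "d_fb_ratio": "interactions",
}

#: Default biotic classification: diversity, microbial pools, and all
#: invader–community interaction (Δ) variables are biotic (11 of 16);
#: climate, pH, texture and nutrient supply are abiotic (5 of 16).
DEFAULT_BIOTIC: frozenset = frozenset(
    {"richness", "evenness", "bacteria", "fungi", "fb_ratio"}
    | {f"d_{v}" for v in ("richness", "ph", "nutrients", "bacteria", "fungi", "fb_ratio")}
)


class DegenerateInputError(ValueError):
    """Raised for zero-variance responses/predictors or all-zero importances."""


class SingularFitError(np.linalg.LinAlgError):
    """Raised when a candidate subset is rank deficient."""


class SmallSampleError(ValueError):
    """Raised when n − k − 1 ≤ 0 so AICc is undefined."""


@dataclass(frozen=True)
class PredictorSchema:
    """Names, category labels and biotic flags of the predictor set."""

    names: tuple[str, ...]
    category: dict[str, str]
    biotic: frozenset

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("predictor names must be unique")
        missing = [n for n in self.names if n not in self.category]
        if missing:
            raise ValueError(f"predictors without a category label: {missing}")
        unknown = set(self.biotic) - set(self.names)
        if unknown:
            raise ValueError(f"biotic flags for unknown predictors: {sorted(unknown)}")

    @classmethod
    def survey_default(cls) -> "PredictorSchema":
        """The 16-driver survey schema: climate(2), diversity(2), soil(6), interactions(6)."""
        return cls(
            names=tuple(DEFAULT_CATEGORIES),
            category=dict(DEFAULT_CATEGORIES),
            biotic=DEFAULT_BIOTIC,
        )

    @classmethod
    def uniform(cls, names, category: str = "all", biotic=()) -> "PredictorSchema":
        names = tuple(names)
        return cls(names=names, category={n: category for n in names}, biotic=frozenset(biotic))

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for n in self.names:
            seen.setdefault(self.category[n], None)
        return tuple(seen)


def standardize_predictors(env: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each predictor column; returns (standardized, transform table).

    The transform table records the mean and SD removed from each column
    so averaged effects can be reported back on original scales.
    """
    columns = list(columns) if columns is not None else list(env.columns)
    x = env.loc[:, columns].astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise DegenerateInputError(f"zero-variance predictor column(s): {list(zero.index)}")
    z = (x - mean) / sd
    transform = pd.DataFrame({"mean": mean, "sd": sd})
    return z, transform


def aicc(n: int, k: int, rss: float) -> float:
    """Small-sample AIC for a Gaussian least-squares fit."""
    if n - k - 1 <= 0:
        raise SmallSampleError(f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)")
    if rss <= 0:
        raise DegenerateInputError("AICc undefined for rss <= 0 (degenerate likelihood)")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_subset(X: np.ndarray, y: np.ndarray, mask) -> tuple[float, np.ndarray]:
    """OLS fit of y on the masked predictor columns plus an intercept.

    Returns (rss, coefficients) with the intercept first.  The empty mask
    gives the intercept-only model, whose RSS is the total sum of squares
    about the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(mask)
    design = np.column_stack([np.ones(len(y)), X[:, cols]])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise SingularFitError(f"rank-deficient subset {cols.tolist()}")
    resid = y - design @ coef
    return float(resid @ resid), coef


@dataclass
class ModelSet:
    """All 2^p candidate models, sorted by (AICc, mask).

    ``masks`` are predictor-subset bitmasks; ``coef`` and ``coef_var``
    are dense (models × (p+1)) arrays — intercept first, zeros for
    predictors absent from a model.
    """

    names: tuple[str, ...]
    masks: np.ndarray
    k: np.ndarray
    rss: np.ndarray
    aicc: np.ndarray
    coef: np.ndarray
    coef_var: np.ndarray
    n: int
    delta_aicc: np.ndarray = field(default=None)
    weight: np.ndarray = field(default=None)

    @property
    def p(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.masks)

    def membership(self) -> np.ndarray:
        """Boolean (models × p) matrix: model m contains predictor j."""
        return (self.masks[:, None] >> np.arange(self.p)[None, :]) & 1 == 1

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        idx = slice(None) if top is None else slice(top)
        frame = pd.DataFrame(
            {
                "mask": [
                    "+".join(n for j, n in enumerate(self.names) if m >> j & 1) or "(intercept)"
                    for m in self.masks[idx]
                ],
                "k": self.k[idx],
                "rss": self.rss[idx],
                "aicc": self.aicc[idx],
            }
        )
        if self.delta_aicc is not None:
            frame["delta_aicc"] = self.delta_aicc[idx]
            frame["weight"] = self.weight[idx]
        return frame


def _mask_array(p: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    combos = list(itertools.combinations(range(p), size))
    out = np.zeros(len(combos), dtype=np.int64)
    for i, combo in enumerate(combos):
        for j in combo:
            out[i] |= 1 << j
    return out, np.asarray(combos, dtype=np.int64).reshape(len(combos), size)


def enumerate_models(X, y, names=None, compute_weights: bool = True) -> ModelSet:
    """Fit every subset of the predictors and rank by AICc.

    ``X`` may be a DataFrame (column names used) or array.  Subsets whose
    k would violate n − k − 1 > 0 are skipped with a logged warning.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns) if names is None else tuple(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(X.shape[1]))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.std(y) == 0:
        raise DegenerateInputError("response has zero variance")

    ones = np.ones((n, 1))
    xa = np.hstack([ones, X])
    gram = xa.T @ xa                      # (p+1, p+1)
    xty = xa.T @ y
    yty = float(y @ y)

    masks_all, k_all, rss_all = [], [], []
    coef_all, cvar_all = [], []
    skipped = 0
    for size in range(p + 1):
        k = size + 2
        if n - k - 1 <= 0:
            skipped += sum(1 for _ in itertools.combinations(range(p), size))
            continue
        masks, combos = _mask_array(p, size)
        # gathered design indices: intercept (0) plus selected columns (+1 offset)
        idx = np.concatenate([np.zeros((len(masks), 1), dtype=np.int64), combos + 1], axis=1)
        sub_gram = gram[idx[:, :, None], idx[:, None, :]]
        sub_xty = xty[idx]
        try:
            coefs = np.linalg.solve(sub_gram, sub_xty[..., None])[..., 0]
            inv_diag = np.diagonal(np.linalg.inv(sub_gram), axis1=1, axis2=2)
        except np.linalg.LinAlgError as err:
            raise SingularFitError(f"rank-deficient candidate subset at size {size}") from err
        rss = np.maximum(yty - np.einsum("mj,mj->m", coefs, sub_xty), 0.0)
        sigma2 = rss / (n - size - 1)
        cvar = inv_diag * sigma2[:, None]

        coef_dense = np.zeros((len(masks), p + 1))
        cvar_dense = np.zeros((len(masks), p + 1))
        rows = np.repeat(np.arange(len(masks)), size + 1)
        coef_dense[rows, idx.ravel()] = coefs.ravel()
        cvar_dense[rows, idx.ravel()] = cvar.ravel()

        masks_all.append(masks)
        k_all.append(np.full(len(masks), k))
        rss_all.append(rss)
        coef_all.append(coef_dense)
        cvar_all.append(cvar_dense)
    if skipped:
        logger.warning("skipped %d candidate subsets with n - k - 1 <= 0 (n=%d)", skipped, n)
    if not masks_all:
        raise SmallSampleError(f"no admissible candidate model at n={n}")

    masks = np.concatenate(masks_all)
    k = np.concatenate(k_all)
    rss = np.concatenate(rss_all)
    coef = np.concatenate(coef_all)
    cvar = np.concatenate(cvar_all)
    if np.any(rss <= 0):
        raise DegenerateInputError(
            "a candidate model fits the response exactly (rss = 0); AICc is undefined"
        )
    crit = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    order = np.lexsort((masks, crit))
    model_set = ModelSet(
        names=names,
        masks=masks[order],
        k=k[order],
        rss=rss[order],
        aicc=crit[order],
        coef=coef[order],
        coef_var=cvar[order],
        n=n,
    )
    if compute_weights:
        model_set = akaike_weights(model_set)
    return model_set


def akaike_weights(model_set: ModelSet) -> ModelSet:
    """Attach ΔAICc and normalised Akaike weights (in place; returned for chaining)."""
    delta = model_set.aicc - model_set.aicc.min()
    w = np.exp(-delta / 2.0)
    model_set.delta_aicc = delta
    model_set.weight = w / w.sum()
    return model_set


def confidence_set(model_set: ModelSet, level: float = 0.95) -> np.ndarray:
    """Indices of the smallest AICc-ordered prefix with cumulative weight ≥ level."""
    if not 0 < level <= 1:
        raise ValueError(f"confidence level must be in (0, 1], got {level}")
    if model_set.weight is None:
        raise ValueError("weights not computed; call akaike_weights first")
    cum = np.cumsum(model_set.weight)
    stop = int(np.searchsorted(cum, level)) + 1  # include the crossing model
    return np.arange(min(stop, len(model_set)))


def average_coefficients(
    model_set: ModelSet,
    set_indices: np.ndarray | None = None,
    conditional: bool = False,
) -> pd.DataFrame:
    """Model-averaged coefficients over a confidence set.

    Full (zero-substituted) averaging by default: absent predictors
    contribute estimate 0 with zero variance; ``conditional=True``
    averages only over the models that contain each predictor.
    Unconditional SE follows the standard model-averaging variance
    combination sqrt(Σ w_m [var(β|m) + (β_m − β̄)²]); p-values are
    two-sided normal on z = estimate/SE.
    """
    if set_indices is None:
        set_indices = confidence_set(model_set)
    set_indices = np.asarray(set_indices)
    if set_indices.size == 0:
        raise ValueError("confidence set is empty")
    w = model_set.weight[set_indices]
    cum_weight = float(w.sum())
    w = w / w.sum()
    coef = model_set.coef[set_indices, 1:]        # drop intercept
    cvar = model_set.coef_var[set_indices, 1:]
    member = model_set.membership()[set_indices]

    if conditional:
        denom = (w[:, None] * member).sum(axis=0)
        est = np.where(denom > 0, (w[:, None] * coef).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
        wn = np.where(denom[None, :] > 0, w[:, None] * member / np.where(denom, denom, 1.0)[None, :], 0.0)
        var = (wn * (cvar + (coef - est[None, :]) ** 2)).sum(axis=0)
    else:
        est = (w[:, None] * coef).sum(axis=0)
        var = (w[:, None] * (cvar + (coef - est[None, :]) ** 2)).sum(axis=0)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    sign = np.sign(est).astype(int)
    out = pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "p_value": pval, "sign": sign},
        index=list(model_set.names),
    )
    out.attrs["confidence_set_size"] = int(set_indices.size)
    out.attrs["cumulative_weight"] = cum_weight
    return out


def variable_importance(model_set: ModelSet) -> pd.Series:
    """Per-predictor importance: summed Akaike weight of containing models."""
    if model_set.weight is None:
        raise ValueError("weights not computed; call akaike_weights first")
    imp = (model_set.weight[:, None] * model_set.membership()).sum(axis=0)
    return pd.Series(imp, index=list(model_set.names), name="importance")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ContributionTable:
    """Per-predictor and per-category contribution decomposition (percent)."""

    predictors: pd.DataFrame     # importance, contribution_pct, sign, stars, category, biotic
    categories: pd.DataFrame     # total_pct, n_members, per_capita_pct
    biotic_total_pct: float
    abiotic_total_pct: float


def relative_contributions(
    importance: pd.Series,
    schema: PredictorSchema,
    averaged: pd.DataFrame | None = None,
) -> ContributionTable:
    """Decompose summed-weight importances into relative contributions.

    Each predictor's contribution is its importance divided by the total
    importance, in percent; category totals are sums over members and
    per-capita contributions divide each total by the member count.
    Signs and significance stars are taken from the averaged
    coefficients when supplied.
    """
    importance = importance.loc[list(schema.names)]
    total = float(importance.sum())
    if total <= 0:
        raise DegenerateInputError("all importances are zero; contributions undefined")
    contrib = 100.0 * importance / total

    pred = pd.DataFrame(
        {
            "importance": importance,
            "contribution_pct": contrib,
            "category": [schema.category[n] for n in schema.names],
            "biotic": [n in schema.biotic for n in schema.names],
        }
    )
    if averaged is not None:
        pred["sign"] = averaged["sign"].reindex(pred.index).fillna(0).astype(int)
        pred["stars"] = [_stars(p) for p in averaged["p_value"].reindex(pred.index)]
    else:
        pred["sign"] = 0
        pred["stars"] = ""

    rows = []
    for cat in schema.categories:
        members = pred[pred["category"] == cat]
        total_pct = float(members["contribution_pct"].sum())
        rows.append(
            {"category": cat, "total_pct": total_pct, "n_members": len(members),
             "per_capita_pct": total_pct / len(members)}
        )
    cats = pd.DataFrame(rows).set_index("category")
    biotic_total = float(pred.loc[pred["biotic"], "contribution_pct"].sum())
    return ContributionTable(
        predictors=pred,
        categories=cats,
        biotic_total_pct=biotic_total,
        abiotic_total_pct=100.0 - biotic_total,
    )


@dataclass(frozen=True)
class MMIResult:
    """Full multimodel-inference output for one response."""

    response: str
    model_set: ModelSet
    confidence_indices: np.ndarray
    averaged: pd.DataFrame
    importance: pd.Series
    contributions: ContributionTable


def run_mmi(
    env: pd.DataFrame,
    y,
    schema: PredictorSchema | None = None,
    response_name: str = "response",
    level: float = 0.95,
    conditional: bool = False,
) -> MMIResult:
    """End-to-end multimodel inference for one response.

    Standardizes the schema's predictor columns of ``env``, enumerates
    all subsets, and derives weights, the confidence set, averaged
    coefficients, importances and the contribution decomposition.
    """
    schema = schema or PredictorSchema.survey_default()
    z, _ = standardize_predictors(env, columns=list(schema.names))
    model_set = enumerate_models(z, np.asarray(y, dtype=float), names=schema.names)
    idx = confidence_set(model_set, level=level)
    averaged = average_coefficients(model_set, idx, conditional=conditional)
    importance = variable_importance(model_set)
    contributions = relative_contributions(importance, schema, averaged)
    return MMIResult(
        response=response_name,
        model_set=model_set,
        confidence_indices=idx,
        averaged=averaged,
        importance=importance,
        contributions=contributions,
    )
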