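"""Model-II (standardized major axis) regression and the PVI ANOVA.

Trait–trait and production–tolerance relationships involve error on both
axes, so ordinary least squares (which minimises vertical offsets only)
underestimates the slope; the standardized major axis (SMA) line, with
``|slope| = SD(y)/SD(x)`` signed by the Pearson correlation, is the
standard model-II summary for such allometric/bivariate trait data.
Significance of an SMA fit is the test of zero correlation (t
distribution with n − 2 df), which is what ``scipy.stats.pearsonr``
computes.

Differences in phenotypic variation among the seven traits are compared
with a one-way ANOVA followed by all-pairs Tukey HSD at α = 0.05,
summarised as a compact letter display: groups sharing a letter are not
significantly different.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class DegenerateError(ValueError):
    """Raised when an axis has zero variance."""


class SampleSizeError(ValueError):
    """Raised when a group or sample is too small for the requested fit."""


@dataclass(frozen=True)
class SMAFit:
    """A standardized-major-axis line fit.

    ``slope`` carries the sign of the correlation and magnitude
    SD(y)/SD(x); ``p_value`` tests H0: r = 0.
    """

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def sma_fit(x, y, log_transform: bool = False) -> SMAFit:
    """Fit a standardized major axis line to (x, y).

    Parameters
    ----------
    x, y
        Paired observations, n ≥ 3, each with positive variance.
    log_transform
        Natural-log both axes first (the convention for raw leaf traits;
        composite indices are fitted untransformed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise SampleSizeError("SMA fit needs at least 3 points")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise DegenerateError("log transform requires strictly positive values")
        x, y = np.log(x), np.log(y)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateError("SMA fit undefined for a zero-variance axis")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(
        slope=float(slope),
        intercept=intercept,
        r=r,
        r_squared=r * r,
        p_value=float(p),
        n=int(x.size),
    )


def sma_pairwise(table: pd.DataFrame, columns=None, log_transform: bool = True) -> pd.DataFrame:
    """SMA fits for every unordered column pair; one row per pair."""
    columns = list(columns) if columns is not None else list(table.columns)
    rows = []
    for a, b in itertools.combinations(columns, 2):
        fit = sma_fit(table[a].to_numpy(), table[b].to_numpy(), log_transform=log_transform)
        rows.append(
            {"x": a, "y": b, "slope": fit.slope, "intercept": fit.intercept,
             "r": fit.r, "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaLetters:
    """One-way ANOVA with Tukey-HSD compact letter display."""

    group_means: pd.Series
    group_se: pd.Series
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.group_means, "se": self.group_se,
             "letter": pd.Series(self.letters)}
        ).loc[self.group_means.index]


def _insert_absorb(names: list[str], significant: dict[frozenset, bool]) -> list[set]:
    """Piepho-style insert-and-absorb: valid letter groups, not always minimal."""
    groups: list[set[str]] = [set(names)]
    for pair, sig in significant.items():
        if not sig:
            continue
        a, b = tuple(pair)
        nxt = []
        for g in groups:
            if a in g and b in g:
                nxt.extend([g - {a}, g - {b}])
            else:
                nxt.append(g)
        # absorb: drop empties and strict subsets, deduplicate
        groups = []
        for g in nxt:
            if not g or any(g < h for h in nxt):
                continue
            if g not in groups:
                groups.append(g)
    return groups


def _minimal_cover(names: list[str], significant: dict[frozenset, bool]) -> list[set]:
    """Exact minimum letter-group family (feasible for small group counts).

    Valid families consist of sets with no significant pair inside that
    jointly cover every group and every non-significant pair; the search
    runs over maximal admissible sets by increasing family size.
    """
    nonsig = [
        frozenset(p)
        for p in itertools.combinations(names, 2)
        if not significant.get(frozenset(p), False)
    ]
    admissible = [
        frozenset(c)
        for r in range(1, len(names) + 1)
        for c in itertools.combinations(names, r)
        if all(
            not significant.get(frozenset((a, b)), False)
            for a, b in itertools.combinations(c, 2)
        )
    ]
    maximal = [c for c in admissible if not any(c < d for d in admissible)]
    upper = len(_insert_absorb(names, significant))
    for size in range(1, upper + 1):
        for family in itertools.combinations(maximal, size):
            if set().union(*family) != set(names):
                continue
            if all(any(pair <= g for g in family) for pair in nonsig):
                return [set(g) for g in family]
    return _insert_absorb(names, significant)  # unreachable for consistent input


def compact_letter_display(
    names: list[str], significant: dict[frozenset, bool]
) -> dict[str, str]:
    """Assign letters so two groups share one iff their pair is not significant.

    Uses a minimal exact cover for up to 12 groups and the
    insert-and-absorb construction beyond.  Letters are ordered by the
    input ``names`` order of each group's first member.
    """
    names = list(names)
    if len(names) <= 12:
        groups = _minimal_cover(names, significant)
    else:
        groups = _insert_absorb(names, significant)
    order = {n: i for i, n in enumerate(names)}
    groups.sort(key=lambda g: min(order[m] for m in g))
    letters = {n: "" for n in names}
    for i, g in enumerate(groups):
        letter = chr(ord("a") + i)
        for n in names:
            if n in g:
                letters[n] += letter
    return letters


def pvi_anova(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaLetters:
    """One-way ANOVA across trait groups of PVI values plus Tukey letters.

    ``groups`` maps trait name → vector of per-unit PVI values.  Every
    group needs at least two observations.
    """
    if len(groups) < 2:
        raise SampleSizeError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise SampleSizeError(f"group {k!r} has fewer than 2 observations")
    names = list(arrays)
    f_stat, p_val = stats.f_oneway(*arrays.values())

    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([np.full(arrays[k].size, k) for k in names])
    if np.ptp(values) == 0:
        # every observation identical: nothing distinguishable
        f_stat, p_val = 0.0, 1.0
        significant = {frozenset(p): False for p in itertools.combinations(names, 2)}
    else:
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        frame = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        significant = {
            frozenset((row["group1"], row["group2"])): bool(row["reject"])
            for _, row in frame.iterrows()
        }
    letters = compact_letter_display(names, significant)
    means = pd.Series({k: v.mean() for k, v in arrays.items()}, name="mean").loc[names]
    se = pd.Series(
        {k: v.std(ddof=1) / np.sqrt(v.size) for k, v in arrays.items()}, name="se"
    ).loc[names]
    return AnovaLetters(
        group_means=means,
        group_se=se,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=letters,
        alpha=alpha,
    )
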