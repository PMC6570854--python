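"""Independent brute-force oracles written directly against the formulas.

Deliberately naive (per-subset refits with pinv, explicit loops, no
shared code with the package) so they can serve as a second route for
checking the multimodel-inference chain and the compact letter display.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ols_pinv(X, y, subset):
    """Least-squares via pseudoinverse on intercept + selected columns."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones(len(y))] + [X[:, j] for j in subset])
    coef = np.linalg.pinv(design) @ y
    resid = y - design @ coef
    return float(resid @ resid), coef, design


def aicc_formula(n, k, rss):
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def brute_force_chain(X, y, level=0.95):
    """Full chain: enumerate → AICc → weights → confidence set → averaging → importance.

    Returns a dict of plain arrays keyed by predictor order of X.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    models = []
    for size in range(p + 1):
        for subset in itertools.combinations(range(p), size):
            rss, coef, design = ols_pinv(X, y, subset)
            k = size + 2
            crit = aicc_formula(n, k, rss)
            sigma2 = rss / (n - size - 1)
            cov = sigma2 * np.linalg.inv(design.T @ design)
            mask = sum(1 << j for j in subset)
            beta = np.zeros(p)
            var = np.zeros(p)
            for pos, j in enumerate(subset):
                beta[j] = coef[pos + 1]
                var[j] = cov[pos + 1, pos + 1]
            models.append({"mask": mask, "k": k, "rss": rss, "aicc": crit,
                           "beta": beta, "var": var})
    models.sort(key=lambda m: (m["aicc"], m["mask"]))
    amin = models[0]["aicc"]
    raw = [math.exp(-(m["aicc"] - amin) / 2) for m in models]
    total = sum(raw)
    for m, w in zip(models, raw):
        m["weight"] = w / total

    cum, cset = 0.0, []
    for m in models:
        cset.append(m)
        cum += m["weight"]
        if cum >= level:
            break
    wsum = sum(m["weight"] for m in cset)
    est = np.zeros(p)
    for m in cset:
        est += (m["weight"] / wsum) * m["beta"]
    var = np.zeros(p)
    for m in cset:
        var += (m["weight"] / wsum) * (m["var"] + (m["beta"] - est) ** 2)

    importance = np.zeros(p)
    for m in models:
        for j in range(p):
            if m["mask"] >> j & 1:
                importance[j] += m["weight"]
    contributions = 100.0 * importance / importance.sum()
    return {
        "aicc_sorted": np.array([m["aicc"] for m in models]),
        "masks_sorted": np.array([m["mask"] for m in models]),
        "weights_sorted": np.array([m["weight"] for m in models]),
        "cset_size": len(cset),
        "averaged": est,
        "unconditional_se": np.sqrt(var),
        "importance": importance,
        "contributions": contributions,
    }


def minimal_letter_cover(names, significant):
    """Smallest family of letter groups consistent with the significance matrix.

    A valid family: every group is a set with no significant pair inside,
    every unit appears in some group, and every non-significant pair
    shares some group.  Searches candidate families over maximal
    admissible sets by increasing size; feasible only for <= 7 names.
    """
    names = list(names)
    nonsig_pairs = [
        frozenset(p)
        for p in itertools.combinations(names, 2)
        if not significant.get(frozenset(p), False)
    ]

    def admissible(group):
        return all(
            not significant.get(frozenset((a, b)), False)
            for a, b in itertools.combinations(group, 2)
        )

    candidates = [
        frozenset(c)
        for r in range(1, len(names) + 1)
        for c in itertools.combinations(names, r)
        if admissible(c)
    ]
    # keep maximal candidates only; any valid cover can be lifted to maximal sets
    maximal = [c for c in candidates if not any(c < d for d in candidates)]
    for size in range(1, len(maximal) + 1):
        for family in itertools.combinations(maximal, size):
            covered_units = set().union(*family)
            if covered_units != set(names):
                continue
            if all(any(pair <= g for g in family) for pair in nonsig_pairs):
                return family
    raise RuntimeError("no valid letter cover found")  # unreachable for valid input


def sma_formulas(x, y):
    """SMA slope/intercept/r^2 straight from the defining formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = np.corrcoef(x, y)[0, 1]
    slope = (1.0 if r >= 0 else -1.0) * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    return slope, intercept, r * r
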