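"""Exact statistical primitives shared across the pipeline.

Every test used downstream (Fisher's exact test, exact binomial tails,
Benjamini-Hochberg FDR, chi-squared goodness of fit, Mann-Whitney U) is
implemented here from its defining formula so results can be audited
against closed forms and enumeration oracles.  Distribution functions come
from scipy; the test logic itself is local.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, chi2, hypergeom, norm

__all__ = [
    "fisher_exact",
    "binomial_tail",
    "bh_fdr",
    "chi_squared_gof",
    "rank_sum",
    "PValueSet",
]

# Fudge for comparing floating point pmf values in the two-sided Fisher sum,
# matching the conventional (1 + 1e-7) relative slack.
_REL_EPS = 1.0 + 1e-7


def fisher_exact(table, sidedness: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 contingency table.

    The null distribution is hypergeometric with all margins fixed.  The
    two-sided p-value follows the probability-mass convention: the sum of
    the probabilities of all tables (with the same margins) whose point
    probability does not exceed that of the observed table.

    Parameters
    ----------
    table : 2x2 array-like of non-negative ints ``[[a, b], [c, d]]``
    sidedness : "two-sided", "greater" or "less".  One-sided alternatives
        refer to the (0,0) cell: "greater" tests for enrichment of ``a``.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        import warnings

        warnings.warn("all-zero contingency table; p = 1 by convention")
        return 1.0
    r1 = a + b          # first-row margin
    c1 = a + c          # first-column margin
    rv = hypergeom(n, r1, c1)
    amin = max(0, c1 - (c + d))
    amax = min(r1, c1)
    if sidedness == "greater":
        return float(min(1.0, rv.sf(a - 1)))
    if sidedness == "less":
        return float(min(1.0, rv.cdf(a)))
    if sidedness != "two-sided":
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p_obs = rv.pmf(a)
    ks = np.arange(amin, amax + 1)
    pk = rv.pmf(ks)
    return float(min(1.0, pk[pk <= p_obs * _REL_EPS].sum()))


def binomial_tail(k: int, n: int, p0: float, side: str = "greater") -> float:
    """Exact binomial tail probability, with no normal approximation.

    side="greater" returns P(X >= k); side="less" returns P(X <= k),
    for X ~ Binomial(n, p0).
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if side == "greater":
        return float(binom.sf(k - 1, n, p0))
    if side == "less":
        return float(binom.cdf(k, n, p0))
    raise ValueError(f"unknown side {side!r}")


@dataclass
class PValueSet:
    """Result of a multiple-testing correction over a family of p-values."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    rejected: np.ndarray
    alpha: float = 0.05
    n_rejected: int = field(init=False)

    def __post_init__(self):
        self.n_rejected = int(np.sum(self.rejected))


def bh_fdr(pvalues, alpha: float = 0.05) -> PValueSet:
    """Benjamini-Hochberg step-up FDR control.

    Rejects all hypotheses whose rank i satisfies p(i) <= i*alpha/m for the
    largest such i.  q-values are the monotone (step-up) adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return PValueSet(p, p.copy(), np.zeros(0, dtype=bool), alpha)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ranked = ranked * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    crit = ranked <= alpha * np.arange(1, m + 1) / m
    rejected = np.zeros(m, dtype=bool)
    if crit.any():
        kmax = np.max(np.nonzero(crit)[0])
        rejected[order[: kmax + 1]] = True
    return PValueSet(p, q, rejected, alpha)


def chi_squared_gof(observed, expected_proportions) -> tuple[float, int, float]:
    """Chi-squared goodness of fit of observed counts against proportions.

    Returns (statistic, dof, p) with dof = categories - 1.  Expected counts
    are ``proportions * sum(observed)`` and must all be positive.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    total = obs.sum()
    exp = props / props.sum() * total
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    dof = obs.size - 1
    return stat, dof, float(chi2.sf(stat, dof))


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, u_obs: float, sidedness: str) -> float:
    """Full enumeration of the permutation distribution of U (small n)."""
    pooled = np.concatenate([a, b])
    n1 = a.size
    idx = range(pooled.size)
    us = []
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        ga, gb = pooled[mask], pooled[~mask]
        # U = #(a > b) + 0.5 #(a == b), computed pairwise
        diff = ga[:, None] - gb[None, :]
        us.append(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    us = np.asarray(us)
    eps = 1e-9
    if sidedness == "greater":
        return float(np.mean(us >= u_obs - eps))
    if sidedness == "less":
        return float(np.mean(us <= u_obs + eps))
    lo = np.mean(us <= u_obs + eps)
    hi = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2 * min(lo, hi)))


def rank_sum(group_a, group_b, sidedness: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test.

    U counts pairs (a, b) with a > b, ties counting 1/2.  For up to 20
    combined observations the p-value is computed by full enumeration of
    the permutation distribution; beyond that a normal approximation with
    midrank tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    diff = a[:, None] - b[None, :]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    n1, n2 = a.size, b.size
    if n1 + n2 <= 20:
        return u, _exact_rank_sum_p(a, b, u, sidedness)
    pooled = np.concatenate([a, b])
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return u, 1.0
    if sidedness == "greater":
        z = (u - mu - 0.5) / math.sqrt(var)
        return u, float(norm.sf(z))
    if sidedness == "less":
        z = (u - mu + 0.5) / math.sqrt(var)
        return u, float(norm.cdf(z))
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    return u, float(min(1.0, 2 * norm.sf(z)))
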