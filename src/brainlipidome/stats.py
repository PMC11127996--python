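"""Shared statistical machinery: BH adjustment, exact tests, permutations.

Everything here is deliberately oracle-verifiable: each test agrees with an
exhaustive-enumeration computation on instances small enough to enumerate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _iter_permutations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "hypergeom_over",
    "fisher_2x2",
    "rank_tests",
    "permutation_engine",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    tails: str = "two-sided"
    adjusted_p: float | None = None
    method: str = ""
    flags: tuple[str, ...] = ()


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN inputs are propagated as NaN (with a warning) and do not count
    toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn("NaN p-values propagated unadjusted", stacklevel=2)
    q = p[~nan_mask]
    m = q.size
    if m == 0:
        return out
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[~nan_mask] = res
    return out


def hypergeom_over(hits_in_set: int, set_size: int, pop_hits: int,
                   pop_size: int) -> float:
    """One-sided (over-representation) hypergeometric p-value.

    Probability of drawing >= ``hits_in_set`` marked items when ``set_size``
    items are drawn without replacement from a population of ``pop_size``
    containing ``pop_hits`` marked items.
    """
    if not (0 <= hits_in_set <= set_size <= pop_size
            and 0 <= pop_hits <= pop_size and hits_in_set <= pop_hits):
        raise ValueError(
            f"impossible counts: {hits_in_set}/{set_size} hits, "
            f"{pop_hits}/{pop_size} in population"
        )
    return float(sps.hypergeom.sf(hits_in_set - 1, pop_size, pop_hits,
                                  set_size))


def fisher_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (probability-ordering definition).

    A table with a zero margin is degenerate: p = 1 by convention, flagged.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    flags: tuple[str, ...] = ()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        flags = ("zero_margin",)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), n=int(t.sum()),
                      tails="two-sided", method="fisher_exact", flags=flags)


def rank_tests(x, y, alternative: str = "two-sided",
               paired: bool = False, exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U (independent) or Wilcoxon signed-rank (paired) test.

    Uses the exact null distribution when the combined sample size is
    ``<= exact_max_n`` and there are no ties, otherwise the normal
    approximation with tie correction; the mode used is recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    flags: tuple[str, ...] = ()
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return TestResult(0.0, 1.0, x.size, alternative,
                              method="wilcoxon_degenerate",
                              flags=("all_tied",))
        exact = x.size <= exact_max_n and np.unique(np.abs(d[d != 0])).size \
            == np.count_nonzero(d)
        method = "exact" if exact else "approx"
        res = sps.wilcoxon(x, y, alternative=alternative,
                           method="exact" if exact else "approx")
        return TestResult(float(res.statistic), float(res.pvalue), x.size,
                          alternative, method=f"wilcoxon_{method}",
                          flags=flags)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size) <= exact_max_n and not ties
    if np.all(x[:, None] == y[None, :]) and x.size * y.size:
        flags = ("all_tied",)
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue),
                      x.size + y.size, alternative,
                      method=f"mannwhitneyu_{'exact' if exact else 'approx'}",
                      flags=flags)


def permutation_engine(statistic_fn: Callable[[np.ndarray], float], n_items: int,
                       n_perm: int, seed: int | None = None,
                       alternative: str = "greater",
                       exhaustive_max: int = 10_000):
    """Generic label-permutation test.

    ``statistic_fn`` maps a permutation (an index array of length
    ``n_items``) to a scalar; the observed statistic is taken at the identity
    permutation.  When ``n_items!`` <= ``exhaustive_max`` the full permutation
    set is enumerated; otherwise ``n_perm`` random permutations are drawn and
    the add-one convention p = (1 + #{null >= obs}) / (n_perm + 1) is used
    (never exactly zero).

    Returns ``(observed, null_distribution, p, mode)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    identity = np.arange(n_items)
    obs = float(statistic_fn(identity))

    def _extreme(null: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return null >= obs
        if alternative == "less":
            return null <= obs
        return np.abs(null) >= abs(obs)

    if math.factorial(n_items) <= exhaustive_max:
        null = np.array([
            float(statistic_fn(np.array(perm)))
            for perm in _iter_permutations(range(n_items))
        ])
        p = float(np.mean(_extreme(null)))  # includes the identity
        return obs, null, p, "exhaustive"
    rng = np.random.default_rng(seed)
    null = np.array([
        float(statistic_fn(rng.permutation(n_items))) for _ in range(n_perm)
    ])
    p = (1.0 + int(_extreme(null).sum())) / (n_perm + 1.0)
    return obs, null, p, "sampled"
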