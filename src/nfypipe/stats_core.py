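"""Nonparametric primitives shared by every pipeline stage.

Implements the Wilcoxon/Mann–Whitney rank-sum test, the Jonckheere–Terpstra
trend test for ordered groups, and Benjamini–Hochberg FDR adjustment.  Small
instances use exact permutation null distributions; larger ones use the
standard normal approximations with tie correction (rank-sum) and a 0.5
continuity correction.

Conventions (documented rather than inherited from any one R/Python tool):

* two-sided p = min(1, 2·min(one-sided p's));
* ties contribute ½ to the Jonckheere count;
* the exact rank-sum path requires no ties and n1+n2 small enough to
  enumerate; ``method="exact"`` forces it (raising if infeasible).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr  # standard normal CDF

__all__ = ["TestResult", "rank_sum_test", "jonckheere_test", "bh_adjust"]

#: exact rank-sum enumeration is used at or below this pooled sample size
EXACT_RANKSUM_MAX_N = 12
#: exact Jonckheere enumeration is used when the multinomial arrangement
#: count is at or below this
EXACT_JONCKHEERE_MAX_ARRANGEMENTS = 200_000


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``method`` is ``"exact"`` when the p-value comes from full enumeration of
    the permutation null, ``"normal_approx"`` otherwise.  ``degenerate`` marks
    inputs with no information (e.g. all values identical), for which p = 1.
    """

    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]
    z_value: float | None = None
    alternative: str = "two_sided"
    degenerate: bool = False

    @property
    def n1(self) -> int:
        return self.group_sizes[0]

    @property
    def n2(self) -> int:
        return self.group_sizes[1] if len(self.group_sizes) > 1 else 0


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _two_sided(p_less: float, p_greater: float) -> float:
    return min(1.0, 2.0 * min(p_less, p_greater))


def rank_sum_test(x, y, alternative: str = "two_sided",
                  method: str = "auto") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney U) test for two independent samples.

    ``alternative="less"`` tests whether ``x`` is stochastically smaller
    than ``y``; ``"greater"`` the reverse.  The exact path enumerates all
    rank assignments (requires no ties); the normal approximation uses
    midranks, tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=n1 * n2 / 2.0, p_value=1.0,
                          method="normal_approx", group_sizes=(n1, n2),
                          alternative=alternative, degenerate=True)

    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # Mann–Whitney U of x over y

    has_ties = len(np.unique(pooled)) < pooled.size
    want_exact = method == "exact" or (
        method == "auto" and n1 + n2 <= EXACT_RANKSUM_MAX_N and not has_ties)
    if method == "exact" and has_ties:
        raise ValueError("exact rank-sum path requires tie-free data")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")

    if want_exact:
        p_less, p_greater = _exact_u_tail_probs(n1, n2, u)
        p = {"less": p_less, "greater": p_greater,
             "two_sided": _two_sided(p_less, p_greater)}[alternative]
        return TestResult(statistic=u, p_value=p, method="exact",
                          group_sizes=(n1, n2), alternative=alternative)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(sigma2)
    # continuity-corrected one-sided tails
    z_greater = (u - mu - 0.5) / sigma
    z_less = (u - mu + 0.5) / sigma
    p_greater = float(1.0 - ndtr(z_greater))
    p_less = float(ndtr(z_less))
    p = {"less": p_less, "greater": p_greater,
         "two_sided": _two_sided(p_less, p_greater)}[alternative]
    z = (u - mu) / sigma
    return TestResult(statistic=u, p_value=p, method="normal_approx",
                      group_sizes=(n1, n2), z_value=z, alternative=alternative)


def _exact_u_tail_probs(n1: int, n2: int, u: float) -> tuple[float, float]:
    """Tail probabilities of U under the permutation null, by exhaustive
    enumeration of all C(n1+n2, n1) rank assignments (tie-free data)."""
    n = n1 + n2
    if n > 20:
        raise ValueError("exact rank-sum enumeration limited to n1+n2 <= 20")
    combos = np.array(list(itertools.combinations(range(1, n + 1), n1)))
    u_all = combos.sum(axis=1) - n1 * (n1 + 1) / 2.0
    p_less = float(np.mean(u_all <= u + 1e-9))
    p_greater = float(np.mean(u_all >= u - 1e-9))
    return p_less, p_greater


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra
# ---------------------------------------------------------------------------

def _jt_statistic(groups: list[np.ndarray]) -> float:
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += float(np.sum(diff > 0)) + 0.5 * float(np.sum(diff == 0))
    return j


def _multinomial(sizes) -> int:
    total = sum(sizes)
    out = math.factorial(total)
    for s in sizes:
        out //= math.factorial(s)
    return out


def jonckheere_test(groups, alternative: str = "two_sided") -> TestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    J sums, over all ordered group pairs (i < j), the number of value pairs
    with the later group larger (ties count ½).  ``alternative="increasing"``
    rejects for large J, ``"decreasing"`` for small J.  Small instances are
    solved by exact enumeration of group assignments; otherwise the normal
    approximation with E[J] = (N² − Σn_k²)/4 and the standard tie-free
    variance is used, with a 0.5 continuity correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("jonckheere_test needs >=3 ordered groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("two_sided", "increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    sizes = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    n = pooled.size

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=_jt_statistic(groups), p_value=1.0,
                          method="normal_approx", group_sizes=sizes,
                          alternative=alternative, degenerate=True)

    j_obs = _jt_statistic(groups)

    if _multinomial(sizes) <= EXACT_JONCKHEERE_MAX_ARRANGEMENTS:
        p_le, p_ge = _exact_jt_tail_probs(pooled, sizes, j_obs)
        p = {"increasing": p_ge, "decreasing": p_le,
             "two_sided": _two_sided(p_le, p_ge)}[alternative]
        return TestResult(statistic=j_obs, p_value=p, method="exact",
                          group_sizes=sizes, alternative=alternative)

    sum_sq = sum(s * s for s in sizes)
    mu = (n * n - sum_sq) / 4.0
    sigma2 = (n * n * (2 * n + 3) - sum(s * s * (2 * s + 3) for s in sizes)) / 72.0
    sigma = math.sqrt(sigma2)
    p_ge = float(1.0 - ndtr((j_obs - mu - 0.5) / sigma))
    p_le = float(ndtr((j_obs - mu + 0.5) / sigma))
    p = {"increasing": p_ge, "decreasing": p_le,
         "two_sided": _two_sided(p_le, p_ge)}[alternative]
    return TestResult(statistic=j_obs, p_value=p, method="normal_approx",
                      group_sizes=sizes, z_value=(j_obs - mu) / sigma,
                      alternative=alternative)


def _exact_jt_tail_probs(pooled: np.ndarray, sizes: tuple[int, ...],
                         j_obs: float) -> tuple[float, float]:
    """Tail probabilities of J by enumerating all assignments of the pooled
    values (with multiplicity) to the ordered groups."""
    n_le = 0
    n_ge = 0
    total = 0
    indices = tuple(range(len(pooled)))

    def recurse(remaining: tuple[int, ...], k: int, chosen: list[np.ndarray]):
        nonlocal n_le, n_ge, total
        if k == len(sizes) - 1:
            groups = chosen + [pooled[list(remaining)]]
            j = _jt_statistic(groups)
            total += 1
            if j <= j_obs + 1e-9:
                n_le += 1
            if j >= j_obs - 1e-9:
                n_ge += 1
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, k + 1, chosen + [pooled[list(combo)]])

    recurse(indices, 0, [])
    return n_le / total, n_ge / total


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j>=i} ( m · p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
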