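"""Brute-force enumeration oracles shared by the unit and acceptance tests.

These deliberately re-derive every statistic from first principles (pair
counting over explicit value assignments) and share no code with the
implementation under test.
"""

import itertools

import numpy as np


def brute_force_ranksum_p(x, y, alternative):
    """Enumerate every reassignment of the pooled values to the two groups
    and count pair-dominances directly."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        stats.append(u_stat(xs, ys))
    stats = np.array(stats)
    p_less = np.mean(stats <= u_obs + 1e-9)
    p_greater = np.mean(stats >= u_obs - 1e-9)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def brute_force_jt(groups, alternative):
    """Enumerate all assignments of pooled values to the ordered groups."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]

    def j_stat(parts):
        j = 0.0
        for i in range(len(parts)):
            for k in range(i + 1, len(parts)):
                for a in parts[i]:
                    for b in parts[k]:
                        if b > a:
                            j += 1.0
                        elif b == a:
                            j += 0.5
        return j

    j_obs = j_stat(groups)
    stats = []

    def recurse(remaining, parts):
        if len(parts) == len(sizes) - 1:
            stats.append(j_stat(parts + [[pooled[i] for i in remaining]]))
            return
        k = len(parts)
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = [i for i in remaining if i not in set(combo)]
            recurse(rest, parts + [[pooled[i] for i in combo]])

    recurse(list(range(len(pooled))), [])
    stats = np.array(stats)
    p_le = np.mean(stats <= j_obs + 1e-9)
    p_ge = np.mean(stats >= j_obs - 1e-9)
    if alternative == "increasing":
        return p_ge
    if alternative == "decreasing":
        return p_le
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_bh(p):
    """Literal step-up rule: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos - 1, m)]
        q[idx] = min(1.0, min(candidates))
    return q
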