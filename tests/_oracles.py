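"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from first principles (enumeration,
closed-form sums of squares) and never calls back into the package's own
computation paths.
"""

from __future__ import annotations

import math

import numpy as np


def min_cost_integer_coupling(D, a, b) -> float:
    """Exhaustive minimum of sum(D_ij * x_ij) over integer couplings.

    ``a`` and ``b`` are integer mass vectors with equal totals.  The optimum
    over integer couplings equals the LP optimum because the transportation
    polytope with integer marginals has integer vertices.  Returns the
    *unnormalized* optimal cost (divide by the total mass for distributions).
    """
    a = [int(x) for x in a]
    b = [int(x) for x in b]
    assert sum(a) == sum(b) > 0
    n = len(b)
    best = [math.inf]
    rem = list(b)

    def place_row(i: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if i == len(a):
            best[0] = cost
            return
        supply = a[i]
        if supply == 0:
            place_row(i + 1, cost)
            return

        def compositions(j: int, left: int, c: float) -> None:
            if c >= best[0]:
                return
            if j == n - 1:
                if left <= rem[j]:
                    rem[j] -= left
                    place_row(i + 1, c + left * D[i][j])
                    rem[j] += left
                return
            for x in range(min(left, rem[j]) + 1):
                rem[j] -= x
                compositions(j + 1, left - x, c + x * D[i][j])
                rem[j] += x

        compositions(0, supply, cost)

    place_row(0, 0.0)
    return best[0]


def wasserstein_path_cdf(p, q) -> float:
    """1-D closed form on a path graph: sum of |CDF differences|."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.abs(np.cumsum(p - q)[:-1]).sum())


def welch_from_formulas(x, y) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df, evaluated directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx_ + vy / ny_
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny_) ** 2 / (ny_ - 1))
    return t, df


def kendall_tau_enumerated(x, y) -> float:
    """Kendall tau-a by enumerating all pairs (valid when there are no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)


def by_fdr_stepup(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment written out by hand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, p[idx] * m * c_m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def mixed_anova_sums_of_squares(values: np.ndarray, groups: np.ndarray,
                                sessions: np.ndarray, subjects: np.ndarray) -> dict:
    """Split-plot (two-way mixed) ANOVA F statistics for a balanced design.

    Classic sums-of-squares decomposition: between factor A (group), within
    factor B (session), subjects nested in groups.
    """
    values = np.asarray(values, dtype=float)
    glev = sorted(set(groups))
    tlev = sorted(set(sessions))
    slev = sorted(set(subjects))
    g, T = len(glev), len(tlev)
    n_subjects = len(slev)
    gm = values.mean()

    def mean_where(mask):
        return values[mask].mean()

    m_g = {a: mean_where(groups == a) for a in glev}
    m_t = {t: mean_where(sessions == t) for t in tlev}
    m_gt = {(a, t): mean_where((groups == a) & (sessions == t))
            for a in glev for t in tlev}
    m_s = {s: mean_where(subjects == s) for s in slev}
    group_of = {s: groups[subjects == s][0] for s in slev}
    n_per_group = n_subjects // g

    ss_a = T * n_per_group * sum((m_g[a] - gm) ** 2 for a in glev)
    ss_sa = T * sum((m_s[s] - m_g[group_of[s]]) ** 2 for s in slev)
    ss_b = n_subjects * sum((m_t[t] - gm) ** 2 for t in tlev)
    ss_ab = n_per_group * sum(
        (m_gt[(a, t)] - m_g[a] - m_t[t] + gm) ** 2 for a in glev for t in tlev
    )
    ss_err = 0.0
    for v, a, t, s in zip(values, groups, sessions, subjects):
        ss_err += (v - m_gt[(a, t)] - m_s[s] + m_g[a]) ** 2

    df_a, df_sa = g - 1, n_subjects - g
    df_b = T - 1
    df_ab = (g - 1) * (T - 1)
    df_err = (n_subjects - g) * (T - 1)
    return {
        "between": ((ss_a / df_a) / (ss_sa / df_sa), df_a, df_sa),
        "within": ((ss_b / df_b) / (ss_err / df_err), df_b, df_err),
        "interaction": ((ss_ab / df_ab) / (ss_err / df_err), df_ab, df_err),
    }
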