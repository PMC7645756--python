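"""Independent brute-force oracles used by the test suite.

These deliberately use the most literal possible algorithms (full
enumeration, triple loops) so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def exact_rank_sum_p(x, y) -> tuple[float, float]:
    """Two-sided exact Wilcoxon p by literal enumeration of rank subsets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    le = ge = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - offset
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / comb(n, n1))
    return float(u_obs), p


def exact_rank_sum_p_dp(x, y) -> float:
    """Two-sided exact Wilcoxon p via the full subset-sum distribution.

    Computes the same exhaustive permutation distribution as
    :func:`exact_rank_sum_p` with a subset-sum table instead of literal
    enumeration (identical answers, used when C(n, n1) is too large to
    enumerate in reasonable time; the agreement is asserted in the test
    suite on enumerable sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    doubled = np.rint(2 * ranks).astype(int)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    s_obs = int(round(2 * (u_obs + n1 * (n1 + 1) / 2.0)))
    max_sum = int(doubled.sum())
    table = [[0.0] * (max_sum + 1) for _ in range(n1 + 1)]
    table[0][0] = 1.0
    for val in doubled:
        for k in range(n1, 0, -1):
            row_prev, row = table[k - 1], table[k]
            for s in range(max_sum, val - 1, -1):
                if row_prev[s - val]:
                    row[s] += row_prev[s - val]
    counts = table[n1]
    le = sum(counts[: s_obs + 1])
    ge = sum(counts[s_obs:])
    return min(1.0, 2.0 * min(le, ge) / comb(n, n1))


def brute_force_network(counts, cell_types, gene_ids, pairs, threshold=0.20):
    """Edge weights by a literal triple loop over (pair, sender, receiver).

    ``counts`` is a dense cells x genes array; expressed fractions are
    recomputed from scratch per (type, gene) lookup.
    """
    counts = np.asarray(counts)
    cell_types = np.asarray(cell_types, dtype=object)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    types = sorted(set(cell_types))

    def frac(ct, gene):
        rows = counts[cell_types == ct]
        return (rows[:, gene_pos[gene]] > 0).mean()

    weights: dict[tuple[str, str], int] = {}
    for lig, rec in pairs:
        if lig not in gene_pos or rec not in gene_pos:
            continue
        for sender in types:
            if frac(sender, lig) < threshold:
                continue
            for receiver in types:
                if frac(receiver, rec) >= threshold:
                    weights[(sender, receiver)] = weights.get((sender, receiver), 0) + 1
    return weights


def bh_step_up(pvals):
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end  # 1-based rank of p[i] in ascending order
        running_min = min(running_min, p[i] * m / k)
        adj[i] = running_min
    return adj
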