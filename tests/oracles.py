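"""Brute-force reference implementations used only to check the package.

Each oracle is written from the defining formula or by exhaustive
enumeration, independently of the implementation paths it validates, and is
only feasible at tiny problem sizes.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def ari_pair_counting(a, b) -> float:
    """Adjusted Rand index by explicit pair counting over all item pairs."""
    a, b = list(a), list(b)
    n = len(a)
    both = same_a = same_b = 0
    for i, j in combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        both += sa and sb
        same_a += sa
        same_b += sb
    total = comb(n, 2)
    expected = same_a * same_b / total
    maximum = (same_a + same_b) / 2
    if maximum == expected:  # both partitions trivial
        return 1.0
    return (both - expected) / (maximum - expected)


def mwu_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Enumerates every way of labelling the pooled observations, computes U
    from rank sums each time, and doubles the smaller tail (capped at 1).
    Valid without ties (midranks would need a different null).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x = len(x)
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n_x):
        us.append(ranks[list(idx)].sum() - n_x * (n_x + 1) / 2)
    us = np.asarray(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return float(u_obs), float(min(1.0, 2 * min(p_lo, p_hi)))


def bh_stepup(p):
    """Benjamini-Hochberg q-values from the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


def gsea_running_sum(values, in_set, weight) -> float:
    """Enrichment score by the literal running-sum walk over a ranked list.

    ``values``: per-gene expression; ``in_set``: boolean membership. Genes
    are ranked descending with ties broken by gene position id (assumed
    pre-sorted by id).
    """
    values = np.asarray(values, float)
    in_set = np.asarray(in_set, bool)
    n = len(values)
    n_in = int(in_set.sum())
    order = sorted(range(n), key=lambda i: (-values[i], i))
    denom_hit = sum(abs(values[i]) ** weight for i in order if in_set[i])
    es, running = 0.0, 0.0
    for i in order:
        if in_set[i]:
            running += (abs(values[i]) ** weight / denom_hit) if denom_hit > 0 else 1 / n_in
        else:
            running -= 1 / (n - n_in)
        if abs(running) > abs(es):
            es = running
    return es


def tau_direct(profile) -> float:
    """Tau from its definition on an already-transformed tissue profile."""
    x = np.asarray(profile, float)
    xhat = x / x.max()
    return float(np.sum(1 - xhat) / (len(x) - 1))


def tsps_direct(profile) -> float:
    """TSPS (relative entropy vs uniform) on a linear tissue profile."""
    x = np.asarray(profile, float)
    p = x / x.sum()
    n = len(x)
    return float(sum(pi * np.log2(pi * n) for pi in p if pi > 0))
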