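"""Independent brute-force oracles for the rank tests.

These enumerate the full permutation null distributions directly and
share no code with the implementations they check.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def mwu_exact_oracle(x, y, alternative="two_sided"):
    """Mann-Whitney U p-value by enumerating all label assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = rankdata(pooled)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = n1 * n2 / 2
    us = np.array([u_of(c) for c in combinations(range(n1 + n2), n1)])
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu)))


def signed_rank_exact_oracle(x, y, alternative="two_sided"):
    """Wilcoxon signed-rank p-value by enumerating all 2^n sign patterns."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total_rank = ranks.sum()
    ws = np.array(
        [ranks[[bool(m >> i & 1) for i in range(n)]].sum() for m in range(2**n)]
    )
    if alternative == "less":
        return float(np.mean(ws <= w_obs))
    if alternative == "greater":
        return float(np.mean(ws >= w_obs))
    mid = total_rank / 2
    return float(np.mean(np.abs(ws - mid) >= abs(w_obs - mid)))


def bh_oracle(p):
    """Step-up Benjamini-Hochberg computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)
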