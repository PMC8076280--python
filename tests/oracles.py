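"""Independent brute-force oracles used to cross-check the statistics code.

These deliberately avoid the implementation's code paths: the Holm oracle is
a python loop over the sorted list, the signed-rank oracle enumerates all
2^n sign assignments, and the rank oracle counts smaller/equal elements
directly.
"""

import numpy as np
from scipy import stats as sps


def holm_oracle(ps):
    """Hand step-down: p_adj_(i) = max_{j<=i} min(1, (m-j+1) p_(j))."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * ps[idx]))
        adj[idx] = running
    return adj


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by full enumeration (no ties, no zeros)."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = np.array([sum(r for r, bit in zip(ranks, range(n))
                       if (mask >> bit) & 1)
                   for mask in range(2 ** n)])
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


def ranks_with_ties(x):
    x = np.asarray(x, float)
    return np.array([(x < v).sum() + ((x == v).sum() + 1) / 2 for v in x])


def spearman_oracle(x, y):
    return np.corrcoef(ranks_with_ties(x), ranks_with_ties(y))[0, 1]
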