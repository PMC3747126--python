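"""Brute-force dip oracle: LP minimization over unimodal CDFs.

Independent of the fast algorithm in sibewas.dip: for each candidate mode
(every unique data point, with a jump allowed at the mode only), the set of
unimodal CDF values at the data points compatible with a sup-distance d from
the empirical CDF is a polytope, so the minimal d is a linear program.  The
dip is the minimum over modes.  Only practical for small n.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(values) -> float:
    x = np.sort(np.asarray(values, float))
    n = x.size
    t, first_idx, counts = np.unique(x, return_index=True, return_counts=True)
    u = t.size
    last = first_idx + counts
    lo = last / n  # CDF value at the point, lower band anchor
    hi = first_idx / n  # left limit at the point, upper band anchor
    best = np.inf
    for k in range(u):
        best = min(best, _solve_mode(t, lo, hi, u, k))
    return best


def _solve_mode(t, lo, hi, u, k):
    # variables: g_0..g_{u-1}, g_k^- (left limit at the mode), d
    nv = u + 2
    gm, di = u, u + 1
    A, b = [], []

    def band(var, lo_r, hi_r):
        row = np.zeros(nv); row[var] = -1; row[di] = -1
        A.append(row); b.append(-lo_r)
        row = np.zeros(nv); row[var] = 1; row[di] = -1
        A.append(row); b.append(hi_r)

    for i in range(u):
        if i == k:
            band(i, lo[i], lo[i])
            band(gm, hi[i], hi[i])
        else:
            band(i, lo[i], hi[i])
    chain = []
    for i in range(u):
        if i == k:
            chain.extend([gm, i])
        else:
            chain.append(i)
    for a_, b_ in zip(chain, chain[1:]):  # monotone
        row = np.zeros(nv); row[a_] = 1; row[b_] = -1
        A.append(row); b.append(0.0)
    left = [(t[i], (gm if i == k else i)) for i in range(k + 1)]
    right = [(t[i], i) for i in range(k, u)]
    for pts, sign in ((left, -1.0), (right, 1.0)):  # convex / concave
        for (ta, va), (tb, vb), (tc, vc) in zip(pts, pts[1:], pts[2:]):
            row = np.zeros(nv)
            row[va] += 1 / (tb - ta)
            row[vb] += -1 / (tb - ta) - 1 / (tc - tb)
            row[vc] += 1 / (tc - tb)
            A.append(sign * row); b.append(0.0)
    c = np.zeros(nv); c[di] = 1
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0, 1)] * (nv - 1) + [(0, None)], method="highs")
    return res.fun if res.success else np.inf
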