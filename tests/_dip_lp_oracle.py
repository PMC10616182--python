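"""Exact small-n oracle for the dip statistic.

Solves the defining problem directly: the minimal sup-norm distance between
the ECDF and a unimodal CDF, as one linear program per candidate mode
location.  For mode at the k-th distinct value, the CDF is convex-increasing
up to the mode (left-limit variable, jump allowed at the mode) and
concave-increasing after; sup deviations against both ECDF corners at each
distinct value are bounded by t, which is minimised.  Far slower than the
production algorithm but independent of it.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    u, start = np.unique(x, return_index=True)
    cnt = np.diff(np.append(start, n))
    lo_c = start / n          # ECDF left limit at each distinct value
    hi_c = (start + cnt) / n  # ECDF value
    K = len(u)
    if K == 1:
        return 0.0
    best = np.inf
    for m in range(K):
        nv = K + 2
        ivm, it = K, K + 1  # left-limit-at-mode variable, objective t
        A, b = [], []

        def row(pairs, rhs):
            a = np.zeros(nv)
            for idx, c in pairs:
                a[idx] += c
            A.append(a)
            b.append(rhs)

        for k in range(K):
            if k == m:
                continue
            for y in (lo_c[k], hi_c[k]):
                row([(k, 1), (it, -1)], y)
                row([(k, -1), (it, -1)], -y)
        row([(ivm, 1), (it, -1)], lo_c[m])
        row([(ivm, -1), (it, -1)], -lo_c[m])
        row([(m, 1), (it, -1)], hi_c[m])
        row([(m, -1), (it, -1)], -hi_c[m])
        chain = list(range(m)) + [ivm, m] + list(range(m + 1, K))
        for a1, b1 in zip(chain[:-1], chain[1:]):
            row([(a1, 1), (b1, -1)], 0.0)
        row([(0, -1)], 0.0)
        row([(K - 1, 1)], 1.0)
        # convexity left of the mode, concavity right of it
        lidx = list(range(m)) + [ivm]
        lx = u[: m + 1]
        for k in range(1, len(lidx) - 1):
            d01, d12 = lx[k] - lx[k - 1], lx[k + 1] - lx[k]
            row([(lidx[k - 1], -1 / d01), (lidx[k], 1 / d01 + 1 / d12), (lidx[k + 1], -1 / d12)], 0.0)
        ridx = list(range(m, K))
        rx = u[m:]
        for k in range(1, len(ridx) - 1):
            d01, d12 = rx[k] - rx[k - 1], rx[k + 1] - rx[k]
            row([(ridx[k - 1], 1 / d01), (ridx[k], -1 / d01 - 1 / d12), (ridx[k + 1], 1 / d12)], 0.0)
        c = np.zeros(nv)
        c[it] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=[(None, None)] * nv,
                      method="highs")
        if res.success:
            best = min(best, res.fun)
    return float(best)
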