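"""Hartigan's dip statistic of unimodality.

The dip of an empirical distribution function F_n is

    dip(F_n) = min_G  sup_x |F_n(x) - G(x)|,

the minimum taken over all unimodal CDFs G (convex on the left of the mode,
concave on the right, a single atom allowed at the mode).  It is computed by
the iterative greatest-convex-minorant / least-concave-majorant algorithm of
Hartigan & Hartigan (1985, Ann. Statist.; AS 217): the candidate modal
interval is shrunk while tracking the largest deviation of the ECDF from the
hull fits outside it, until the residual gap between the two hulls no longer
exceeds the committed fit error.

Tied observations are separated by a deterministic spread of 1e-11 of the
data range before computing the statistic; the dip is continuous under this
perturbation, which lets a single distinct-abscissa code path serve exact
(to ~1e-10) for tied data as well.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]

_TIE_EPS = 1e-11


def _gcm_vertices(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Vertex indices of the greatest convex minorant of (x_i, i), i in [lo, hi]."""
    verts = [lo]
    for i in range(lo + 1, hi + 1):
        while len(verts) >= 2:
            a, b = verts[-2], verts[-1]
            if (b - a) * (x[i] - x[b]) <= (i - b) * (x[b] - x[a]):
                break
            verts.pop()
        verts.append(i)
    return np.asarray(verts)


def _lcm_vertices(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Vertex indices of the least concave majorant of (x_i, i), i in [lo, hi]."""
    verts = [lo]
    for i in range(lo + 1, hi + 1):
        while len(verts) >= 2:
            a, b = verts[-2], verts[-1]
            if (b - a) * (x[i] - x[b]) >= (i - b) * (x[b] - x[a]):
                break
            verts.pop()
        verts.append(i)
    return np.asarray(verts)


def dip_statistic(samples) -> float:
    """Compute the dip statistic of a 1-d sample.

    Parameters
    ----------
    samples : array-like
        Observations; need not be sorted.  At least 2 values.

    Returns
    -------
    float
        The dip, in (0, 0.25].  A sample whose values are all identical is a
        point mass (perfectly unimodal) and returns 0.0.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite observations")
    if x[0] == x[-1]:
        return 0.0
    # deterministic tie-break: strictly increasing abscissae
    x = x + np.arange(n) * (max(x[-1] - x[0], 1.0) * _TIE_EPS)

    lo, hi = 0, n - 1
    # Heights in count units: the ECDF at x_i rises from i to i+1 (0-based);
    # the GCM touches lower corners (x_i, i), the LCM upper corners (x_i, i+1).
    best_dev = 1.0  # fit deviation is exactly 1 count at every hull touch point
    for _ in range(n + 2):
        g = _gcm_vertices(x, lo, hi)
        c = _lcm_vertices(x, lo, hi)
        gcm_at = lambda xq: np.interp(xq, x[g], g.astype(float))  # noqa: E731
        lcm_at = lambda xq: np.interp(xq, x[c], (c + 1).astype(float))  # noqa: E731

        gap_at_c = (c + 1) - gcm_at(x[c])
        gap_at_g = lcm_at(x[g]) - g
        i_c = int(np.argmax(gap_at_c))
        i_g = int(np.argmax(gap_at_g))
        if gap_at_c[i_c] >= gap_at_g[i_g]:
            d = float(gap_at_c[i_c])
            v = int(c[i_c])
            j = int(np.searchsorted(x[g], x[v], side="right")) - 1
            j = min(max(j, 0), len(g) - 1)
            lo_new, hi_new = int(g[j]), v
        else:
            d = float(gap_at_g[i_g])
            u = int(g[i_g])
            j = int(np.searchsorted(x[c], x[u], side="left"))
            j = min(max(j, 0), len(c) - 1)
            lo_new, hi_new = u, int(c[j])
        if d <= best_dev:
            break
        idx_l = np.arange(lo, lo_new + 1)
        idx_u = np.arange(hi_new, hi + 1)
        dev_l = float(np.max((idx_l + 1) - gcm_at(x[idx_l]))) if idx_l.size else 0.0
        dev_u = float(np.max(lcm_at(x[idx_u]) - idx_u)) if idx_u.size else 0.0
        best_dev = max(best_dev, dev_l, dev_u)
        if lo_new == lo and hi_new == hi:
            best_dev = max(best_dev, d)
            break
        lo, hi = lo_new, hi_new
        if hi - lo < 1:
            break
    return best_dev / (2.0 * n)
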