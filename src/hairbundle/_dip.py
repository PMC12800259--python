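"""Hartigan & Hartigan dip statistic, exact.

The dip of a sample is the minimax sup-norm distance between its empirical
CDF and the nearest unimodal CDF (convex below the mode, concave above it;
an atom at the mode is admitted, as for a degenerate point mass).

Candidate modal positions are every gap between adjacent order statistics
and every data point. For a candidate, each branch (convex left of the
mode, concave right of it) must thread the box constraints imposed by the
ECDF's jump corners; branch feasibility reduces to a greatest-convex-
minorant / least-concave-majorant condition, and the two branches must
additionally connect monotonically. Connection feasibility at a trial dip
value d is evaluated for all candidates in one sweep using the minimal-
endpoint characterisation of boxed convex sequences (forced-slope lines,
queried through an upper envelope), and the dip is located by bisection.
Numba is used because the oscillation classifier bootstraps the dip null
distribution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic_sorted"]


@njit(cache=True)
def _prefix_pass(xu, F, Fm):
    """Deviations of the ECDF above the incremental GCM of (xu, Fm).

    Returns (A, Aexcl), raw (not halved):
      A[j]     = max_{i<=j} F[i] - GCM_j(xu[i])
      Aexcl[j] = same restricted to i<j (the candidate-mode point itself
                 may carry an atom, so its own deviation is dropped).
    """
    m = xu.size
    A = np.zeros(m)
    Aexcl = np.zeros(m)
    stack = np.empty(m, dtype=np.int64)
    segmax = np.empty(m)   # per stack slot: max dev over (prev hull pt, pt]
    cummax = np.empty(m)
    stack[0] = 0
    segmax[0] = F[0] - Fm[0]
    cummax[0] = segmax[0]
    top = 0
    A[0] = segmax[0]
    Aexcl[0] = 0.0
    for j in range(1, m):
        while top >= 1:
            p = stack[top - 1]
            q = stack[top]
            if (Fm[q] - Fm[p]) * (xu[j] - xu[q]) >= (Fm[j] - Fm[q]) * (xu[q] - xu[p]):
                top -= 1
            else:
                break
        p = stack[top]
        intmax = 0.0
        if j - p > 1:
            sl = (Fm[j] - Fm[p]) / (xu[j] - xu[p])
            for i in range(p + 1, j):
                dev = F[i] - (Fm[p] + sl * (xu[i] - xu[p]))
                if dev > intmax:
                    intmax = dev
        base = cummax[top]
        Aexcl[j] = max(base, intmax)
        top += 1
        stack[top] = j
        segmax[top] = max(intmax, F[j] - Fm[j])
        cummax[top] = max(base, segmax[top])
        A[j] = cummax[top]
    return A, Aexcl


@njit(cache=True)
def _max_slope_to_point(hull, top, xu, Fm, d, xP, yP):
    """Max slope from hull points (xu[h], Fm[h]+d) to P = (xP, yP).

    The hull is the lower convex hull of prefix points; the slope as a
    function of hull index is unimodal, so binary search on the chain-slope
    predicate locates the tangent vertex.
    """
    if top < 0:
        return 0.0
    lo = 0
    hi = top
    # pred(k): P strictly above chord through hull[k], hull[k+1]
    # => slope to P still increasing at k
    while lo < hi:
        mid = (lo + hi) // 2
        a = hull[mid]
        b = hull[mid + 1]
        ca = Fm[a] + d
        cb = Fm[b] + d
        sl = (cb - ca) / (xu[b] - xu[a])
        if yP - (ca + sl * (xP - xu[a])) > 0.0:
            lo = mid + 1
        else:
            hi = mid
    j = hull[lo]
    return (yP - (Fm[j] + d)) / (xP - xu[j])


@njit(cache=True)
def _lichao_insert(tree_s, tree_b, xu, m, s, b):
    node = 1
    lo = 0
    hi = m - 1
    while True:
        mid = (lo + hi) // 2
        xm = xu[mid]
        if s * xm + b > tree_s[node] * xm + tree_b[node]:
            ts = tree_s[node]
            tb = tree_b[node]
            tree_s[node] = s
            tree_b[node] = b
            s = ts
            b = tb
        if lo == hi:
            return
        if s * xu[lo] + b > tree_s[node] * xu[lo] + tree_b[node]:
            node = 2 * node
            hi = mid
        elif s * xu[hi] + b > tree_s[node] * xu[hi] + tree_b[node]:
            node = 2 * node + 1
            lo = mid + 1
        else:
            return


@njit(cache=True)
def _lichao_query(tree_s, tree_b, xu, m, i):
    node = 1
    lo = 0
    hi = m - 1
    x = xu[i]
    best = -1.0e300
    while True:
        v = tree_s[node] * x + tree_b[node]
        if v > best:
            best = v
        if lo == hi:
            return best
        mid = (lo + hi) // 2
        if i <= mid:
            node = 2 * node
            hi = mid
        else:
            node = 2 * node + 1
            lo = mid + 1


@njit(cache=True)
def _endpoint_sweep(xu, F, Fm, d, h_pt, h_gap):
    """Minimal convex-branch endpoint value for every candidate, at dip d.

    h_pt[t]:  branch through boxes at points 0..t-1, ending at the left
              limit of xu[t] (own lower bound Fm[t]-d).
    h_gap[t]: branch through boxes at points 0..t (endpoint at xu[t],
              lower bound F[t]-d).
    """
    m = xu.size
    tree_s = np.zeros(4 * m + 4)
    tree_b = np.full(4 * m + 4, -1.0e300)
    hull = np.empty(m, dtype=np.int64)
    top = -1
    for t in range(m):
        q = _lichao_query(tree_s, tree_b, xu, m, t)
        h_pt[t] = max(Fm[t] - d, q)
        h_gap[t] = max(F[t] - d, q)
        # create the forced-slope line for point t and insert it
        Lt = F[t] - d
        s = _max_slope_to_point(hull, top, xu, Fm, d, xu[t], Lt)
        if s < 0.0:
            s = 0.0
        _lichao_insert(tree_s, tree_b, xu, m, s, Lt - s * xu[t])
        # push (xu[t], Fm[t]) onto the lower hull
        while top >= 1:
            p = hull[top - 1]
            qq = hull[top]
            if (Fm[qq] - Fm[p]) * (xu[t] - xu[qq]) >= (Fm[t] - Fm[qq]) * (xu[qq] - xu[p]):
                top -= 1
            else:
                break
        top += 1
        hull[top] = t


@njit(cache=True)
def _feasible(xu, F, Fm, xr, Fr, Fmr, A, Aexcl, B, Bexcl, d,
              h_pt, h_gap, r_pt, r_gap):
    """Is there a unimodal CDF within sup-distance d of the ECDF?"""
    m = xu.size
    d2 = 2.0 * d + 1e-14
    _endpoint_sweep(xu, F, Fm, d, h_pt, h_gap)
    _endpoint_sweep(xr, Fr, Fmr, d, r_pt, r_gap)
    # all-concave / all-convex candidates
    if B[0] <= d2 or A[m - 1] <= d2:
        return True
    for t in range(m):
        # mode at point t (atom allowed)
        if Aexcl[t] <= d2 and Bexcl[t] <= d2:
            r = 1.0 - r_pt[m - 1 - t]
            if h_pt[t] <= r + 1e-14:
                return True
        # mode in the gap after point t
        if t + 1 < m and A[t] <= d2 and B[t + 1] <= d2:
            r = 1.0 - r_gap[m - 1 - (t + 1)]
            if h_gap[t] <= r + 1e-14:
                return True
    return False


@njit(cache=True)
def _dip_core(xu, F, Fm):
    m = xu.size
    if m == 1:
        return 0.0
    A, Aexcl = _prefix_pass(xu, F, Fm)
    xr = np.empty(m)
    Fr = np.empty(m)
    Fmr = np.empty(m)
    for i in range(m):
        xr[i] = -xu[m - 1 - i]
        Fr[i] = 1.0 - Fm[m - 1 - i]
        Fmr[i] = 1.0 - F[m - 1 - i]
    B_, Bexcl_ = _prefix_pass(xr, Fr, Fmr)
    B = B_[::-1].copy()
    Bexcl = Bexcl_[::-1].copy()

    # lower bound: branch feasibility alone (connection relaxed)
    lo = min(B[0], A[m - 1])
    for t in range(m):
        v = max(Aexcl[t], Bexcl[t])
        if v < lo:
            lo = v
        if t + 1 < m:
            v = max(A[t], B[t + 1])
            if v < lo:
                lo = v
    lo = 0.5 * lo

    h_pt = np.empty(m)
    h_gap = np.empty(m)
    r_pt = np.empty(m)
    r_gap = np.empty(m)
    if _feasible(xu, F, Fm, xr, Fr, Fmr, A, Aexcl, B, Bexcl, lo,
                 h_pt, h_gap, r_pt, r_gap):
        return lo
    hi = 0.251
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _feasible(xu, F, Fm, xr, Fr, Fmr, A, Aexcl, B, Bexcl, mid,
                     h_pt, h_gap, r_pt, r_gap):
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13:
            break
    return hi


def dip_statistic_sorted(x_sorted: np.ndarray) -> float:
    """Dip of a sorted 1-D sample (ties allowed)."""
    n = x_sorted.size
    xu, counts = np.unique(x_sorted, return_counts=True)
    F = np.cumsum(counts) / n
    Fm = F - counts / n
    return float(_dip_core(xu, F, Fm))
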