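"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the dip oracle solves
the defining minimax problem directly as a sequence of linear programs,
the correlation oracle evaluates the covariance formula with explicit
loops, and the frequency oracle counts zero crossings.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog


def dip_lp(x: np.ndarray) -> float:
    """Exact dip: minimize sup|Fn - G| over unimodal CDFs G.

    G must be convex below its mode and concave above it; an atom at the
    mode is admitted (CDFs are right-continuous, so the jump sits at the
    mode itself). Every modal position (each inter-point gap and each data
    point) is enumerated; for a fixed position the problem is linear in
    the CDF values at the data points and the sup-distance d, and is
    solved with scipy's LP solver.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    xu, counts = np.unique(x, return_counts=True)
    F = np.cumsum(counts) / n
    Fm = F - counts / n
    m = xu.size
    if m == 1:
        return 0.0
    best = np.inf
    candidates = [("gap", j) for j in range(-1, m)] + \
        [("pt", t) for t in range(m)]
    for kind, t in candidates:
        nh = 1 if kind == "pt" else 0
        nv = m + nh + 1
        ih = m
        idd = m + nh
        A_ub, b_ub = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for i in range(m):
            if kind == "pt" and i == t:
                le([(i, -1.0), (idd, -1.0)], -F[i])
                le([(i, 1.0), (idd, -1.0)], F[i])
            else:
                le([(i, -1.0), (idd, -1.0)], -F[i])
                le([(i, 1.0), (idd, -1.0)], Fm[i])
        if kind == "pt":
            le([(ih, -1.0), (idd, -1.0)], -Fm[t])
            le([(ih, 1.0), (idd, -1.0)], Fm[t])
        order = []
        for i in range(m):
            if kind == "pt" and i == t:
                order.append(ih)
            order.append(i)
        for a, b in zip(order[:-1], order[1:]):
            le([(a, 1.0), (b, -1.0)], 0.0)
        le([(order[0], -1.0)], 0.0)
        le([(m - 1, 1.0)], 1.0)
        if kind == "pt":
            cvx = [(xu[i], i) for i in range(t)] + [(xu[t], ih)]
            ccv = [(xu[i], i) for i in range(t, m)]
        else:
            cvx = [(xu[i], i) for i in range(t + 1)]
            ccv = [(xu[i], i) for i in range(t + 1, m)]
        for pts, sgn in ((cvx, 1.0), (ccv, -1.0)):
            for (xa, va), (xb, vb), (xc, vc) in zip(pts[:-2], pts[1:-1],
                                                    pts[2:]):
                le([(va, -sgn * (xc - xb)), (vb, sgn * (xc - xa)),
                    (vc, -sgn * (xb - xa))], 0.0)
        res = linprog(np.eye(nv)[idd], A_ub=np.array(A_ub),
                      b_ub=np.array(b_ub),
                      bounds=[(None, None)] * (nv - 1) + [(0, None)],
                      method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return float(best)


def cross_correlation_loops(x, y) -> float:
    """Direct double-loop evaluation of cc = cov(x,y) / (sx * sy)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n)) / n
    sx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)) / n)
    sy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)) / n)
    return cov / (sx * sy)


def zero_crossing_frequency(x: np.ndarray, fs: float) -> float:
    """Cycle-counting rate: upward+downward crossings / 2 / duration."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    s = np.signbit(x)
    crossings = int(np.count_nonzero(s[1:] != s[:-1]))
    return crossings / 2.0 / (x.size / fs)


def logistic_map(n: int, x0: float = 0.383451) -> np.ndarray:
    """Trajectory of x -> 4 x (1 - x), the fully chaotic logistic map
    (Kolmogorov-Sinai entropy ln 2 per iterate)."""
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = 4.0 * x * (1.0 - x)
        out[i] = x
    return out
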