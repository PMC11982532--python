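"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: the dip oracle solves
the defining minimax problem by linear programming, and the ARI oracle counts
agreeing/disagreeing pairs explicitly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(sample) -> float:
    """Exact dip by LP: min over unimodal CDFs G of sup |F_n - G|.

    For every candidate mode placement (in a gap between distinct values, or
    at a value where G may jump), the feasible G values at the data points
    form a polytope (band, monotonicity, convexity/concavity constraints),
    all linear in the band half-width d.  Minimizing d per placement and
    taking the overall minimum gives the dip exactly.  Intended for tiny n.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    t, counts = np.unique(x, return_counts=True)
    m = t.size
    if m < 2:
        return 0.0
    n = x.size
    c = np.concatenate(([0.0], np.cumsum(counts))) / n  # c[0..m]

    best = math.inf

    def solve(A_ub, b_ub, nvar):
        cost = np.zeros(nvar)
        cost[0] = 1.0  # minimize d
        bounds = [(0, 0.5)] + [(0.0, 1.0)] * (nvar - 1)
        res = linprog(cost, A_ub=np.asarray(A_ub), b_ub=np.asarray(b_ub),
                      bounds=bounds, method="highs")
        return res.fun if res.success else math.inf

    def band(rows, rhs, var, lo, hi, nvar):
        # lo - d <= v <= hi + d
        r = np.zeros(nvar); r[var] = 1.0; r[0] = -1.0
        rows.append(r.copy()); rhs.append(hi)
        r = np.zeros(nvar); r[var] = -1.0; r[0] = -1.0
        rows.append(r.copy()); rhs.append(-lo)

    def mono(rows, rhs, va, vb, nvar):
        r = np.zeros(nvar); r[va] = 1.0; r[vb] = -1.0
        rows.append(r.copy()); rhs.append(0.0)

    def bend(rows, rhs, pts, nvar, convex: bool):
        # pts: list of (t, var); slope constraints between consecutive triples
        for (t0, v0), (t1, v1), (t2, v2) in zip(pts, pts[1:], pts[2:]):
            h0, h1 = t1 - t0, t2 - t1
            # convex: (y1-y0)/h0 <= (y2-y1)/h1  ->  y0*h1 - y1*(h0+h1) + y2*h0 >= 0
            r = np.zeros(nvar)
            r[v0] = -h1; r[v1] = h0 + h1; r[v2] = -h0
            if not convex:
                r = -r
            rows.append(r); rhs.append(0.0)

    # mode in the gap after point k (k=0 -> all concave, k=m -> all convex).
    # The fitted CDF must traverse the gap: the convex piece keeps rising at
    # its carried slope until the mode M, and the concave piece's first slope
    # dominates its later slopes.  The best M is at one end of the gap, so
    # two variants are solved: M just after t[k-1] (the concave piece spans
    # the gap) and M just before t[k] (the convex piece spans it).
    for k in range(m + 1):
        for variant in ("concave_spans", "convex_spans"):
            nvar = 1 + m + 1  # d, values, one handover variable
            w = m + 1         # handover value at the mode
            rows, rhs = [], []
            for j in range(m):
                band(rows, rhs, j + 1, c[j + 1], c[j], nvar)
                if j:
                    mono(rows, rhs, j, j + 1, nvar)
            bend(rows, rhs, [(t[j], j + 1) for j in range(k)], nvar, convex=True)
            bend(rows, rhs, [(t[j], j + 1) for j in range(k, m)], nvar,
                 convex=False)
            if 0 < k < m:
                gap = t[k] - t[k - 1]
                if variant == "concave_spans":
                    # w = value just after the jump at M ~ t[k-1]
                    mono(rows, rhs, k, w, nvar)            # g_k <= w
                    band(rows, rhs, w, c[k], c[k], nvar)   # |w - F(gap)| <= d
                    mono(rows, rhs, w, k + 1, nvar)        # w <= h_{k+1}
                    if k + 2 <= m:
                        # slope(M -> t_k) >= slope(t_k -> t_{k+1})
                        h1 = gap
                        h2 = t[k + 1] - t[k]
                        r = np.zeros(nvar)
                        r[w] = h2
                        r[k + 1] = -(h1 + h2)
                        r[k + 2] = h1
                        rows.append(r)
                        rhs.append(0.0)
                else:
                    # w = left limit at M ~ t[k]; the convex piece carries
                    # its final slope across the whole gap
                    mono(rows, rhs, k, w, nvar)            # g_k <= w
                    r = np.zeros(nvar)                     # w <= F(gap) + d
                    r[w] = 1.0
                    r[0] = -1.0
                    rows.append(r)
                    rhs.append(c[k])
                    mono(rows, rhs, w, k + 1, nvar)        # w <= h_{k+1}
                    if k >= 2:
                        h0 = t[k - 1] - t[k - 2]
                        r = np.zeros(nvar)
                        # w >= g_k + gap * (g_k - g_{k-1}) / h0
                        r[k] = h0 + gap
                        r[k - 1] = -gap
                        r[w] = -h0
                        rows.append(r)
                        rhs.append(0.0)
            best = min(best, solve(rows, rhs, nvar))
            if not 0 < k < m:
                break  # single-flank placements need no second variant

    # mode at point t[j]: G may jump there, so its left limit a (extra
    # variable) only needs to track F(t_j-) = c[j], while the value b at t[j]
    # only needs to track F(t_j) = c[j+1]
    for j in range(m):
        nvar = 1 + m + 1
        a = m + 1
        rows, rhs = [], []
        for i in range(m):
            if i == j:
                band(rows, rhs, a, c[j], c[j], nvar)
                band(rows, rhs, j + 1, c[j + 1], c[j + 1], nvar)
            else:
                band(rows, rhs, i + 1, c[i + 1], c[i], nvar)
        for i in range(1, m):
            mono(rows, rhs, i, i + 1, nvar)
        if j:
            mono(rows, rhs, j, a, nvar)   # g_{j-1} <= a
        mono(rows, rhs, a, j + 1, nvar)   # a <= b
        left_pts = [(t[i], i + 1) for i in range(j)] + [(t[j], a)]
        right_pts = [(t[i], i + 1) for i in range(j, m)]
        bend(rows, rhs, left_pts, nvar, convex=True)
        bend(rows, rhs, right_pts, nvar, convex=False)
        best = min(best, solve(rows, rhs, nvar))

    return float(best)


def ari_pair_counting(labels_a, labels_b) -> float:
    """ARI from explicit enumeration of all C(n,2) item pairs."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def all_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
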