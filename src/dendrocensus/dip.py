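"""Hartigan's dip statistic for unimodality.

The dip of a distribution function ``F`` is the smallest sup-norm distance
between ``F`` and the class of unimodal distribution functions (convex up to
some mode, concave after, with an atom allowed at the mode).  For an
empirical CDF of ``n`` points the dip lies in ``[0, 1/4]``; the maximum
``1/4`` is attained exactly by a balanced two-point sample, and samples with
fewer than two distinct values have dip 0.

Algorithm: bisection on the band half-width ``d`` with an exact feasibility
test.  ``F`` is within ``d`` of some unimodal CDF iff there is a mode
placement (in a gap between adjacent distinct values, or at a value where
the fitted CDF may jump) such that

* a convex nondecreasing function fits the band ``[F(x)-d, F(x)+d]`` left of
  the mode,
* a concave nondecreasing function fits the band right of the mode, and
* the convex piece, continued past its last point at its (forced) final
  slope, can hand over to the concave piece at the mode without leaving the
  band (the coupling condition).

The convex-side quantities are computed in one left-to-right sweep: an
incremental convex hull of the band ceilings yields, for each point, the
minimal slope any feasible convex fit must carry out of that point; a Li
Chao line container maintains the maximum over the induced support lines,
which equals the pointwise minimum of all feasible convex fits.  The
concave side is the same sweep on the mirrored sample.  Feasibility of each
``d`` is then a linear scan over mode placements.  The implementation is
validated in the test suite against an exhaustive linear-programming
solution of the defining minimax problem on small samples.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["dip_statistic", "empirical_cdf"]

_NEG = -1e30
_POS = 1e30


def empirical_cdf(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, F(x))`` of the empirical CDF at the unique sample values."""
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    ux, counts = np.unique(x, return_counts=True)
    return ux, np.cumsum(counts) / x.size


@njit(cache=True)
def _lichao_insert(node_s, node_b, has, t, node, lo, hi, s, b):
    # insert line y = s*x + b over query positions t[lo..hi]
    while True:
        if not has[node]:
            node_s[node] = s
            node_b[node] = b
            has[node] = True
            return
        mid = (lo + hi) // 2
        xm = t[mid]
        cur_mid = node_s[node] * xm + node_b[node]
        new_mid = s * xm + b
        if new_mid > cur_mid:
            s, node_s[node] = node_s[node], s
            b, node_b[node] = node_b[node], b
        if lo == hi:
            return
        xl = t[lo]
        if s * xl + b > node_s[node] * xl + node_b[node]:
            node, hi = 2 * node, mid
        else:
            node, lo = 2 * node + 1, mid + 1


@njit(cache=True)
def _lichao_query(node_s, node_b, has, t, pos, m):
    node, lo, hi = 1, 0, m - 1
    best = _NEG
    x = t[pos]
    while True:
        if has[node]:
            v = node_s[node] * x + node_b[node]
            if v > best:
                best = v
        if lo == hi:
            return best
        mid = (lo + hi) // 2
        if pos <= mid:
            node, hi = 2 * node, mid
        else:
            node, lo = 2 * node + 1, mid + 1


@njit(cache=True)
def _convex_sweep(t, lower, upper, d, feas, env):
    """Left-to-right convex-fit sweep.

    feas[j] <- a convex nondecreasing function fits the bands of points 0..j
    env[j]  <- pointwise minimum over feasible convex fits of points < j,
               evaluated (extended) at t[j]; -inf when no point precedes j.
    """
    m = t.size
    hx = np.empty(m)
    hy = np.empty(m)
    hn = 0
    node_s = np.zeros(4 * m)
    node_b = np.zeros(4 * m)
    has = np.zeros(4 * m, dtype=np.bool_)
    ok = True
    for j in range(m):
        L = upper[j] - d
        U = lower[j] + d
        e = _lichao_query(node_s, node_b, has, t, j, m)
        env[j] = e
        val = L if L > e else e
        if val > U + 1e-13:
            ok = False
        feas[j] = ok
        # minimal slope a feasible fit must carry out of point j: steepest
        # line from (t_j, L_j) back to a band ceiling (t_a, U_a), floored at 0
        s = 0.0
        if hn > 0:
            lo_i, hi_i = 0, hn - 1
            while lo_i < hi_i:
                mid = (lo_i + hi_i) // 2
                s1 = (L - hy[mid]) / (t[j] - hx[mid])
                s2 = (L - hy[mid + 1]) / (t[j] - hx[mid + 1])
                if s2 > s1:
                    lo_i = mid + 1
                else:
                    hi_i = mid
            s = (L - hy[lo_i]) / (t[j] - hx[lo_i])
            if s < 0.0:
                s = 0.0
        _lichao_insert(node_s, node_b, has, t, 1, 0, m - 1, s, L - s * t[j])
        # push band ceiling onto the lower convex hull of ceilings
        while hn >= 2:
            x1, y1 = hx[hn - 2], hy[hn - 2]
            x2, y2 = hx[hn - 1], hy[hn - 1]
            if (y2 - y1) * (t[j] - x1) >= (U - y1) * (x2 - x1):
                hn -= 1
            else:
                break
        hx[hn] = t[j]
        hy[hn] = U
        hn += 1


@njit(cache=True)
def _feasible(t, lower, upper, d):
    m = t.size
    feasP = np.empty(m, dtype=np.bool_)
    envA = np.empty(m)
    _convex_sweep(t, lower, upper, d, feasP, envA)
    # mirrored sweep handles the concave side: x -> -x, y -> 1 - y
    tm = -t[::-1].copy()
    lowm = 1.0 - upper[::-1]
    upm = 1.0 - lower[::-1]
    feasM = np.empty(m, dtype=np.bool_)
    envM = np.empty(m)
    _convex_sweep(tm, lowm, upm, d, feasM, envM)
    feasS = feasM[::-1].copy()     # feasS[j]: concave fit over points >= j
    Hext = np.empty(m)             # max concave-fit value at t_j, points > j
    for j in range(m):
        e = envM[m - 1 - j]
        Hext[j] = _POS if e <= _NEG else 1.0 - e

    tol = 1e-13
    # gap placements: mode strictly between t[k-1] and t[k]
    for k in range(m + 1):
        if k > 0 and not feasP[k - 1]:
            break  # prefixes only get harder
        if k < m and not feasS[k]:
            continue
        if 0 < k < m:
            e_ext = envA[k]
            fl = upper[k - 1] - d
            if fl > e_ext:
                e_ext = fl
            h_own = lower[k] + d
            h2 = Hext[k] if k == m - 1 else min(Hext[k], lower[k + 1] + d)
            if h2 < h_own:
                h_own = h2
            branch1 = e_ext <= h_own + tol
            e_own = upper[k - 1] - d
            if envA[k - 1] > e_own:
                e_own = envA[k - 1]
            h_ext = min(Hext[k - 1], lower[k] + d)
            branch2 = e_own <= h_ext + tol
            if not (branch1 or branch2):
                continue
        return True
    # point placements: mode at t[p], jump allowed there
    for p in range(m):
        if p > 0 and not feasP[p - 1]:
            break
        if p < m - 1 and not feasS[p + 1]:
            continue
        e_ext = _NEG
        if p > 0:
            e_ext = envA[p]
            fl = upper[p - 1] - d
            if fl > e_ext:
                e_ext = fl
            if e_ext > lower[p] + d + tol:
                continue
        h_ext = _POS
        if p < m - 1:
            h_ext = min(Hext[p], lower[p + 1] + d)
            if h_ext < upper[p] - d - tol:
                continue
        a = max(lower[p] - d, e_ext)
        b = min(upper[p] + d, h_ext)
        if a <= b + tol:
            return True
    return False


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan's dip of the empirical CDF of ``sample`` (unscaled).

    Returns 0.0 for samples with fewer than two distinct values (a single
    atom is itself unimodal).
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size == 0:
        raise ValueError("dip_statistic requires a non-empty sample")
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample contains non-finite values")

    ux, cum = empirical_cdf(sample)
    m = ux.size
    if m < 2:
        return 0.0
    upper = cum
    lower = np.concatenate(([0.0], cum[:-1]))

    lo, hi = 0.0, 0.25
    if _feasible(ux, lower, upper, lo):
        return 0.0
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if _feasible(ux, lower, upper, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
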