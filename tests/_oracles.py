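"""Independent oracles used by the test-suite.

Each reimplements a quantity from first principles (enumeration, closed
form, or direct optimisation of the defining problem) without touching the
package's own computational path.
"""

import itertools

import numpy as np
from scipy import stats
from scipy.optimize import linprog


def mann_whitney_enum(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments
    (no ties, n1+n2 small)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = x.size, pooled.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([ranks[list(c)].sum() - n1 * (n1 + 1) / 2
                   for c in itertools.combinations(range(n), n1)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def chi2_direct(table):
    """Pearson chi-squared by direct sum of (O-E)^2/E."""
    table = np.asarray(table, float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def partial_corr_first_order(x, y, z):
    """Closed-form first-order partial correlation on average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))


def slope_t_direct(s1, e1, n1, s2, e2, n2):
    """Slope-contrast t by direct evaluation of the defining formula."""
    t = (s1 - s2) / np.sqrt(e1 ** 2 + e2 ** 2)
    return t, n1 + n2 - 4


# ---------------------------------------------------------------------------
# Dip oracle: minimise sup|F - G| over unimodal G by solving, for every
# candidate mode placement (at a data location, or on a grid over each gap
# between locations), the linear program in the CDF values with
# convexity/concavity, monotonicity, tube and junction constraints.

def _lp(c, A, ub, nv):
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(ub),
                  bounds=[(None, None)] * (nv - 1) + [(0, None)],
                  method="highs")
    return res.fun if res.success else np.inf


def _rows_convex(le, idx, xs, sign=1.0):
    for i in range(len(xs) - 2):
        x1, x2, x3 = xs[i], xs[i + 1], xs[i + 2]
        if x3 - x2 <= 0 or x2 - x1 <= 0:
            continue
        c1 = 1.0 / (x2 - x1)
        c2 = -1.0 / (x2 - x1) - 1.0 / (x3 - x2)
        c3 = 1.0 / (x3 - x2)
        le([(idx[i], -sign * c1), (idx[i + 1], -sign * c2),
            (idx[i + 2], -sign * c3)], 0.0)


def _solve_gap(xs, a, b, s, m):
    """Mode at position m inside the gap [xs[s-1], xs[s]]."""
    J = len(xs)
    nv = J + 3
    iv, ip, it = J, J + 1, J + 2
    A, ub = [], []

    def le(coefs, rhs):
        row = np.zeros(nv)
        for i, c in coefs:
            row[i] += c
        A.append(row)
        ub.append(rhs)

    for i in range(J):
        le([(i, 1.0), (it, -1.0)], a[i])
        le([(i, -1.0), (it, -1.0)], -b[i])
    for i in range(J - 1):
        if i != s - 1:
            le([(i, 1.0), (i + 1, -1.0)], 0.0)
    le([(s - 1, 1.0), (iv, -1.0)], 0.0)
    le([(iv, 1.0), (ip, -1.0)], 0.0)
    le([(ip, 1.0), (s, -1.0)], 0.0)
    le([(iv, 1.0), (it, -1.0)], b[s - 1])
    le([(iv, -1.0), (it, -1.0)], -b[s - 1])
    le([(ip, 1.0), (it, -1.0)], b[s - 1])
    _rows_convex(le, list(range(s)) + [iv],
                 [xs[i] for i in range(s)] + [m])
    _rows_convex(le, [ip] + list(range(s, J)),
                 [m] + [xs[i] for i in range(s, J)], sign=-1.0)
    c = np.zeros(nv)
    c[it] = 1.0
    return _lp(c, A, ub, nv)


def _solve_at_location(xs, a, b, j):
    """Mode (atom) exactly at data location j."""
    J = len(xs)
    nv = J + 2
    ivl, it = J, J + 1
    A, ub = [], []

    def le(coefs, rhs):
        row = np.zeros(nv)
        for i, c in coefs:
            row[i] += c
        A.append(row)
        ub.append(rhs)

    for i in range(J):
        le([(i, 1.0), (it, -1.0)], b[i] if i == j else a[i])
        le([(i, -1.0), (it, -1.0)], -b[i])
    le([(ivl, 1.0), (it, -1.0)], a[j])
    le([(ivl, -1.0), (it, -1.0)], -a[j])
    for i in range(J - 1):
        if i != j - 1:
            le([(i, 1.0), (i + 1, -1.0)], 0.0)
    if j >= 1:
        le([(j - 1, 1.0), (ivl, -1.0)], 0.0)
    le([(ivl, 1.0), (j, -1.0)], 0.0)
    _rows_convex(le, list(range(j)) + [ivl],
                 [xs[i] for i in range(j)] + [xs[j]])
    _rows_convex(le, list(range(j, J)), [xs[i] for i in range(j, J)],
                 sign=-1.0)
    c = np.zeros(nv)
    c[it] = 1.0
    return _lp(c, A, ub, nv)


def _solve_pure(xs, a, b, concave):
    """Mode outside the data range (whole chain convex or concave)."""
    J = len(xs)
    nv = J + 1
    it = J
    A, ub = [], []

    def le(coefs, rhs):
        row = np.zeros(nv)
        for i, c in coefs:
            row[i] += c
        A.append(row)
        ub.append(rhs)

    for i in range(J):
        le([(i, 1.0), (it, -1.0)], a[i])
        le([(i, -1.0), (it, -1.0)], -b[i])
    for i in range(J - 1):
        le([(i, 1.0), (i + 1, -1.0)], 0.0)
    _rows_convex(le, list(range(J)), list(xs),
                 sign=-1.0 if concave else 1.0)
    c = np.zeros(nv)
    c[it] = 1.0
    return _lp(c, A, ub, nv)


def dip_lp_oracle(values, grid=16, refine=2):
    """Dip by direct optimisation of the defining problem (slow; small n)."""
    x = np.sort(np.asarray(values, float))
    n = x.size
    xs, counts = np.unique(x, return_counts=True)
    J = xs.size
    if J == 1:
        return 0.0
    cum = np.cumsum(counts)
    b = cum / n
    a = (cum - counts) / n

    best = min(_solve_pure(xs, a, b, False), _solve_pure(xs, a, b, True))
    for j in range(J):
        best = min(best, _solve_at_location(xs, a, b, j))
    for s in range(1, J):
        ms = list(np.linspace(xs[s - 1], xs[s], grid))
        vals = {m: _solve_gap(xs, a, b, s, m) for m in ms}
        for _ in range(refine):
            mbest = min(vals, key=vals.get)
            idx = ms.index(mbest)
            lo = ms[max(0, idx - 1)]
            hi = ms[min(len(ms) - 1, idx + 1)]
            ms = sorted(set(ms) | set(np.linspace(lo, hi, grid)))
            for m in ms:
                if m not in vals:
                    vals[m] = _solve_gap(xs, a, b, s, m)
        best = min(best, min(vals.values()))
    return best
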