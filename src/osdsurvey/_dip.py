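"""Hartigan-Hartigan dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to a mode, concave after it, with an
atom permitted at the mode).  It is computed with the classical
modal-interval refinement: working in count units, the greatest convex
minorant (GCM) of the empirical CDF touches the lower step corners
``(x_j, j-1)`` and the least concave majorant (LCM) the upper corners
``(x_j, j)``.  Each cycle finds the largest vertical separation ``d``
between the two hulls on the current interval, shrinks the interval to
where that separation occurs, and accrues the one-sided fit errors of the
hulls outside the new interval; the dip is half the final maximum, scaled
by ``1/n``.  The iteration terminates because the candidate modal interval
strictly shrinks.

The implementation is exercised in the test-suite against an independent
linear-programming formulation of the defining minimisation (nearest
convex-concave CDF, with the mode swept over data points and the gaps
between them).

Bounds: ``1/(2n) <= dip <= 1/4`` for samples with at least two distinct
values; a constant sample (a point mass is unimodal) has dip 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue_bootstrap"]


def dip_statistic(values) -> float:
    """Dip statistic of a 1-d sample.

    Parameters
    ----------
    values : array-like
        Sample values; ties are allowed.

    Returns
    -------
    float
        The dip, in [0, 0.25].
    """
    xs = np.sort(np.asarray(values, dtype=float).ravel())
    n = xs.size
    if n == 0:
        raise ValueError("empty sample")
    if n < 2 or xs[0] == xs[-1]:
        return 0.0
    x = np.empty(n + 1)
    x[1:] = xs  # 1-based indexing below

    # mn[j]: previous touchpoint of the GCM of the prefix ending at j;
    # mj[k]: next touchpoint of the LCM of the suffix starting at k.
    mn = np.empty(n + 1, dtype=np.int64)
    mj = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or ((x[j] - x[mnj]) * (mnj - mnmnj)
                            < (x[mnj] - x[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or ((x[k] - x[mjk]) * (mjk - mjmjk)
                            < (x[mjk] - x[mjmjk]) * (k - mjk)):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; the result is dip / (2n)
    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)
    for _cycle in range(n + 1):
        # GCM touchpoints from high down to low; LCM from low up to high.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i

        # Largest vertical separation d between the hulls on [low, high];
        # (ig, ih) mark the chord/touchpoint pair where it occurs.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            ix, iv = l_gcm - 1, 2
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next event: an LCM touchpoint under a GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - \
                        (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / \
                        (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next event: a GCM touchpoint over an LCM chord
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / \
                        (x[lcmiv] - x[lcmiv1]) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # One-sided fit errors of the hulls outside the new modal interval:
        # empirical CDF above the GCM on [low, gcm[ig]] ...
        dl = 0.0
        if ig != l_gcm:
            for j in range(ig, l_gcm):
                temp = 1.0
                jb = gcm[j + 1]
                je = gcm[j]
                if je - jb > 1 and x[je] != x[jb]:
                    C = (je - jb) / (x[je] - x[jb])
                    for jj in range(jb, je + 1):
                        tt = (jj - jb + 1) - (x[jj] - x[jb]) * C
                        if temp < tt:
                            temp = tt
                if dl < temp:
                    dl = temp
        # ... and below the LCM on [lcm[ih], high].
        du = 0.0
        if ih != l_lcm:
            for j in range(ih, l_lcm):
                temp = 1.0
                jb = lcm[j]
                je = lcm[j + 1]
                if je - jb > 1 and x[je] != x[jb]:
                    C = (je - jb) / (x[je] - x[jb])
                    for jj in range(jb, je + 1):
                        tt = (x[jj] - x[jb]) * C - (jj - jb - 1)
                        if temp < tt:
                            temp = tt
                if du < temp:
                    du = temp

        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            # no further shrink possible; the interior separation itself
            # bounds the fit
            if dip < d:
                dip = d
            break
        low = gcm[ig]
        high = lcm[ih]
    return float(dip / (2.0 * n))


def dip_pvalue_bootstrap(dip: float, n: int, reps: int,
                         rng: np.random.Generator) -> float:
    """Bootstrap p-value: share of uniform samples of size n whose dip is
    at least as large as the observed one."""
    count = 0
    for _ in range(reps):
        if dip_statistic(rng.random(n)) >= dip:
            count += 1
    return count / reps
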