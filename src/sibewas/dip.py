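"""Hartigan & Hartigan dip statistic and its Monte-Carlo p-value.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (a function that is convex up to some mode and
concave after it).  A large dip indicates that no unimodal distribution fits
the sample well, i.e. the sample looks multi-modal.  The statistic is bounded
by 1/4, attained by two equal point masses, and its minimum for an n-point
sample is 1/(2n).

The computation follows the classical O(n) algorithm: maintain a candidate
modal interval [low, high], fit the greatest convex minorant (GCM) below it
and the least concave majorant (LCM) above it, and shrink the interval until
the largest ECDF deviation inside equals the deviation outside.

Significance is assessed against samples from the uniform distribution, the
unimodal null with the stochastically largest dip, which makes the test
conservative for any other unimodal data-generating law.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_test_pvalue"]


class InsufficientDataError(ValueError):
    """Raised when a computation receives fewer observations than it needs."""


def dip_statistic(values) -> float:
    """Dip statistic of a 1-d sample.

    Parameters
    ----------
    values : array-like
        Sample of at least 4 numbers; sorted internally.

    Returns
    -------
    float
        The dip, in (0, 0.25].  Affine transforms of the data leave it
        unchanged; an all-tied sample returns the minimum 1/(2n).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 4:
        raise InsufficientDataError(
            f"dip statistic needs at least 4 observations, got {x.size}"
        )
    x = np.sort(x)
    return _dip_sorted(x)


def _dip_sorted(x: np.ndarray) -> float:
    """Dip of an already-sorted float64 vector (core algorithm)."""
    n = x.size
    low, high = 0, n - 1
    dip = 1.0  # on the n*dip scale until the final division
    if x[high] == x[low]:
        return 0.5 / n

    # Pointers for the greatest convex minorant: mn[j] is the previous index
    # retained on the convex hull when scanning left to right.
    mn = np.empty(n, dtype=np.intp)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj

    # Pointers for the least concave majorant, scanning right to left.
    mj = np.empty(n, dtype=np.intp)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (
                k - mjk
            ):
                break
            mj[k] = mjmjk

    gcm = np.empty(n, dtype=np.intp)
    lcm = np.empty(n, dtype=np.intp)

    while True:
        # Change points of the GCM from high down to low.
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1

        # Change points of the LCM from low up to high.
        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 1

        # Largest separation between GCM and LCM inside [low, high].
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d <= dip:
            break

        # Deviation of the ECDF below the GCM on [gcm[ig], low..].
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Deviation of the ECDF above the LCM on [.., lcm[ih], high].
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2 * n)


@lru_cache(maxsize=8)
def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    """Sorted dips of n_boot uniform(0,1) samples of size n (cached)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        out[b] = _dip_sorted(np.sort(rng.random(n)))
    out.sort()
    return out


def dip_test_pvalue(dip: float, n: int, n_boot: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo p-value of an observed dip under the uniform null.

    p = (b + 1) / (n_boot + 1) where b counts uniform samples of size ``n``
    whose dip is at least the observed one (add-one smoothing keeps p > 0).
    The uniform null distribution is cached per (n, n_boot, seed), so scans
    over many sites of equal sample size pay the simulation cost once.
    """
    if dip < 0:
        raise ValueError(f"dip must be non-negative, got {dip}")
    if n < 4:
        raise InsufficientDataError(f"dip test needs n >= 4, got n={n}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    null = _null_dips(int(n), int(n_boot), int(seed))
    b = null.size - np.searchsorted(null, dip, side="left")
    return (b + 1) / (n_boot + 1)
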