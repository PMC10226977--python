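"""Compiled hot loops for the sampler's likelihood gradient.

The HMC gradient is evaluated hundreds of thousands of times per fit; the
dominant cost is evaluating the monotone spline basis (and its derivative)
at every observation's shifted age and accumulating per-parameter
gradients.  This module does that in one numba pass using the Cox-de Boor
recurrence (basis values and first derivatives from the classic ndu-table
algorithm), exploiting that a cubic B-spline row has only four nonzero
entries and that the I-spline row is its right tail sum.

Results agree with the numpy/scipy path in ``splines.MonotoneBasis`` to
machine precision (asserted in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _basis_and_deriv(x, knots, p, bvals, dvals):
    """Nonzero B-spline values/derivatives at x; returns the knot span i.

    Writes the p+1 nonzero basis values into ``bvals`` and their first
    derivatives into ``dvals``; the nonzero B-spline indices are
    i-p .. i.
    """
    nb = knots.shape[0] - p - 1
    i = np.searchsorted(knots, x, side="right") - 1
    if i < p:
        i = p
    if i > nb - 1:
        i = nb - 1
    left = np.empty(p + 1)
    right = np.empty(p + 1)
    ndu = np.empty((p + 1, p + 1))
    ndu[0, 0] = 1.0
    for j in range(1, p + 1):
        left[j] = x - knots[i + 1 - j]
        right[j] = knots[i + j] - x
        saved = 0.0
        for r in range(j):
            ndu[j, r] = right[r + 1] + left[j - r]
            temp = ndu[r, j - 1] / ndu[j, r]
            ndu[r, j] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        ndu[j, j] = saved
    for r in range(p + 1):
        bvals[r] = ndu[r, p]
        d = 0.0
        if r > 0:
            d += ndu[r - 1, p - 1] / ndu[p, r - 1]
        if r < p:
            d -= ndu[r, p - 1] / ndu[p, r]
        dvals[r] = p * d
    return i


@njit(cache=True)
def likelihood_accumulate(
    t, y, mk, part, knots, p, lo, hi,
    w, c, sigma,
    dc, dW, G, rss,
):
    """Gaussian log likelihood plus gradient accumulators, in one pass.

    Parameters are the flat observation arrays (shifted age ``t``,
    standardized response ``y``, marker index ``mk``, participant index
    ``part``), the clamped knot vector, curve weights ``w`` (K, nb) and
    intercepts ``c``, and residual SDs ``sigma``.  Outputs (zeroed by the
    caller): ``dc`` (K,) sum of r; ``dW`` (K, nb) sum of r * I_row;
    ``G`` (n, K) sum of r * g'; ``rss`` (K,) residual sum of squares.
    Returns the log likelihood (constants included).
    """
    N = t.shape[0]
    K = c.shape[0]
    nb_total = knots.shape[0] - p - 1
    nbasis = nb_total - 1
    bvals = np.empty(p + 1)
    dvals = np.empty(p + 1)
    sb = np.empty(p + 1)       # suffix sums of bvals
    sd = np.empty(p + 1)
    LOG2PI = 1.8378770664093453
    loglik = 0.0
    # prefix sums of weights: wpre[k, j] = sum of w[k, :j]
    wpre = np.zeros((K, nbasis + 1))
    for k in range(K):
        acc = 0.0
        for j in range(nbasis):
            acc += w[k, j]
            wpre[k, j + 1] = acc
    # "add r to dW[k, 0..b]" accumulator, resolved in a post-pass
    ones_add = np.zeros((K, nbasis))
    for o in range(N):
        k = mk[o]
        x = t[o]
        if x < lo:
            mu = c[k]
            gp = 0.0
            full = -1       # number of leading I=1 basis functions, minus 1
            i = -1
        elif x >= hi:
            mu = c[k] + wpre[k, nbasis]
            gp = 0.0
            full = nbasis - 1
            i = -1
        else:
            i = _basis_and_deriv(x, knots, p, bvals, dvals)
            acc_b = 0.0
            acc_d = 0.0
            for m in range(p, -1, -1):
                acc_b += bvals[m]
                acc_d += dvals[m]
                sb[m] = acc_b
                sd[m] = acc_d
            # I-basis index jj maps to B-spline index jj+1; indices
            # <= i-p-1 are saturated (I=1), i-p .. i-1 are partial tails
            full = i - p - 1
            mu = c[k] + wpre[k, full + 1]
            gp = 0.0
            for m in range(1, p + 1):
                jj = i - p + m - 1
                if jj < nbasis:
                    mu += w[k, jj] * sb[m]
                    gp += w[k, jj] * sd[m]
        s = sigma[k]
        resid = y[o] - mu
        loglik += -0.5 * LOG2PI - np.log(s) - 0.5 * (resid / s) ** 2
        r = resid / (s * s)
        dc[k] += r
        rss[k] += resid * resid
        if full >= 0:
            ones_add[k, full] += r
        if i >= 0:
            for m in range(1, p + 1):
                jj = i - p + m - 1
                if jj < nbasis:
                    dW[k, jj] += r * sb[m]
        G[part[o], k] += r * gp
    # resolve the saturated-region contributions: dW[k, j] += sum of
    # ones_add[k, b] over b >= j
    for k in range(K):
        acc = 0.0
        for j in range(nbasis - 1, -1, -1):
            acc += ones_add[k, j]
            dW[k, j] += acc
    return loglik
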