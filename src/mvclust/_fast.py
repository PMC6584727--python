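"""Exhaustive Bayes-risk scan for the known-parameter two-cluster case.

With known per-cluster parameters the labeling likelihood factorizes over
points, so the posterior over size-constrained reference bipartitions is a
function of per-point log-likelihood-ratio sums.  Writing a bipartition as
a +/-1 membership vector b, the partition cost between candidate a and
reference b is 1/2 - |a.b| / (2n), hence

    risk(a) = 1/2 - E_b |a.b| / (2n).

|a.b| depends on a reference block B only through k = |B intersect P| where
P = {x : a_x = +1}, so the posterior expectation collapses to a sum over k
weighted by elementary symmetric polynomials (ESP) of the per-point
likelihood ratios e^{delta_x}, split over P and its complement.  The kernel
scans all 2^(n-1) candidate sign vectors exactly, reusing ESP prefix state
across candidates that share a prefix (binary-counter order), in log space
throughout.  This reproduces plain enumeration exactly (same minimizer,
same risk) and is cross-checked against it in the test suite.
"""

import numpy as np
from numba import njit

NEG = -1.0e300


@njit(cache=True, inline="always")
def _lae(a, b):
    """log(exp(a) + exp(b)), branchy and -inf safe."""
    if a < b:
        a, b = b, a
    if b < a - 45.0 or b <= NEG:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def log_esp(logu, kmax):
    """Log elementary symmetric polynomials e_0..e_kmax of {exp(logu_i)}."""
    e = np.full(kmax + 1, NEG)
    e[0] = 0.0
    cnt = 0
    for i in range(logu.shape[0]):
        cnt += 1
        top = min(cnt, kmax)
        for k in range(top, 0, -1):
            e[k] = _lae(e[k], e[k - 1] + logu[i])
    return e


@njit(cache=True)
def optimal_scan(delta, T1, T2, n1, equal_sizes):
    """Exact risk minimization over all 2^(n-1) candidate bipartitions.

    delta[x]   log-likelihood ratio of point x (label 1 minus label 2)
    T1, T2     sum of per-point log densities under labels 1 and 2
    n1         block size defining the reference set (partitions with block
               sizes {n1, n-n1})
    equal_sizes  True when n1 == n - n1 (single-orientation weights; each
               partition is then visited via both subset orientations)

    Returns (best_phi, ties, n_ties) where best_phi = E|a.b| for the best
    candidate (risk = 1/2 - best_phi / (2n)) and ties holds candidate codes
    (bit j set => point n-1-j in the negative block; point 0 always
    positive) whose objective ties the best to within 1e-12 relative.
    """
    n = delta.shape[0]
    n2 = n - n1
    # log Z over the full reference set
    eu = log_esp(delta, n1)
    if equal_sizes:
        logZ = T2 + eu[n1]
    else:
        einv = log_esp(-delta, n1)
        logZ = _lae(T2 + eu[n1], T1 + einv[n1])

    # depth-indexed ESP state; state[d] covers points 0..d-1
    espP = np.full((n + 1, n1 + 1), NEG)
    espC = np.full((n + 1, n1 + 1), NEG)
    espPi = np.full((n + 1, n1 + 1), NEG)
    espCi = np.full((n + 1, n1 + 1), NEG)
    cntP = np.zeros(n + 1, dtype=np.int64)
    espP[0, 0] = 0.0
    espC[0, 0] = 0.0
    espPi[0, 0] = 0.0
    espCi[0, 0] = 0.0

    ncand = 1 << (n - 1)
    best = -1.0
    ties = np.zeros(64, dtype=np.int64)
    n_ties = 0
    prev = np.int64(-1)
    for c in range(ncand):
        if c == 0:
            start = 0
        else:
            x = np.int64(c - 1) ^ np.int64(c)
            h = 0
            while (x >> (h + 1)) != 0:
                h += 1
            start = n - 1 - h
        for pt in range(start, n):
            # copy previous depth
            for k in range(n1 + 1):
                espP[pt + 1, k] = espP[pt, k]
                espC[pt + 1, k] = espC[pt, k]
                if not equal_sizes:
                    espPi[pt + 1, k] = espPi[pt, k]
                    espCi[pt + 1, k] = espCi[pt, k]
            if pt == 0:
                neg = False
            else:
                neg = ((c >> (n - 1 - pt)) & 1) == 1
            v = delta[pt]
            if neg:
                cntP[pt + 1] = cntP[pt]
                top = min(pt + 1 - cntP[pt + 1], n1)
                for k in range(top, 0, -1):
                    espC[pt + 1, k] = _lae(espC[pt + 1, k], espC[pt + 1, k - 1] + v)
                    if not equal_sizes:
                        espCi[pt + 1, k] = _lae(
                            espCi[pt + 1, k], espCi[pt + 1, k - 1] - v
                        )
            else:
                cntP[pt + 1] = cntP[pt] + 1
                top = min(cntP[pt + 1], n1)
                for k in range(top, 0, -1):
                    espP[pt + 1, k] = _lae(espP[pt + 1, k], espP[pt + 1, k - 1] + v)
                    if not equal_sizes:
                        espPi[pt + 1, k] = _lae(
                            espPi[pt + 1, k], espPi[pt + 1, k - 1] - v
                        )
        p = cntP[n]
        Sa = 2 * p - n
        phi = 0.0
        klo = n1 - (n - p)
        if klo < 0:
            klo = 0
        khi = n1 if n1 < p else p
        for k in range(klo, khi + 1):
            coef = 2 * (2 * k - n1) - Sa
            if coef < 0:
                coef = -coef
            if coef == 0:
                continue
            a = T2 + espP[n, k] + espC[n, n1 - k] - logZ
            if a > -45.0:
                phi += coef * np.exp(a)
            if not equal_sizes:
                b = T1 + espPi[n, k] + espCi[n, n1 - k] - logZ
                if b > -45.0:
                    phi += coef * np.exp(b)
        tol = 1e-12 * (1.0 if best < 1.0 else best)
        if phi > best + tol:
            best = phi
            ties[0] = c
            n_ties = 1
        elif phi >= best - tol and n_ties < 64:
            ties[n_ties] = c
            n_ties += 1
    return best, ties, n_ties
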