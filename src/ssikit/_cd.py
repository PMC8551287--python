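"""Numba coordinate-descent kernel for the L1-penalized selection index.

Solves, along a descending penalty grid with warm starts,

    min_b  0.5 b' C b  -  g' b  +  lam * sum_j |b_j|

for a single prediction individual (C = K_TS + lambda0*I, g = similarities
to the training set).  The residual r = g - C b is maintained incrementally;
after the active-set iterations converge, one full sweep verifies the KKT
conditions before moving to the next penalty.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _sweep(C, b, r, lam, active_only):
    n = b.shape[0]
    max_delta = 0.0
    for j in range(n):
        if active_only and b[j] == 0.0:
            continue
        cjj = C[j, j]
        z = r[j] + cjj * b[j]
        if z > lam:
            bn = (z - lam) / cjj
        elif z < -lam:
            bn = (z + lam) / cjj
        else:
            bn = 0.0
        d = bn - b[j]
        if d != 0.0:
            for t in range(n):
                r[t] -= C[t, j] * d
            b[j] = bn
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=False)
def cd_path(C, g, lambdas, tol, max_iter):
    """Coefficients for each penalty in ``lambdas`` (descending), warm-started.

    Returns (B, n_sweeps, converged) where B is (n_lambda, n) and
    ``converged[li]`` is False when the sweep budget was exhausted.
    """
    n = g.shape[0]
    nl = lambdas.shape[0]
    B = np.zeros((nl, n))
    sweeps = np.zeros(nl, np.int64)
    ok = np.ones(nl, np.bool_)
    b = np.zeros(n)
    r = g.copy()
    for li in range(nl):
        lam = lambdas[li]
        it = 0
        done = False
        while it < max_iter:
            delta = _sweep(C, b, r, lam, False)
            it += 1
            if delta < tol:
                done = True
                break
            while it < max_iter:
                delta = _sweep(C, b, r, lam, True)
                it += 1
                if delta < tol:
                    break
        sweeps[li] = it
        ok[li] = done
        B[li] = b
    return B, sweeps, ok
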