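"""Numba coordinate-descent kernels for weighted LASSO.

Objective: (1/2n) ||y - X beta||^2 + lambda * sum_j w_j |beta_j|, with
w_j = 0 for penalty-exempt columns. Updates use precomputed Gram quantities
G = X'X / n and c = X'y / n, so each coordinate update is O(p) regardless of
the sample size and path fits warm-start cheaply.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def soft_threshold(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def cd_gram(G, c, lam, w, beta, tol, max_iter):
    """Cyclic coordinate descent on the Gram form. Modifies beta in place.

    Returns the number of sweeps used; ``max_iter + 1`` signals
    non-convergence.
    """
    p = G.shape[0]
    Gb = G @ beta
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            if G[j, j] <= 0.0:
                continue
            b_old = beta[j]
            rho = c[j] - Gb[j] + G[j, j] * b_old
            if w[j] > 0.0:
                b_new = soft_threshold(rho, lam * w[j]) / G[j, j]
            else:
                b_new = rho / G[j, j]
            d = b_new - b_old
            if d != 0.0:
                beta[j] = b_new
                for k in range(p):
                    Gb[k] += G[k, j] * d
                if abs(d) > max_change:
                    max_change = abs(d)
        if max_change < tol:
            return it + 1
    return max_iter + 1


@njit(cache=False)
def cd_path(G, c, lams, w, tol, max_iter):
    """Warm-started solutions along a decreasing lambda path.

    Returns (betas K x p, iters K)."""
    K, p = lams.shape[0], G.shape[0]
    betas = np.zeros((K, p))
    beta = np.zeros(p)
    iters = np.zeros(K, dtype=np.int64)
    for k in range(K):
        iters[k] = cd_gram(G, c, lams[k], w, beta, tol, max_iter)
        betas[k] = beta
    return betas, iters
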