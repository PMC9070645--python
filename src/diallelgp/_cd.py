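"""Numba kernels for cyclic coordinate descent on the penalized least-squares
objective (1/2n)||y - b0 - X beta||^2 + lambda * P(beta), with Gram ("covariance")
updates: the kernels work on G = X'X/n and c = X'y/n only."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_gram(G, c, lam, l1, beta, tol, max_sweeps):
    """One penalized fit by cyclic coordinate descent on the Gram system.

    l1=True soft-thresholds (LASSO penalty lambda*||beta||_1); l1=False is the
    ridge penalty (lambda/2)*||beta||^2. ``beta`` is the warm start (modified in
    place). Returns (sweeps used, converged flag).
    """
    p = G.shape[0]
    r = c - G @ beta
    for sweep in range(max_sweeps):
        maxd = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = r[j] + gjj * beta[j]
            if l1:
                if rho > lam:
                    new = (rho - lam) / gjj
                elif rho < -lam:
                    new = (rho + lam) / gjj
                else:
                    new = 0.0
            else:
                new = rho / (gjj + lam)
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                for i in range(p):
                    r[i] -= G[i, j] * d
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        if maxd < tol:
            return sweep + 1, True
    return max_sweeps, False


@njit(cache=True)
def cd_path(G, c, lambdas, l1, tol, max_sweeps):
    """Pathwise fits over a descending lambda grid with warm starts."""
    p = G.shape[0]
    betas = np.zeros((lambdas.size, p))
    beta = np.zeros(p)
    ok = True
    for t in range(lambdas.size):
        _, conv = cd_gram(G, c, lambdas[t], l1, beta, tol, max_sweeps)
        if not conv:
            ok = False
        betas[t] = beta
    return betas, ok
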