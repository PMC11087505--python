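"""Independent reference implementations used to check the EM path.

These deliberately avoid the package's vectorised likelihood/EM code:
the per-read oracle multiplies Bernoulli mixture probabilities one read at
a time, and the grid oracle maximises the likelihood by exhaustive search
over the probability simplex.
"""

import math

import numpy as np


def per_read_loglik(counts, mu, phi):
    """Log-likelihood as an explicit product over individual reads."""
    total = 0.0
    for i in range(counts.n_variants):
        p_alt = sum(phi[k] * mu[i, k] for k in range(len(phi)))
        p_ref = sum(phi[k] * (1.0 - mu[i, k]) for k in range(len(phi)))
        for _ in range(int(counts.a[i])):
            total += math.log(p_alt)
        for _ in range(int(counts.b[i])):
            total += math.log(p_ref)
    return total


def _loglik_batch(a, b, mu, P):
    """Log-likelihood for a batch of candidate phi vectors (rows of P)."""
    M = np.clip(mu @ P.T, 1e-12, 1 - 1e-12)   # (N, n_candidates)
    return a @ np.log(M) + b @ np.log1p(-M)


def grid_search_mle(counts, gm, theta, step=1e-3, refine=1e-4):
    """Exhaustive simplex maximiser of the pooled likelihood (K = 2 or 3)."""
    K = gm.n_donors
    mu = theta.as_array()[gm.G]
    a = counts.a.astype(float)
    b = counts.b.astype(float)
    if K == 2:
        best = _best_k2(a, b, mu, np.arange(0.0, 1.0 + step / 2, step))
        lo, hi = max(0.0, best - step), min(1.0, best + step)
        best = _best_k2(a, b, mu, np.arange(lo, hi + refine / 2, refine))
        return np.array([1.0 - best, best])
    if K == 3:
        best = _best_k3(a, b, mu, 0.0, 1.0, 0.0, 1.0, step)
        p1, p2 = best
        best = _best_k3(
            a, b, mu,
            max(0.0, p1 - step), min(1.0, p1 + step),
            max(0.0, p2 - step), min(1.0, p2 + step),
            refine,
        )
        p1, p2 = best
        return np.array([p1, p2, 1.0 - p1 - p2])
    raise NotImplementedError("grid oracle implemented for K in {2, 3}")


def _best_k2(a, b, mu, grid):
    P = np.column_stack([1.0 - grid, grid])
    ll = _loglik_batch(a, b, mu, P)
    return float(grid[np.argmax(ll)])


def _best_k3(a, b, mu, lo1, hi1, lo2, hi2, step):
    g1 = np.arange(lo1, hi1 + step / 2, step)
    g2 = np.arange(lo2, hi2 + step / 2, step)
    p1, p2 = np.meshgrid(g1, g2, indexing="ij")
    p1, p2 = p1.ravel(), p2.ravel()
    ok = p1 + p2 <= 1.0 + 1e-12
    p1, p2 = p1[ok], p2[ok]
    best_ll, best = -np.inf, (0.0, 0.0)
    for start in range(0, len(p1), 50_000):
        sl = slice(start, start + 50_000)
        P = np.column_stack([p1[sl], p2[sl], 1.0 - p1[sl] - p2[sl]])
        ll = _loglik_batch(a, b, mu, P)
        j = int(np.argmax(ll))
        if ll[j] > best_ll:
            best_ll = float(ll[j])
            best = (float(p1[sl][j]), float(p2[sl][j]))
    return best
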