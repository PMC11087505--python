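"""Binomial-mixture likelihood and EM estimation of donor proportions.

Model
-----
A pooled sample contains reads from K genotyped donors in unknown
proportions phi (a point on the K-simplex). At an effective SNP i, donor k's
expected ALT-read fraction is ``mu[i, k] = theta[g_ik]`` where ``g_ik`` is
the donor's genotype category (0/1/2) and theta the genotype-specific
ALT-allele fractions. Marginalising the (latent) donor of origin of each
read, the ALT count ``a_i`` out of depth ``d_i`` is binomial with success
probability ``mu_i . phi``, so up to the binomial coefficient (constant in
phi and theta, and omitted throughout)

    log L(phi, theta) = sum_i a_i log(mu_i . phi) + (d_i - a_i) log(1 - mu_i . phi).

The EM algorithm treats each read's donor of origin as the latent variable:
the E-step computes per-(SNP, allele-class) donor responsibilities, the
M-step re-estimates phi as the responsibility-weighted read mass per donor
and, in adaptive mode, theta as the ALT fraction of the read mass assigned
to each genotype category. Reads of the same allele class at one SNP are
exchangeable, so responsibilities are computed once per (SNP, class) and
weighted by the counts.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np

from .datatypes import (
    MISSING,
    AllelicCounts,
    AlleleFreqParams,
    DemuxError,
    FitResult,
    GenotypeMatrix,
    check_simplex,
    require_aligned,
)

__all__ = [
    "AlleleFreqParams",
    "FitResult",
    "donor_allele_means",
    "log_likelihood",
    "em_fit",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12
_THETA_CLIP = 1e-4
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


def donor_allele_means(gm: GenotypeMatrix, theta: AlleleFreqParams) -> np.ndarray:
    """Expected ALT-read fraction per (SNP, donor): ``mu[i,k] = theta[G[i,k]]``."""
    if np.any(gm.G == MISSING):
        raise DemuxError("genotype matrix contains missing calls; filter first")
    return theta.as_array()[gm.G]


def log_likelihood(
    counts: AllelicCounts, mu: np.ndarray, phi: np.ndarray
) -> float:
    """Pooled-sample log-likelihood (binomial coefficient omitted).

    ``mu . phi`` is clamped to [1e-12, 1 - 1e-12] if it strays outside
    (0, 1); rows with zero depth contribute nothing.
    """
    phi = check_simplex(phi)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (counts.n_variants, phi.shape[0]):
        raise DemuxError(
            f"mu shape {mu.shape} does not match {counts.n_variants} SNPs x "
            f"{phi.shape[0]} donors"
        )
    p = mu @ phi
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        logger.debug("log_likelihood: clamping mixture rate into (0, 1)")
        p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(counts.a @ np.log(p) + counts.b @ np.log1p(-p))


def em_fit(
    counts: AllelicCounts,
    gm: GenotypeMatrix,
    theta_mode: Literal["fixed", "adaptive"] = "fixed",
    theta0: AlleleFreqParams | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    phi0: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood donor proportions by expectation-maximisation.

    Parameters
    ----------
    counts, gm
        Effective-filtered pooled counts and aligned genotype matrix.
    theta_mode
        ``"fixed"`` keeps ``theta0``; ``"adaptive"`` re-estimates the
        genotype-specific ALT fractions each M-step (clipped to
        [1e-4, 1 - 1e-4] and re-sorted so theta0 < theta1 < theta2).
    tol
        Convergence threshold on the log-likelihood increase per iteration.
    phi0
        Starting proportions; default uniform 1/K.

    Returns
    -------
    :class:`FitResult` with the estimate, the (possibly updated) theta and a
    non-decreasing log-likelihood trace. Deterministic given its inputs.
    """
    require_aligned(gm, counts)
    theta = theta0 if theta0 is not None else AlleleFreqParams()
    K = gm.n_donors
    if K == 1:
        mu = donor_allele_means(gm, theta)
        phi = np.ones(1)
        ll = log_likelihood(counts, mu, phi)
        return FitResult(
            phi=phi, theta=theta, loglik_trace=np.array([ll]), n_iter=0,
            converged=True, donors=list(gm.donors),
        )
    if tol <= 0 or max_iter < 1:
        raise DemuxError("tol must be > 0 and max_iter >= 1")

    a = counts.a.astype(float)
    b = counts.b.astype(float)
    total = float(counts.d.sum())
    if total == 0:
        raise DemuxError("no reads in counts")
    G = gm.G
    mu = donor_allele_means(gm, theta)
    if phi0 is None:
        phi = np.full(K, 1.0 / K)
    else:
        # Zero entries are EM-absorbing; floor the start strictly inside
        # the simplex so every donor can gain mass.
        phi = np.clip(check_simplex(np.asarray(phi0)), 1e-6, None)
        phi = phi / phi.sum()

    trace = [log_likelihood(counts, mu, phi)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: donor responsibilities per SNP for ALT- and REF-class reads.
        num_a = phi * mu                    # (N, K)
        num_b = phi * (1.0 - mu)
        p = num_a.sum(axis=1)               # = mu @ phi
        q = num_b.sum(axis=1)
        r_a = num_a / np.clip(p, _EPS, None)[:, None]
        r_b = num_b / np.clip(q, _EPS, None)[:, None]

        # M-step: phi <- responsibility-weighted read mass per donor.
        w_a = a[:, None] * r_a
        w_b = b[:, None] * r_b
        phi = (w_a + w_b).sum(axis=0) / total
        phi = phi / phi.sum()               # guard rounding drift

        if theta_mode == "adaptive":
            theta = _update_theta(G, w_a, w_b, theta)
            mu = theta.as_array()[G]

        trace.append(log_likelihood(counts, mu, phi))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break

    if not converged:
        logger.warning("em_fit: no convergence after %d iterations", max_iter)
    return FitResult(
        phi=phi,
        theta=theta,
        loglik_trace=np.array(trace),
        n_iter=n_iter,
        converged=converged,
        donors=list(gm.donors),
    )


def _update_theta(
    G: np.ndarray, w_a: np.ndarray, w_b: np.ndarray, current: AlleleFreqParams
) -> AlleleFreqParams:
    """M-step for theta: ALT fraction of read mass per genotype category."""
    theta = np.array(current.theta, dtype=float)
    for t in range(3):
        mask = G == t
        alt_mass = w_a[mask].sum()
        tot_mass = alt_mass + w_b[mask].sum()
        if tot_mass > 0:
            theta[t] = alt_mass / tot_mass
    theta = np.clip(theta, _THETA_CLIP, 1.0 - _THETA_CLIP)
    resorted = np.sort(theta)
    if not np.array_equal(resorted, theta):
        logger.debug("_update_theta: re-sorted theta to keep ordering")
    # Strict ordering required by AlleleFreqParams; nudge exact ties apart.
    for t in (1, 2):
        if resorted[t] <= resorted[t - 1]:
            resorted[t] = min(resorted[t - 1] + _THETA_CLIP, 1.0 - _THETA_CLIP / 2)
    return AlleleFreqParams(theta=tuple(resorted))
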