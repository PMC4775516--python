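"""Numba kernel for the admixture-model Gibbs sampler.

The sampler follows the classic no-prior-information admixture model for
unlinked codominant loci: latent cluster origins Z for every allele copy,
per-individual ancestry Q ~ Dirichlet(alpha, ..., alpha) with alpha updated
by random-walk Metropolis under a uniform(0, 10) prior, and per-cluster
allele frequencies P with either an uncorrelated Dirichlet(1) prior or the
correlated-frequencies prior Dirichlet(pa * (1 - F_k) / F_k) around fixed
ancestral frequencies pa, with per-cluster drift F_k updated by
random-walk Metropolis under a uniform prior.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["admixture_chain"]


@njit(cache=True)
def _dirichlet(params, out):
    total = 0.0
    for i in range(params.shape[0]):
        g = np.random.gamma(params[i], 1.0)
        out[i] = g
        total += g
    if total <= 0.0:
        for i in range(params.shape[0]):
            out[i] = 1.0 / params.shape[0]
    else:
        for i in range(params.shape[0]):
            out[i] = out[i] / total
            if out[i] < 1e-12:
                out[i] = 1e-12


@njit(cache=True)
def _drift_logdensity(p_k, pa, n_alleles, f):
    """Log density (up to a constant) of cluster frequencies under the
    correlated prior with drift f."""
    c0 = (1.0 - f) / f
    total = 0.0
    n_loci = n_alleles.shape[0]
    for l in range(n_loci):
        total += math.lgamma(c0)
        for a in range(n_alleles[l]):
            c = pa[l, a] * c0
            total += (c - 1.0) * math.log(p_k[l, a]) - math.lgamma(c)
    return total


@njit(cache=True)
def admixture_chain(
    x,
    n_alleles,
    K,
    burn_in,
    reps,
    correlated,
    pa,
    alpha_init,
    alpha_step,
    f_step,
    seed,
):
    """Run one admixture-model chain.

    Parameters: ``x`` (n, L, 2) allele indices with -1 missing;
    ``n_alleles`` per-locus allele counts; ``pa`` (L, Amax) pooled
    (ancestral) frequencies used by the correlated prior.  ``reps``
    post-burn-in sweeps are recorded.

    Returns (q_mean, p_mean, loglik_trace, alpha_mean, drift_mean).
    """
    np.random.seed(seed)
    n, n_loci = x.shape[0], x.shape[1]
    a_max = pa.shape[1]
    total_sweeps = burn_in + reps

    q = np.full((n, K), 1.0 / K)
    p = np.empty((K, n_loci, a_max))
    for k in range(K):
        for l in range(n_loci):
            for a in range(a_max):
                p[k, l, a] = pa[l, a] if a < n_alleles[l] else 0.0
    z = np.zeros((n, n_loci, 2), dtype=np.int64)
    alpha = alpha_init
    drift = np.full(K, 0.1)

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, n_loci, a_max))
    ll_trace = np.empty(reps)
    alpha_sum = 0.0
    drift_sum = np.zeros(K)

    counts_ik = np.zeros((n, K))
    counts_kla = np.zeros((K, n_loci, a_max))
    w = np.empty(K)
    buf = np.empty(a_max)
    bufk = np.empty(K)

    for sweep in range(total_sweeps):
        # --- latent origins Z and the count tables -----------------------
        for i in range(n):
            for k in range(K):
                counts_ik[i, k] = 0.0
        for k in range(K):
            for l in range(n_loci):
                for a in range(a_max):
                    counts_kla[k, l, a] = 0.0
        loglik = 0.0
        for i in range(n):
            for l in range(n_loci):
                for c in range(2):
                    a = x[i, l, c]
                    if a < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        w[k] = q[i, k] * p[k, l, a]
                        tot += w[k]
                    loglik += math.log(tot)
                    u = np.random.random() * tot
                    acc = 0.0
                    kk = K - 1
                    for k in range(K):
                        acc += w[k]
                        if u <= acc:
                            kk = k
                            break
                    z[i, l, c] = kk
                    counts_ik[i, kk] += 1.0
                    counts_kla[kk, l, a] += 1.0
        # --- ancestry Q --------------------------------------------------
        for i in range(n):
            for k in range(K):
                bufk[k] = alpha + counts_ik[i, k]
            _dirichlet(bufk, bufk)
            for k in range(K):
                q[i, k] = bufk[k]
        # --- cluster frequencies P ---------------------------------------
        for k in range(K):
            if correlated:
                c0 = (1.0 - drift[k]) / drift[k]
            else:
                c0 = 0.0
            for l in range(n_loci):
                na = n_alleles[l]
                for a in range(na):
                    if correlated:
                        buf[a] = pa[l, a] * c0 + counts_kla[k, l, a]
                    else:
                        buf[a] = 1.0 + counts_kla[k, l, a]
                _dirichlet(buf[:na], buf[:na])
                for a in range(na):
                    p[k, l, a] = buf[a]
        # --- admixture parameter alpha -----------------------------------
        if K > 1:
            prop = alpha + np.random.normal() * alpha_step
            if 0.0 < prop < 10.0:
                slogq = 0.0
                for i in range(n):
                    for k in range(K):
                        slogq += math.log(q[i, k])
                cur = n * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) + (
                    alpha - 1.0
                ) * slogq
                new = n * (math.lgamma(K * prop) - K * math.lgamma(prop)) + (
                    prop - 1.0
                ) * slogq
                if math.log(np.random.random()) < new - cur:
                    alpha = prop
        # --- drift parameters (correlated model) --------------------------
        if correlated:
            for k in range(K):
                prop = drift[k] + np.random.normal() * f_step
                if 0.001 < prop < 0.999:
                    cur = _drift_logdensity(p[k], pa, n_alleles, drift[k])
                    new = _drift_logdensity(p[k], pa, n_alleles, prop)
                    if math.log(np.random.random()) < new - cur:
                        drift[k] = prop
        # --- record -------------------------------------------------------
        if sweep >= burn_in:
            idx = sweep - burn_in
            ll_trace[idx] = loglik
            alpha_sum += alpha
            for i in range(n):
                for k in range(K):
                    q_sum[i, k] += q[i, k]
            for k in range(K):
                drift_sum[k] += drift[k]
                for l in range(n_loci):
                    for a in range(a_max):
                        p_sum[k, l, a] += p[k, l, a]

    q_mean = q_sum / reps
    p_mean = p_sum / reps
    return q_mean, p_mean, ll_trace, alpha_sum / reps, drift_sum / reps
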