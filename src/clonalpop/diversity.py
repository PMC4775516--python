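"""Per-population diversity statistics and null-allele / inbreeding estimation.

Implements the survey-table statistics for each population (region x
mitochondrial type, clone-corrected): observed and unbiased expected
heterozygosity, the multilocus inbreeding index F_IS = 1 - H_O / H_E,
rarefied allelic richness A_R, an expectation-maximization estimate of
per-locus null-allele frequency, and a Bayesian individual-inbreeding-model
sampler (`NullAlleleInbreedingModel`) in two flavours: ``nfb`` (null
alleles, inbreeding coefficients and genotyping failures) and ``nb`` (null
alleles and genotyping failures only), compared by DIC.

The sampler's observation model: at each locus a null allele of frequency
rho segregates alongside the visible alleles; a carrier heterozygote is
scored as a visible homozygote, a null homozygote as a blank, and any
genotype blanks independently with failure probability beta.  Individual
inbreeding coefficients Fi follow a spike-and-slab prior (exactly zero
with probability 1 - pi, otherwise uniform on (0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "allele_frequencies",
    "heterozygosity",
    "f_is_estimate",
    "allelic_richness",
    "default_rarefaction_size",
    "null_allele_em",
    "hpd_interval",
    "NullAlleleInbreedingModel",
    "NullAlleleInbreedingResults",
    "compare_inbreeding_models",
    "DiversitySummary",
    "population_diversity",
]


def allele_frequencies(
    genotypes: np.ndarray,
) -> tuple[list[dict[int, float]], list[dict[int, int]]]:
    """Per-locus allele frequency and count maps over called alleles.

    Loci with no called alleles get an empty map (flagged by emptiness).
    Clone correction is achieved upstream by passing one representative
    genotype per lineage.
    """
    genotypes = np.asarray(genotypes)
    freqs: list[dict[int, float]] = []
    counts: list[dict[int, int]] = []
    for l in range(genotypes.shape[1]):
        alleles = genotypes[:, l, :].ravel()
        alleles = alleles[alleles > 0]
        cnt: dict[int, int] = {}
        for a in alleles:
            cnt[int(a)] = cnt.get(int(a), 0) + 1
        total = sum(cnt.values())
        counts.append(cnt)
        freqs.append({a: c / total for a, c in cnt.items()} if total else {})
    return freqs, counts


def heterozygosity(genotypes: np.ndarray) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per locus.

    H_O is the fraction of heterozygous among called individuals; H_E is
    Nei's unbiased estimator ``(1 - sum f^2) * 2n / (2n - 1)`` with n the
    number of called diploid individuals.  Loci with fewer than two called
    individuals are returned as NaN.  Multilocus values are unweighted
    means over the defined loci (see :func:`f_is_estimate`).
    """
    genotypes = np.asarray(genotypes)
    freqs, _ = allele_frequencies(genotypes)
    rows = []
    for l in range(genotypes.shape[1]):
        called = genotypes[:, l, 0] > 0
        n = int(called.sum())
        if n < 2:
            rows.append((n, np.nan, np.nan))
            continue
        het = genotypes[called, l, 0] != genotypes[called, l, 1]
        h_o = float(het.mean())
        ssq = sum(f * f for f in freqs[l].values())
        h_e = (1.0 - ssq) * (2 * n) / (2 * n - 1)
        rows.append((n, h_o, h_e))
    return pd.DataFrame(rows, columns=["n_called", "H_O", "H_E"])


def f_is_estimate(genotypes: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Multilocus F_IS = 1 - mean(H_O) / mean(H_E), plus per-locus values.

    NaN when every locus is monomorphic (mean H_E = 0 or undefined).
    """
    het = heterozygosity(genotypes)
    with np.errstate(invalid="ignore", divide="ignore"):
        het["F_IS"] = 1.0 - het["H_O"] / het["H_E"]
    ok = het["H_E"].notna()
    mean_ho = het.loc[ok, "H_O"].mean()
    mean_he = het.loc[ok, "H_E"].mean()
    fis = float(1.0 - mean_ho / mean_he) if ok.any() and mean_he > 0 else float("nan")
    return fis, het


def _rarefied_locus(counts: Mapping[int, int], g: int) -> float:
    m = np.array(list(counts.values()), dtype=np.int64)
    big_m = int(m.sum())
    if g > big_m:
        raise ValueError(f"rarefaction size g={g} exceeds {big_m} called genes")

    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        big_m - m >= g,
        1.0 - np.exp([log_comb(big_m - mi, g) - log_comb(big_m, g) for mi in m]),
        1.0,
    )
    return float(terms.sum())


def allelic_richness(genotypes: np.ndarray, g: int) -> tuple[float, list[float]]:
    """Rarefied allelic richness at standardized sample size ``g`` genes.

    Per locus, ``A_R = sum_a [1 - C(M - m_a, g) / C(M, g)]`` -- the
    expected number of distinct alleles in a random subsample of g gene
    copies.  Returns the unweighted mean over loci and the per-locus
    values.  At g = M this is the observed allele count; a monomorphic
    locus gives 1 for any g.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    _, counts = allele_frequencies(np.asarray(genotypes))
    per_locus = [_rarefied_locus(c, g) for c in counts if c]
    if not per_locus:
        raise ValueError("no locus has called alleles")
    return float(np.mean(per_locus)), per_locus


def default_rarefaction_size(populations: Sequence[np.ndarray]) -> int:
    """Smallest called-gene count (2 x called individuals) over all loci and
    populations -- the largest g valid for every compared population."""
    g = None
    for geno in populations:
        geno = np.asarray(geno)
        called = (geno[:, :, 0] > 0).sum(axis=0) * 2
        low = int(called.min())
        g = low if g is None else min(g, low)
    if g is None or g < 2:
        raise ValueError("populations have loci with fewer than 2 called genes")
    return g


# ---------------------------------------------------------------------------
# EM null-allele estimator
# ---------------------------------------------------------------------------


def null_allele_em(
    locus_genotypes: np.ndarray,
    use_missing: bool = True,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[float, dict[int, float], bool]:
    """EM estimate of the null-allele frequency at one locus.

    Treats the observed homozygote excess as hidden visible/null
    heterozygotes and (when ``use_missing``) blanks as null homozygotes,
    under Hardy-Weinberg proportions over the extended allele set.
    Returns ``(null_freq, visible_allele_freqs, converged)``; the visible
    frequencies are renormalized to sum to 1.  On non-convergence the last
    iterate is returned with ``converged=False``.
    """
    geno = np.sort(np.asarray(locus_genotypes, dtype=np.int64), axis=1)
    called = geno[:, 0] > 0
    n_blank = int((~called).sum()) if use_missing else 0
    geno = geno[called]
    alleles = sorted(set(geno.ravel().tolist()))
    if not alleles:
        return 0.0, {}, True
    a_index = {a: k for k, a in enumerate(alleles)}
    A = len(alleles)
    hom = geno[:, 0] == geno[:, 1]
    n_hom = np.zeros(A)
    het_counts = np.zeros(A)
    for a, b in geno:
        if a == b:
            n_hom[a_index[a]] += 1
        else:
            het_counts[a_index[a]] += 1
            het_counts[a_index[b]] += 1
    n_ind = geno.shape[0] + n_blank
    if n_ind == 0:
        return 0.0, {}, True
    # single observed allele and no blanks: no information, estimate 0
    if A == 1 and n_blank == 0:
        return 0.0, {alleles[0]: 1.0}, True
    # init: equal shares, small null
    p = np.full(A, (1.0 - 0.05) / A)
    r = 0.05
    converged = False
    for _ in range(max_iter):
        # E-step: expected allele-copy counts
        exp_vis = het_counts.copy()
        exp_null = 2.0 * n_blank
        for k in range(A):
            if n_hom[k] == 0:
                continue
            denom = p[k] * p[k] + 2.0 * p[k] * r
            if denom <= 0:
                share_null = 0.0
            else:
                share_null = (2.0 * p[k] * r) / denom
            # each observed homozygote carries 2 visible copies if true hom,
            # else 1 visible + 1 null
            exp_vis[k] += n_hom[k] * (2.0 * (1.0 - share_null) + 1.0 * share_null)
            exp_null += n_hom[k] * share_null
        total = exp_vis.sum() + exp_null
        p_new = exp_vis / total
        r_new = exp_null / total
        if abs(r_new - r) < tol and np.abs(p_new - p).max() < tol:
            p, r = p_new, r_new
            converged = True
            break
        p, r = p_new, r_new
    # EM approaches the r = 0 boundary only sublinearly; when the boundary
    # (no nulls, observed frequencies) fits at least as well, snap to it
    if n_blank == 0 and r < 0.05:
        def loglik(pv: np.ndarray, rv: float) -> float:
            ll = 0.0
            for k in range(A):
                if n_hom[k]:
                    ll += n_hom[k] * np.log(pv[k] ** 2 + 2 * pv[k] * rv + 1e-300)
            ll += float((het_counts * np.log(pv + 1e-300)).sum())
            return ll

        p_obs = (het_counts + 2.0 * n_hom) / (het_counts + 2.0 * n_hom).sum()
        if loglik(p_obs, 0.0) >= loglik(p, r):
            return 0.0, {a: float(p_obs[a_index[a]]) for a in alleles}, True
    vis_total = p.sum()
    vis = {a: float(p[a_index[a]] / vis_total) for a in alleles} if vis_total > 0 else {}
    return float(r), vis, converged


# ---------------------------------------------------------------------------
# Bayesian individual-inbreeding model (nfb / nb)
# ---------------------------------------------------------------------------


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sampled mass."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    k = max(1, int(np.ceil(prob * n)))  # points inside the interval
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


@dataclass
class NullAlleleInbreedingResults:
    """Posterior summaries from :class:`NullAlleleInbreedingModel.fit`."""

    model: str
    null_freq_locus: np.ndarray  # posterior mean per locus
    null_freq: float  # mean over loci ("Null freq.")
    failure_rate: float
    avg_fi: float
    avg_fi_hpd: tuple[float, float]
    dic: float
    p_d: float
    mean_deviance: float
    draws: dict[str, np.ndarray]
    settings: dict

    def draws_frame(self) -> pd.DataFrame:
        """Kept posterior draws as one wide table (for TSV export)."""
        rho = self.draws["null_freq"]
        df = pd.DataFrame(
            rho, columns=[f"null_freq_L{l + 1}" for l in range(rho.shape[1])]
        )
        df["failure_rate"] = self.draws["failure_rate"]
        df["avg_fi"] = self.draws["avg_fi"]
        df["deviance"] = self.draws["deviance"]
        return df

    def summary(self) -> pd.DataFrame:
        lo, hi = self.avg_fi_hpd
        return pd.DataFrame(
            {
                "model": [self.model],
                "null_freq": [round(self.null_freq, 4)],
                "failure_rate": [round(self.failure_rate, 4)],
                "avg_fi": [round(self.avg_fi, 4)],
                "avg_fi_hpd_low": [round(lo, 4)],
                "avg_fi_hpd_high": [round(hi, 4)],
                "DIC": [round(self.dic, 3)],
                "p_D": [round(self.p_d, 3)],
            }
        )


class NullAlleleInbreedingModel:
    """Bayesian null-allele / genotyping-failure / inbreeding model.

    Parameters
    ----------
    genotypes : ndarray (n, n_loci, 2)
        Diploid genotypes with 0 = missing allele.
    model : {"nfb", "nb"}
        ``nfb`` samples per-individual inbreeding coefficients alongside
        null-allele frequencies and the failure rate; ``nb`` fixes all
        Fi = 0.

    The sampler is a data-augmentation Gibbs chain: for every cell it
    imputes the latent state (identical-by-descent vs outbred; observed
    homozygote as true homozygote vs visible/null heterozygote; blank as
    failure vs null homozygote vs IBD null), after which the per-locus
    null frequency rho_l, the visible allele frequencies, the failure
    rate beta, the spike-and-slab Fi and its mixing weight pi ~ Beta(1,1)
    all have conjugate Beta/Dirichlet updates.
    """

    def __init__(self, genotypes: np.ndarray, model: str = "nfb") -> None:
        if model not in ("nfb", "nb"):
            raise ValueError("model must be 'nfb' or 'nb'")
        geno = np.sort(np.asarray(genotypes, dtype=np.int64), axis=2)
        if geno.ndim != 3 or geno.shape[1] < 2:
            raise ValueError("need diploid genotypes at >= 2 loci")
        self.model = model
        self.n, self.n_loci = geno.shape[0], geno.shape[1]
        self.is_missing = (geno == 0).all(axis=2)
        self.is_hom = (~self.is_missing) & (geno[:, :, 0] == geno[:, :, 1])
        self.is_het = (~self.is_missing) & ~self.is_hom
        # dense per-locus allele coding for q lookups
        self.alleles: list[list[int]] = []
        self.a_idx = np.zeros((self.n, self.n_loci), dtype=np.int64)
        self.b_idx = np.zeros((self.n, self.n_loci), dtype=np.int64)
        for l in range(self.n_loci):
            obs = sorted({int(a) for a in geno[:, l, :].ravel() if a > 0})
            amap = {a: k for k, a in enumerate(obs)}
            self.alleles.append(obs)
            for i in range(self.n):
                a, b = geno[i, l]
                if a > 0:
                    self.a_idx[i, l] = amap[int(a)]
                    self.b_idx[i, l] = amap[int(b)]

    # -- marginal likelihood (for the deviance / DIC) -----------------------

    def _loglik_cells(
        self,
        q: list[np.ndarray],
        rho: np.ndarray,
        beta: float,
        fi: np.ndarray,
    ) -> np.ndarray:
        """(n, n_loci) observation log-likelihood with latents integrated
        out."""
        ll = np.zeros((self.n, self.n_loci))
        tiny = 1e-300
        for l in range(self.n_loci):
            r = rho[l]
            qa = q[l][self.a_idx[:, l]] * (1.0 - r)
            qb = q[l][self.b_idx[:, l]] * (1.0 - r)
            f = fi
            p_missing = beta + (1.0 - beta) * ((1.0 - f) * r * r + f * r)
            p_hom = (1.0 - beta) * ((1.0 - f) * (qa * qa + 2.0 * qa * r) + f * qa)
            p_het = (1.0 - beta) * (1.0 - f) * 2.0 * qa * qb
            col = np.where(
                self.is_missing[:, l],
                p_missing,
                np.where(self.is_hom[:, l], p_hom, p_het),
            )
            ll[:, l] = np.log(col + tiny)
        return ll

    def deviance(
        self, q: list[np.ndarray], rho: np.ndarray, beta: float, fi: np.ndarray
    ) -> float:
        return float(-2.0 * self._loglik_cells(q, rho, beta, fi).sum())

    # -- sampler ------------------------------------------------------------

    def fit(
        self,
        burn_in: int = 50_000,
        cycles: int = 500_000,
        thin: int = 50,
        seed: int | None = None,
    ) -> NullAlleleInbreedingResults:
        """Run the data-augmentation Gibbs chain.

        ``cycles`` is the total chain length including ``burn_in``; draws
        are recorded every ``thin`` cycles after burn-in.  A fixed seed
        gives bit-identical posterior summaries.
        """
        if cycles <= burn_in:
            raise ValueError("cycles must exceed burn_in")
        rng = np.random.default_rng(seed)
        n, n_loci = self.n, self.n_loci
        q = []
        for l in range(n_loci):
            a_count = max(len(self.alleles[l]), 1)
            cnt = np.full(a_count, 0.5)
            if self.alleles[l]:
                called = ~self.is_missing[:, l]
                np.add.at(cnt, self.a_idx[called, l], 1.0)
                np.add.at(cnt, self.b_idx[called, l], 1.0)
            q.append(cnt / cnt.sum())
        rho = np.full(n_loci, 0.05)
        beta = 0.02
        fi = np.zeros(n)
        z = np.zeros(n, dtype=bool)
        pi = 0.5
        nfb = self.model == "nfb"
        if nfb:
            # start the slab at the moment-based inbreeding estimate so the
            # chain explores both the null-allele and the inbreeding
            # explanation of homozygote excess
            fis0 = 0.0
            het_obs = self.is_het.sum() / max((~self.is_missing).sum(), 1)
            exp_het = np.mean(
                [1.0 - (ql**2).sum() for ql in q if len(ql) > 1] or [0.0]
            )
            if exp_het > 0:
                fis0 = min(max(1.0 - het_obs / exp_het, 0.0), 0.9)
            z[:] = True
            fi[:] = fis0

        keep_rho, keep_beta, keep_avgfi, keep_dev = [], [], [], []
        sum_fi = np.zeros(n)
        sum_q = [np.zeros_like(ql) for ql in q]
        n_kept = 0
        for it in range(cycles):
            null_copies = np.zeros(n_loci)
            vis_copies = np.zeros(n_loci)
            vis_counts = [np.zeros_like(ql) for ql in q]
            k_ibd = np.zeros(n)  # imputed IBD loci per individual
            m_inf = np.zeros(n)  # informative (non-failure) loci
            n_fail = 0
            n_cells = 0
            for l in range(n_loci):
                r = rho[l]
                ql = q[l]
                qa = ql[self.a_idx[:, l]] * (1.0 - r)
                qb = ql[self.b_idx[:, l]] * (1.0 - r)
                u = rng.random(n)
                # observed heterozygotes: outbred, two visible copies
                het = self.is_het[:, l]
                if het.any():
                    idx = self.a_idx[het, l]
                    np.add.at(vis_counts[l], idx, 1.0)
                    np.add.at(vis_counts[l], self.b_idx[het, l], 1.0)
                    vis_copies[l] += 2.0 * het.sum()
                    m_inf[het] += 1.0
                # observed homozygotes: IBD / true hom / visible-null het
                hom = self.is_hom[:, l]
                if hom.any():
                    f = fi[hom]
                    w_ibd = f * qa[hom]
                    w_hom = (1.0 - f) * qa[hom] ** 2
                    w_nul = (1.0 - f) * 2.0 * qa[hom] * r
                    tot = w_ibd + w_hom + w_nul
                    tot[tot <= 0] = 1.0
                    uu = u[hom] * tot
                    pick_ibd = uu < w_ibd
                    pick_hom = (~pick_ibd) & (uu < w_ibd + w_hom)
                    pick_nul = ~(pick_ibd | pick_hom)
                    idx = self.a_idx[hom, l]
                    np.add.at(vis_counts[l], idx, np.where(pick_ibd, 1.0, 2.0 - pick_nul))
                    vis_copies[l] += float(
                        np.where(pick_ibd, 1.0, np.where(pick_nul, 1.0, 2.0)).sum()
                    )
                    null_copies[l] += float(pick_nul.sum())
                    k_ibd[hom] += pick_ibd
                    m_inf[hom] += 1.0
                # blanks: failure / IBD null / null homozygote
                blank = self.is_missing[:, l]
                if blank.any():
                    f = fi[blank]
                    w_fail = np.full(blank.sum(), beta)
                    w_ibd = (1.0 - beta) * f * r
                    w_nul = (1.0 - beta) * (1.0 - f) * r * r
                    tot = w_fail + w_ibd + w_nul
                    uu = u[blank] * tot
                    pick_fail = uu < w_fail
                    pick_ibd = (~pick_fail) & (uu < w_fail + w_ibd)
                    pick_nul = ~(pick_fail | pick_ibd)
                    n_fail += int(pick_fail.sum())
                    null_copies[l] += float(pick_ibd.sum() + 2.0 * pick_nul.sum())
                    k_blank = np.zeros(n)
                    k_blank[blank] = pick_ibd
                    k_ibd += k_blank
                    m_blank = np.zeros(n)
                    m_blank[blank] = ~pick_fail
                    m_inf += m_blank
                n_cells += n
            # conjugate updates
            for l in range(n_loci):
                rho[l] = rng.beta(1.0 + null_copies[l], 1.0 + vis_copies[l])
                if len(self.alleles[l]) > 0:
                    q[l] = rng.dirichlet(1.0 + vis_counts[l])
                    q[l] = np.maximum(q[l], 1e-12)
                    q[l] /= q[l].sum()
            beta = rng.beta(1.0 + n_fail, 1.0 + (n_cells - n_fail))
            if nfb:
                forced = k_ibd > 0
                z[forced] = True
                free = ~forced
                if free.any():
                    # marginal slab likelihood of all-outbred loci:
                    # B(1, m+1) = 1 / (m + 1)
                    odds = pi / (1.0 - pi) / (m_inf[free] + 1.0)
                    z[free] = rng.random(int(free.sum())) < odds / (1.0 + odds)
                fi = np.where(
                    z,
                    rng.beta(1.0 + k_ibd, 1.0 + np.maximum(m_inf - k_ibd, 0.0)),
                    0.0,
                )
                pi = rng.beta(1.0 + z.sum(), 1.0 + n - z.sum())
                # mode-swap Metropolis on the latent-marginalized posterior:
                # trade null-allele mass against slab inbreeding (the two
                # explanations of homozygote excess form a likelihood ridge
                # that single-site updates cross very slowly)
                t = rng.normal(0.0, 0.02)
                rho_p = rho - t
                fi_p = np.where(z, fi + 2.0 * t, fi)
                if (
                    (rho_p > 0).all()
                    and (rho_p < 1).all()
                    and (fi_p >= 0).all()
                    and (fi_p < 1).all()
                ):
                    cur = self._loglik_cells(q, rho, beta, fi).sum()
                    new = self._loglik_cells(q, rho_p, beta, fi_p).sum()
                    if np.log(rng.random()) < new - cur:
                        rho, fi = rho_p, fi_p
            if it >= burn_in and (it - burn_in) % thin == 0:
                keep_rho.append(rho.copy())
                keep_beta.append(beta)
                keep_avgfi.append(float(fi.mean()))
                keep_dev.append(self.deviance(q, rho, beta, fi))
                sum_fi += fi
                for l in range(n_loci):
                    sum_q[l] += q[l]
                n_kept += 1
        rho_draws = np.array(keep_rho)
        dev_draws = np.array(keep_dev)
        avgfi_draws = np.array(keep_avgfi)
        rho_mean = rho_draws.mean(axis=0)
        beta_mean = float(np.mean(keep_beta))
        fi_mean = sum_fi / n_kept
        q_mean = [s / n_kept for s in sum_q]
        d_bar = float(dev_draws.mean())
        d_hat = self.deviance(q_mean, rho_mean, beta_mean, fi_mean)
        p_d = d_bar - d_hat
        return NullAlleleInbreedingResults(
            model=self.model,
            null_freq_locus=rho_mean,
            null_freq=float(rho_mean.mean()),
            failure_rate=beta_mean,
            avg_fi=float(avgfi_draws.mean()),
            avg_fi_hpd=hpd_interval(avgfi_draws, 0.95),
            dic=d_bar + p_d,
            p_d=p_d,
            mean_deviance=d_bar,
            draws={
                "null_freq": rho_draws,
                "failure_rate": np.array(keep_beta),
                "avg_fi": avgfi_draws,
                "deviance": dev_draws,
            },
            settings={
                "burn_in": burn_in,
                "cycles": cycles,
                "thin": thin,
                "seed": seed,
            },
        )


def compare_inbreeding_models(
    genotypes: np.ndarray,
    burn_in: int = 50_000,
    cycles: int = 500_000,
    thin: int = 50,
    seed: int | None = None,
) -> tuple[NullAlleleInbreedingResults, NullAlleleInbreedingResults, str]:
    """Fit nfb and nb and pick the lower-DIC model.

    Returns (nfb, nb, best) where best is "nfb", "nb" or
    "indistinguishable" when |dDIC| < 1.0.
    """
    seeds = np.random.SeedSequence(seed).spawn(2)
    nfb = NullAlleleInbreedingModel(genotypes, "nfb").fit(
        burn_in, cycles, thin, seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )
    nb = NullAlleleInbreedingModel(genotypes, "nb").fit(
        burn_in, cycles, thin, seed=int(seeds[1].generate_state(1)[0] % 2**31)
    )
    if abs(nfb.dic - nb.dic) < 1.0:
        best = "indistinguishable"
    else:
        best = "nfb" if nfb.dic < nb.dic else "nb"
    return nfb, nb, best


# ---------------------------------------------------------------------------
# survey-table assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiversitySummary:
    """One diversity-table row for a population."""

    population: str
    A_R: float
    H_O: float
    H_E: float
    F_IS: float
    null_freq: float
    avg_fi: float
    avg_fi_hpd: tuple[float, float]
    dic_nfb: float
    dic_nb: float
    best_model: str


def population_diversity(
    label: str,
    genotypes: np.ndarray,
    g: int,
    burn_in: int = 50_000,
    cycles: int = 500_000,
    thin: int = 50,
    seed: int | None = None,
) -> DiversitySummary:
    """Assemble the full diversity row for one clone-corrected population."""
    het = heterozygosity(genotypes)
    fis, _ = f_is_estimate(genotypes)
    a_r, _ = allelic_richness(genotypes, g)
    nfb, nb, best = compare_inbreeding_models(
        genotypes, burn_in=burn_in, cycles=cycles, thin=thin, seed=seed
    )
    return DiversitySummary(
        population=label,
        A_R=a_r,
        H_O=float(het["H_O"].mean()),
        H_E=float(het["H_E"].mean()),
        F_IS=fis,
        null_freq=nfb.null_freq,
        avg_fi=nfb.avg_fi,
        avg_fi_hpd=nfb.avg_fi_hpd,
        dic_nfb=nfb.dic,
        dic_nb=nb.dic,
        best_model=best,
    )
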