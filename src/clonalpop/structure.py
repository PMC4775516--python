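"""Bayesian admixture clustering, replicate merging and model choice.

`AdmixtureModel` fits the no-prior-information admixture model with
correlated allele frequencies to clone-corrected multilocus genotypes and
returns an `AdmixtureResults` object carrying the posterior-mean ancestry
matrix Q, cluster allele frequencies P, and the log probability of the
data estimated as ``mean(log L) - var(log L) / 2`` over post-burn-in
sweeps.  `evanno_delta_k` turns a (K, replicate) -> lnPD table into the
second-difference statistic dK and the best-supported K; the table may
come from this sampler or from any external program producing per-K log
probabilities (e.g. an inbreeding-aware sampler), which is how such runs
plug into the same model-choice machinery.  `align_replicates` merges
replicate runs by greedy label alignment, and `flag_cross_type` marks
lineages whose dominant genetic cluster belongs to the opposite
mitochondrial type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._admixture import admixture_chain

__all__ = [
    "AdmixtureModel",
    "AdmixtureResults",
    "ClusterRunTable",
    "run_k_scan",
    "evanno_delta_k",
    "align_replicates",
    "flag_cross_type",
    "plot_ancestry",
]


def _encode_alleles(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Map allele sizes to dense per-locus indices; missing -> -1."""
    geno = np.sort(np.asarray(genotypes, dtype=np.int64), axis=2)
    n, n_loci = geno.shape[0], geno.shape[1]
    x = np.full((n, n_loci, 2), -1, dtype=np.int64)
    alleles_per_locus: list[list[int]] = []
    for l in range(n_loci):
        alleles = sorted({int(a) for a in geno[:, l, :].ravel() if a > 0})
        amap = {a: i for i, a in enumerate(alleles)}
        alleles_per_locus.append(alleles)
        for i in range(n):
            a, b = geno[i, l]
            if a > 0:
                x[i, l, 0] = amap[int(a)]
                x[i, l, 1] = amap[int(b)]
    n_alleles = np.array([max(len(a), 1) for a in alleles_per_locus], dtype=np.int64)
    return x, n_alleles, alleles_per_locus


@dataclass
class AdmixtureResults:
    """Posterior summaries of one admixture-model run."""

    K: int
    Q: np.ndarray  # (n, K) posterior-mean ancestry, rows sum to 1
    P: np.ndarray  # (K, n_loci, A_max) posterior-mean cluster frequencies
    ln_pd: float
    loglik_trace: np.ndarray
    alpha: float
    drift: np.ndarray
    settings: dict

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": [self.K],
                "lnPD": [round(self.ln_pd, 2)],
                "mean_loglik": [round(float(self.loglik_trace.mean()), 2)],
                "alpha": [round(self.alpha, 3)],
                "mean_max_ancestry": [round(float(self.Q.max(axis=1).mean()), 3)],
            }
        )


class AdmixtureModel:
    """Admixture-model Bayesian clustering of diploid microsatellite data.

    Parameters
    ----------
    genotypes : ndarray (n, n_loci, 2)
        Clone-corrected diploid genotypes, 0 = missing allele.
    K : int
        Number of clusters (>= 1).
    correlated_freqs : bool
        Use the correlated-allele-frequencies prior (default), with the
        ancestral frequencies fixed at the pooled sample frequencies and
        per-cluster drift parameters sampled.

    The production chain lengths mirror common practice for this marker
    class (burn-in 100,000 / 1,000,000 replications); desk-scale runs pass
    shorter chains explicitly.
    """

    def __init__(
        self, genotypes: np.ndarray, K: int, correlated_freqs: bool = True
    ) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = int(K)
        self.correlated = bool(correlated_freqs)
        self.x, self.n_alleles, self.alleles = _encode_alleles(genotypes)
        self.n, self.n_loci = self.x.shape[0], self.x.shape[1]
        a_max = int(self.n_alleles.max())
        pa = np.zeros((self.n_loci, a_max))
        for l in range(self.n_loci):
            obs = self.x[:, l, :].ravel()
            obs = obs[obs >= 0]
            counts = np.bincount(obs, minlength=self.n_alleles[l]).astype(float)
            total = counts.sum()
            if total == 0:
                counts[:] = 1.0
                total = counts.sum()
            # small pseudo-count keeps the correlated prior proper
            counts += 0.01
            pa[l, : self.n_alleles[l]] = counts[: self.n_alleles[l]] / counts.sum()
        self.ancestral_freqs = pa

    def fit(
        self,
        burn_in: int = 100_000,
        reps: int = 1_000_000,
        seed: int | None = None,
        alpha_init: float = 1.0,
        alpha_step: float = 0.05,
        drift_step: float = 0.05,
    ) -> AdmixtureResults:
        """Run the Gibbs chain and summarize the posterior.

        ``reps`` counts post-burn-in sweeps.  The log data probability
        lnPD is ``mean(log L) - var(log L) / 2`` over those sweeps.  A
        fixed seed reproduces Q summaries exactly.
        """
        if reps <= 0:
            raise ValueError("reps must exceed 0")
        if burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        seed32 = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
        q, p, ll, alpha, drift = admixture_chain(
            self.x,
            self.n_alleles,
            self.K,
            int(burn_in),
            int(reps),
            self.correlated,
            self.ancestral_freqs,
            float(alpha_init),
            float(alpha_step),
            float(drift_step),
            seed32,
        )
        ln_pd = float(ll.mean() - ll.var() / 2.0)
        return AdmixtureResults(
            K=self.K,
            Q=q,
            P=p,
            ln_pd=ln_pd,
            loglik_trace=ll,
            alpha=float(alpha),
            drift=drift,
            settings={
                "burn_in": burn_in,
                "reps": reps,
                "seed": seed,
                "correlated_freqs": self.correlated,
            },
        )


@dataclass
class ClusterRunTable:
    """Replicate admixture runs across a K scan, plus the dK table."""

    runs: dict[tuple[int, int], AdmixtureResults]  # (K, replicate) -> results
    ln_pd_table: pd.DataFrame  # columns K, replicate, lnPD
    delta_k: pd.DataFrame | None = None
    best_k: int | None = None


def run_k_scan(
    genotypes: np.ndarray,
    k_values: Sequence[int],
    replicates: int = 10,
    burn_in: int = 100_000,
    reps: int = 1_000_000,
    correlated_freqs: bool = True,
    seed: int | None = None,
) -> ClusterRunTable:
    """Fit the admixture model over a K scan with replicate chains and
    attach the Evanno dK table (when >= 3 consecutive K values)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(k_values) * replicates)
    runs: dict[tuple[int, int], AdmixtureResults] = {}
    rows = []
    idx = 0
    for k in k_values:
        model = AdmixtureModel(genotypes, K=k, correlated_freqs=correlated_freqs)
        for rep in range(replicates):
            res = model.fit(
                burn_in=burn_in,
                reps=reps,
                seed=int(children[idx].generate_state(1)[0] % 2**31),
            )
            idx += 1
            runs[(k, rep)] = res
            rows.append({"K": k, "replicate": rep, "lnPD": res.ln_pd})
    table = pd.DataFrame(rows)
    out = ClusterRunTable(runs=runs, ln_pd_table=table)
    ks = sorted(set(int(k) for k in k_values))
    if len(ks) >= 3 and replicates >= 2 and ks == list(range(ks[0], ks[-1] + 1)):
        out.delta_k, out.best_k = evanno_delta_k(table)
    return out


def evanno_delta_k(ln_pd_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno second-difference statistic over a (K, replicate, lnPD) table.

    dK(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)| divided by
    sd(L(K)); defined only for interior K.  Raises when sd(L(K)) is zero
    at an interior K (the ratio is undefined).  Returns the per-K table
    and best_k = argmax dK.
    """
    tab = ln_pd_table.copy()
    ks = sorted(tab["K"].unique())
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError("K values must be consecutive")
    by_k = {
        k: tab[tab["K"] == k].sort_values("replicate")["lnPD"].to_numpy() for k in ks
    }
    counts = {k: len(v) for k, v in by_k.items()}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    if len(set(counts.values())) != 1:
        raise ValueError("replicate counts differ across K")
    rows = []
    for k in ks:
        mean = float(by_k[k].mean())
        sd = float(by_k[k].std(ddof=1))
        rows.append({"K": k, "mean_lnPD": mean, "sd_lnPD": sd, "delta_K": np.nan})
    out = pd.DataFrame(rows).set_index("K")
    for k in ks[1:-1]:
        sd = out.loc[k, "sd_lnPD"]
        if sd == 0:
            raise ValueError(f"sd of lnPD is zero at K={k}: delta K undefined")
        second = np.abs(by_k[k + 1] - 2.0 * by_k[k] + by_k[k - 1]).mean()
        out.loc[k, "delta_K"] = second / sd
    best_k = int(out["delta_K"].idxmax())
    return out.reset_index(), best_k


def align_replicates(
    q_matrices: Sequence[np.ndarray],
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Align cluster labels across replicate runs and average them.

    The first run is the reference; each other run gets the cluster-label
    permutation minimizing the squared difference of its Q matrix to the
    reference (exhaustive search for K <= 8, greedy beyond).  Returns the
    permutations (one per run; ``perm[j]`` = reference cluster matched by
    the run's cluster j is applied as column reordering ``Q[:, perm]``)
    and the consensus (mean aligned) Q.
    """
    if len(q_matrices) < 2:
        raise ValueError("need at least two runs to align")
    ref = np.asarray(q_matrices[0], dtype=float)
    n, k = ref.shape
    perms: list[tuple[int, ...]] = [tuple(range(k))]
    total = ref.copy()
    for q in q_matrices[1:]:
        q = np.asarray(q, dtype=float)
        if q.shape != ref.shape:
            raise ValueError("runs have differing individuals or K")
        if k <= 8:
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(k)):
                cost = float(((ref - q[:, perm]) ** 2).sum())
                if cost < best_cost:
                    best, best_cost = perm, cost
        else:  # greedy column matching
            sim = ref.T @ q
            best_list = [-1] * k
            used = set()
            for _ in range(k):
                i, j = np.unravel_index(
                    np.argmax(
                        np.where(
                            np.isin(np.arange(k), list(used))[None, :], -np.inf, sim
                        )
                    ),
                    sim.shape,
                )
                best_list[i] = j
                sim[i, :] = -np.inf
                used.add(j)
            best = tuple(best_list)
        perms.append(best)
        total += q[:, best]
    consensus = total / len(q_matrices)
    return perms, consensus


def flag_cross_type(
    q: np.ndarray,
    mito_types: Sequence[str],
    q_flag: float = 0.5,
) -> tuple[np.ndarray, dict[int, str]]:
    """Flag lineages assigned to the genetic cluster of the opposite type.

    Clusters are mapped to mitochondrial types by majority membership of
    the individuals whose top-ancestry cluster they are; a lineage is
    flagged when its own top cluster maps to a different type than its
    label and that top ancestry exceeds ``q_flag``.  Raises when a cluster
    has no majority type.

    Returns a boolean flag per individual and the cluster -> type map.
    """
    q = np.asarray(q, dtype=float)
    mito = np.asarray(mito_types)
    top = q.argmax(axis=1)
    cluster_type: dict[int, str] = {}
    for k in range(q.shape[1]):
        members = mito[top == k]
        if len(members) == 0:
            continue
        vals, counts = np.unique(members, return_counts=True)
        order = np.argsort(-counts)
        if len(vals) > 1 and counts[order[0]] == counts[order[1]]:
            raise ValueError(f"cluster {k}: no majority mitochondrial type")
        cluster_type[k] = str(vals[order[0]])
    flags = np.zeros(q.shape[0], dtype=bool)
    for i in range(q.shape[0]):
        k = top[i]
        if k in cluster_type and cluster_type[k] != mito[i]:
            flags[i] = q[i, k] > q_flag
    return flags, cluster_type


def plot_ancestry(q: np.ndarray, labels: Sequence | None = None, ax=None):
    """Basic stacked-bar ancestry plot of a Q matrix."""
    import matplotlib.pyplot as plt

    q = np.asarray(q, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, q.shape[0] / 8), 2.5))
    bottom = np.zeros(q.shape[0])
    x = np.arange(q.shape[0])
    for k in range(q.shape[1]):
        ax.bar(x, q[:, k], bottom=bottom, width=1.0)
        bottom += q[:, k]
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    if labels is not None:
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=5)
    return ax
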