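"""Clone (multilocus lineage) detection.

Colonies sampled within one site and mitochondrial type are grouped into
multilocus genotypes (MLGs, exact matches over all loci) and then into
multilocus lineages (MLLs): MLGs differing at no more than
``max_mismatch_loci`` loci are taken to be ramets of one genet, absorbing
somatic mutations and scoring errors.  Recurrent identical MLGs are tested
with the P_SEX statistic -- the binomial tail probability of drawing the
same multilocus genotype n times in N samples under sexual reproduction --
and recurrences that are plausibly sexual are promoted to separate
lineages.  Clonal diversity is summarized as R = (MLL - 1) / (N - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import binom

__all__ = [
    "MLLPartition",
    "PsexResult",
    "ClonalSummary",
    "count_mlgs",
    "genotype_mismatch_loci",
    "cluster_mlls",
    "representative_genotype",
    "p_gen",
    "p_sex",
    "resolve_recurrent_mlgs",
    "assign_lineages",
    "clonal_richness",
]


def genotype_mismatch_loci(g1: np.ndarray, g2: np.ndarray) -> int:
    """Number of loci at which two diploid genotypes differ.

    Genotypes are (n_loci, 2) sorted allele pairs; a locus differs when the
    unordered pairs are not equal, and missing-vs-called counts as a
    difference (missing-vs-missing does not).
    """
    g1 = np.sort(np.asarray(g1), axis=1)
    g2 = np.sort(np.asarray(g2), axis=1)
    return int((g1 != g2).any(axis=1).sum())


def count_mlgs(genotypes: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Group colonies into exact-match multilocus genotypes.

    Returns ``(G, mlg_index, unique_genotypes)`` where ``mlg_index[i]`` is
    the MLG id of colony *i* and ``unique_genotypes`` has shape
    (G, n_loci, 2).  Missing matches only missing.
    """
    genotypes = np.sort(np.asarray(genotypes, dtype=np.int64), axis=2)
    if genotypes.shape[0] == 0:
        raise ValueError("empty stratum")
    flat = genotypes.reshape(genotypes.shape[0], -1)
    uniq, index = np.unique(flat, axis=0, return_inverse=True)
    # re-label in order of first appearance for stable, readable ids
    order = np.full(uniq.shape[0], -1, dtype=np.int64)
    nxt = 0
    relabeled = np.empty_like(index)
    for i, u in enumerate(index):
        if order[u] < 0:
            order[u] = nxt
            nxt += 1
        relabeled[i] = order[u]
    uniq_sorted = np.empty_like(uniq)
    uniq_sorted[order] = uniq
    return uniq.shape[0], relabeled, uniq_sorted.reshape(-1, genotypes.shape[1], 2)


def cluster_mlls(
    genotypes: np.ndarray,
    max_mismatch_loci: int = 1,
    linkage: str = "single",
) -> np.ndarray:
    """Partition colonies of one stratum into multilocus lineages.

    Two MLGs are linked when they differ at <= ``max_mismatch_loci`` loci.
    With ``linkage="single"`` (default) lineages are the connected
    components of this relation -- transitive closure, matching how manual
    curation merges chains of near-identical ramets.  With
    ``linkage="clique"`` every pair inside a lineage must satisfy the rule
    (greedy strict-clique assignment, largest MLGs first).

    Returns an integer lineage label per colony.
    """
    genotypes = np.asarray(genotypes)
    n_loci = genotypes.shape[1]
    if max_mismatch_loci >= n_loci:
        raise ValueError("max_mismatch_loci must be smaller than the number of loci")
    if max_mismatch_loci < 0:
        raise ValueError("max_mismatch_loci must be >= 0")
    G, mlg_index, uniq = count_mlgs(genotypes)
    if linkage not in ("single", "clique"):
        raise ValueError("linkage must be 'single' or 'clique'")
    diffs = np.zeros((G, G), dtype=np.int64)
    for a in range(G):
        for b in range(a + 1, G):
            d = genotype_mismatch_loci(uniq[a], uniq[b])
            diffs[a, b] = diffs[b, a] = d
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(range(G))
        g.add_edges_from(
            (a, b) for a in range(G) for b in range(a + 1, G) if diffs[a, b] <= max_mismatch_loci
        )
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        labels_mlg = np.array([comp_of[a] for a in range(G)])
    else:
        mult = np.bincount(mlg_index, minlength=G)
        order = np.argsort(-mult, kind="stable")
        labels_mlg = np.full(G, -1, dtype=np.int64)
        members: list[list[int]] = []
        for a in order:
            placed = False
            for ci, mem in enumerate(members):
                if all(diffs[a, b] <= max_mismatch_loci for b in mem):
                    labels_mlg[a] = ci
                    mem.append(a)
                    placed = True
                    break
            if not placed:
                labels_mlg[a] = len(members)
                members.append([a])
    # relabel in order of first appearance over colonies
    labels = labels_mlg[mlg_index]
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def representative_genotype(
    member_genotypes: np.ndarray, counts: Sequence[int] | None = None
) -> np.ndarray:
    """Representative MLG of a lineage: the most common member genotype.

    ``member_genotypes`` holds the distinct MLGs of the lineage (shape
    (m, n_loci, 2)) and ``counts`` their multiplicities (default 1 each).
    When the modal genotype is not unique, every locus at which the tied
    modal genotypes disagree is set to missing (0, 0) in the representative,
    so that an ambiguous locus drops out of downstream analyses.
    """
    member_genotypes = np.sort(np.asarray(member_genotypes, dtype=np.int64), axis=2)
    m = member_genotypes.shape[0]
    counts = np.ones(m, dtype=np.int64) if counts is None else np.asarray(counts)
    if counts.shape != (m,) or (counts < 1).any():
        raise ValueError("counts must give a positive multiplicity per member MLG")
    top = counts.max()
    tied = member_genotypes[counts == top]
    rep = tied[0].copy()
    if tied.shape[0] > 1:
        disagree = (tied != tied[0][None]).any(axis=(0, 2))
        rep[disagree] = 0
    return rep


def p_gen(
    genotype: np.ndarray,
    allele_freqs: Sequence[Mapping[int, float]],
    f_is: float = 0.0,
    tol: float = 1e-9,
) -> float:
    """Probability of a multilocus genotype under sexual reproduction.

    Per called locus, with allele frequencies f and inbreeding coefficient
    F_IS: a homozygote a/a has probability ``f_a^2 + f_a (1 - f_a) F_IS``
    and a heterozygote a/b has ``2 f_a f_b (1 - F_IS)``; missing loci are
    skipped and the product is clamped to [0, 1].
    """
    genotype = np.sort(np.asarray(genotype), axis=1)
    if not -1.0 <= f_is <= 1.0:
        raise ValueError("f_is must lie in [-1, 1]")
    prob = 1.0
    for l, (a, b) in enumerate(genotype):
        if a == 0 and b == 0:
            continue
        freqs = allele_freqs[l]
        total = sum(freqs.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"locus {l}: allele frequencies sum to {total}, not 1")
        for allele in {int(a), int(b)}:
            if allele not in freqs:
                raise KeyError(f"locus {l}: allele {allele} absent from frequency map")
        fa = freqs[int(a)]
        if a == b:
            prob *= fa * fa + fa * (1.0 - fa) * f_is
        else:
            prob *= 2.0 * fa * freqs[int(b)] * (1.0 - f_is)
    return float(min(max(prob, 0.0), 1.0))


def p_sex(p_gen_value: float, n_observed: int, n_stratum: int) -> float:
    """P_SEX: probability that an MLG with genotype probability ``p_gen``
    occurs at least ``n_observed`` times among ``n_stratum`` independent
    sexually produced colonies (upper binomial tail)."""
    if not 0.0 <= p_gen_value <= 1.0:
        raise ValueError("p_gen must lie in [0, 1]")
    if n_observed > n_stratum:
        raise ValueError("n_observed cannot exceed the stratum size")
    return float(binom.sf(n_observed - 1, n_stratum, p_gen_value))


def clonal_richness(n: int, mll: int) -> float:
    """Clonal diversity R = (MLL - 1) / (N - 1).

    0 for a monoclonal sample, 1 when every colony is a distinct lineage.
    Undefined for N = 1 (reported as NaN, printed as a dash).
    """
    if n < 1 or mll < 1 or mll > n:
        raise ValueError("need 1 <= MLL <= N")
    if n == 1:
        return float("nan")
    return (mll - 1) / (n - 1)


# ---------------------------------------------------------------------------
# recurrent-MLG resolution and the full stratum workflow
# ---------------------------------------------------------------------------


@dataclass
class PsexResult:
    """P_SEX verdict for one recurrent MLG."""

    mlg_id: int
    p_gen: float
    n_observed: int
    n_stratum: int
    p_sex: float
    alpha: float
    decision: str  # clonal | sexual_repeat | low_power_clonal
    loci_used: tuple[int, ...] = ()


@dataclass
class MLLPartition:
    """MLL assignment for one (site, type) stratum.

    ``labels`` maps each colony to a base lineage (connected component);
    ``n_lineages`` additionally counts recurrences judged sexual as extra
    lineages, following the survey convention of adding a chance-repeated
    MLG as its own lineage.
    """

    labels: np.ndarray
    mlg_index: np.ndarray
    unique_mlgs: np.ndarray
    representatives: np.ndarray  # (n_base_lineages, n_loci, 2)
    psex_results: list[PsexResult] = field(default_factory=list)
    n_lineages: int = 0

    @property
    def n_base(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def summary(self) -> "ClonalSummary":
        n = len(self.labels)
        g = int(self.mlg_index.max()) + 1 if n else 0
        return ClonalSummary(
            N=n,
            G=g,
            MLL=self.n_lineages,
            R=clonal_richness(n, min(self.n_lineages, n)) if n > 1 else float("nan"),
        )


@dataclass(frozen=True)
class ClonalSummary:
    N: int
    G: int
    MLL: int
    R: float


def resolve_recurrent_mlgs(
    labels: np.ndarray,
    mlg_index: np.ndarray,
    unique_mlgs: np.ndarray,
    allele_freqs: Sequence[Mapping[int, float]],
    f_is: float = 0.0,
    alpha: float = 0.05,
    min_power_genotypes: int = 3,
) -> tuple[int, list[PsexResult]]:
    """Decide whether recurrent identical MLGs are clones or chance repeats.

    For each MLG observed two or more times, P_SEX is evaluated from the
    clone-corrected allele frequencies; loci where the MLG's lineage shows
    internal (somatic-mutation or scoring) discrepancies, or where the MLG
    itself is missing, are excluded from the genotype probability.  A
    P_SEX below ``alpha`` rejects independent sexual origin, so the copies
    stay one lineage; a non-significant P_SEX means the recurrence is
    plausibly sexual and each extra copy is counted as an additional
    lineage.  When the stratum holds fewer than ``min_power_genotypes``
    distinct MLGs the test has no power and recurrences are treated as
    clonal outright.

    Returns the total lineage count and the per-MLG verdicts.
    """
    n = len(labels)
    g = int(mlg_index.max()) + 1 if n else 0
    n_base = int(labels.max()) + 1 if n else 0
    results: list[PsexResult] = []
    extra = 0
    mult = np.bincount(mlg_index, minlength=g)
    lineage_of_mlg = {}
    for i in range(n):
        lineage_of_mlg[mlg_index[i]] = labels[i]
    for mlg in range(g):
        if mult[mlg] < 2:
            continue
        if g < min_power_genotypes:
            results.append(
                PsexResult(
                    mlg_id=mlg,
                    p_gen=float("nan"),
                    n_observed=int(mult[mlg]),
                    n_stratum=n,
                    p_sex=float("nan"),
                    alpha=alpha,
                    decision="low_power_clonal",
                )
            )
            continue
        lin = lineage_of_mlg[mlg]
        member_mlgs = unique_mlgs[
            np.unique(mlg_index[labels == lin])
        ]  # all MLGs of this lineage
        discordant = (member_mlgs != member_mlgs[0][None]).any(axis=(0, 2))
        geno = unique_mlgs[mlg].copy()
        geno[discordant] = 0
        called = ~(geno == 0).all(axis=1)
        pg = p_gen(geno, allele_freqs, f_is)
        ps = p_sex(pg, int(mult[mlg]), n)
        if ps < alpha:
            decision = "clonal"
        else:
            decision = "sexual_repeat"
            extra += int(mult[mlg]) - 1
        results.append(
            PsexResult(
                mlg_id=mlg,
                p_gen=pg,
                n_observed=int(mult[mlg]),
                n_stratum=n,
                p_sex=ps,
                alpha=alpha,
                decision=decision,
                loci_used=tuple(int(l) for l in np.flatnonzero(called)),
            )
        )
    return n_base + extra, results


def assign_lineages(
    genotypes: np.ndarray,
    allele_freqs: Sequence[Mapping[int, float]] | None = None,
    f_is: float = 0.0,
    max_mismatch_loci: int = 1,
    linkage: str = "single",
    alpha: float = 0.05,
    min_power_genotypes: int = 3,
) -> MLLPartition:
    """Full MLL workflow for one stratum.

    Clusters MLGs into lineages, picks representative genotypes, and (when
    ``allele_freqs`` is given) resolves recurrent MLGs by P_SEX.  Without
    frequencies, recurrences count as clonal and ``n_lineages`` equals the
    number of base lineages.
    """
    g, mlg_index, uniq = count_mlgs(genotypes)
    labels = cluster_mlls(genotypes, max_mismatch_loci=max_mismatch_loci, linkage=linkage)
    n_base = int(labels.max()) + 1
    reps = np.zeros((n_base, genotypes.shape[1], 2), dtype=np.int64)
    for lin in range(n_base):
        mlgs_here = np.unique(mlg_index[labels == lin])
        counts = [int((mlg_index == m).sum()) for m in mlgs_here]
        reps[lin] = representative_genotype(uniq[mlgs_here], counts)
    if allele_freqs is not None:
        n_lineages, results = resolve_recurrent_mlgs(
            labels,
            mlg_index,
            uniq,
            allele_freqs,
            f_is=f_is,
            alpha=alpha,
            min_power_genotypes=min_power_genotypes,
        )
    else:
        n_lineages, results = n_base, []
    return MLLPartition(
        labels=labels,
        mlg_index=mlg_index,
        unique_mlgs=uniq,
        representatives=reps,
        psex_results=results,
        n_lineages=n_lineages,
    )
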