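"""Hierarchical AMOVA, pairwise F_ST permutation tests, and the
null-allele-excluding (ENA) F_ST correction.

Differentiation statistics operate on clone-corrected individuals (one
multilocus-lineage representative each).  The inter-individual distance is
the codominant-allelic convention: per locus, the number of allele
differences between the two diploid genotypes (0, 1 or 2, the multiset
mismatch), summed over loci, with pairwise deletion of missing loci.
Variance components follow the standard nested molecular-variance
decomposition; significance comes from the usual nested permutation
schemes with the add-one convention p = (#{permuted >= observed} + 1) /
(permutations + 1), so p-values are never zero.

The ENA correction re-estimates allele frequencies with the EM null-allele
model, drops the null allele, and recomputes a frequency-based (gene-level
ANOVA) F_ST; per-pair 95% confidence intervals come from a percentile
bootstrap over loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import null_allele_em

__all__ = [
    "mismatch_distance_matrix",
    "gene_distance_matrix",
    "AmovaResult",
    "amova",
    "pairwise_fst",
    "fst_matrix",
    "FstMatrix",
    "theta_frequency",
    "fst_ena",
]


def mismatch_distance_matrix(
    genotypes: np.ndarray, metric: str = "codominant"
) -> np.ndarray:
    """Pairwise inter-individual squared genetic distance.

    ``metric="codominant"`` (default) is the codominant genotypic distance
    of the standard spreadsheet toolkit for such surveys: per locus, half
    the squared Euclidean distance between allele-count vectors, i.e.
    0 (identical genotypes), 1 (one shared allele replaced), 2 (disjoint
    heterozygotes), 3 (homozygote vs disjoint heterozygote) or
    4 (opposite homozygotes).  Being Euclidean-embeddable it feeds the
    molecular-variance decomposition without bias.

    ``metric="mismatch"`` is the simple per-locus allele mismatch count
    (0, 1 or 2; the multiset difference), kept as a cross-check variant.

    Loci missing in either colony are pair-deleted in both metrics.
    """
    if metric not in ("codominant", "mismatch"):
        raise ValueError("metric must be 'codominant' or 'mismatch'")
    geno = np.sort(np.asarray(genotypes, dtype=np.int64), axis=2)
    n, n_loci = geno.shape[0], geno.shape[1]
    d = np.zeros((n, n))
    for l in range(n_loci):
        a1 = geno[:, l, 0]
        a2 = geno[:, l, 1]
        called = a1 > 0
        e11 = (a1[:, None] == a1[None, :]).astype(np.int64)
        e22 = (a2[:, None] == a2[None, :]).astype(np.int64)
        e12 = (a1[:, None] == a2[None, :]).astype(np.int64)
        e21 = (a2[:, None] == a1[None, :]).astype(np.int64)
        if metric == "codominant":
            # 0.5 * ||y1 - y2||^2 on per-allele count vectors:
            # y1.y2 counts all cross-matches; ||y||^2 is 4 for homozygotes,
            # 2 for heterozygotes
            dot = e11 + e22 + e12 + e21
            s1 = np.where(a1 == a2, 4, 2)
            dl = (s1[:, None] + s1[None, :] - 2 * dot) / 2.0
        else:
            inter = np.maximum(e11 + e22, e12 + e21)
            dl = 2 - inter
        both = called[:, None] & called[None, :]
        d += np.where(both, dl, 0)
    np.fill_diagonal(d, 0.0)
    return d


def gene_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Squared distance between individual gene copies (allele mismatch
    indicators summed over loci, pairwise deletion of missing loci).

    Genotypes (n, n_loci, 2) expand to 2n gene units (copies of individual
    i at rows 2i and 2i+1); the molecular-variance decomposition runs on
    these units, matching the gene-level convention of the survey
    toolkit (total degrees of freedom 2N - 1).
    """
    geno = np.asarray(genotypes, dtype=np.int64)
    n, n_loci = geno.shape[0], geno.shape[1]
    genes = geno.transpose(0, 2, 1).reshape(2 * n, n_loci)
    d = np.zeros((2 * n, 2 * n))
    for l in range(n_loci):
        a = genes[:, l]
        called = a > 0
        dl = (a[:, None] != a[None, :]).astype(np.float64)
        both = called[:, None] & called[None, :]
        d += np.where(both, dl, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _expand_labels(labels: np.ndarray) -> np.ndarray:
    return np.repeat(np.asarray(labels), 2)


# ---------------------------------------------------------------------------
# sums of squares from a squared-distance matrix
# ---------------------------------------------------------------------------


def _ssd(d2: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Sum over groups of (sum of within-group pairwise squared distances) /
    group size -- the molecular-variance sum of squares."""
    total = 0.0
    for idx in groups:
        if len(idx) == 0:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == v) for v in pd.unique(labels)]


def _two_level_components(
    d2: np.ndarray, pop_labels: np.ndarray
) -> tuple[float, float, float]:
    """(sigma_a, sigma_w, F_ST) for populations vs total."""
    n = d2.shape[0]
    pops = _group_indices(pop_labels)
    p = len(pops)
    if p < 2:
        raise ValueError("need at least two populations")
    ss_total = _ssd(d2, [np.arange(n)])
    ss_wp = _ssd(d2, pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = p - 1, n - p
    if df_wp <= 0:
        raise ValueError("need more individuals than populations")
    ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
    sizes = np.array([len(g) for g in pops], dtype=float)
    n_c = (n - (sizes**2).sum() / n) / df_ap
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_c
    denom = sigma_a + sigma_w
    if denom <= 0:
        raise ValueError("total variance is zero: F_ST undefined (monomorphic data)")
    return sigma_a, sigma_w, sigma_a / denom


@dataclass
class AmovaResult:
    """Three-level nested molecular-variance decomposition."""

    components: pd.DataFrame  # source, df, SS, variance, percent
    f_rt: float
    f_sr: float
    f_st: float
    p_values: dict[str, float]

    def summary(self) -> pd.DataFrame:
        out = self.components.copy()
        stats = {
            "Among types": ("F_RT", self.f_rt),
            "Among regions within types": ("F_SR", self.f_sr),
            "Within regions": ("F_ST", self.f_st),
        }
        fcol = []
        for src in out["source"]:
            if src in stats:
                name, val = stats[src]
                p = self.p_values.get(name, float("nan"))
                fcol.append(f"{name} = {val:.3f} (p = {p:.3f})")
            else:
                fcol.append("")
        out["F"] = fcol
        return out


def _amova_components(
    d2: np.ndarray, type_labels: np.ndarray, region_labels: np.ndarray
) -> tuple[float, float, float, dict]:
    """(sigma_a, sigma_b, sigma_c, detail) for type / region-in-type /
    individual levels."""
    n = d2.shape[0]
    types = pd.unique(type_labels)
    combo = pd.Series(
        [f"{t}::{r}" for t, r in zip(type_labels, region_labels)]
    ).to_numpy()
    regions = pd.unique(combo)
    a, p = len(types), len(regions)
    type_groups = [np.flatnonzero(type_labels == t) for t in types]
    region_groups = [np.flatnonzero(combo == r) for r in regions]
    ss_total = _ssd(d2, [np.arange(n)])
    ss_wg = _ssd(d2, type_groups)
    ss_wp = _ssd(d2, region_groups)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    df_ag, df_ap, df_wp = a - 1, p - a, n - p
    detail = {
        "ss": (ss_ag, ss_ap, ss_wp, ss_total),
        "df": (df_ag, df_ap, df_wp),
        "n": n,
        "a": a,
        "p": p,
    }
    if df_wp <= 0:
        raise ValueError("need more individuals than regions")
    sigma_c = ss_wp / df_wp
    sizes_p = np.array([len(g) for g in region_groups], dtype=float)
    sizes_t = np.array([len(g) for g in type_groups], dtype=float)
    # unequal-sample-size coefficients of the nested expected mean squares
    s1 = 0.0
    for t, tg in zip(types, type_groups):
        in_t = [len(g) for g, r in zip(region_groups, regions) if r.startswith(f"{t}::")]
        s1 += sum(x * x for x in in_t) / len(tg)
    s2 = (sizes_p**2).sum() / n
    s3 = (sizes_t**2).sum() / n
    if df_ap > 0:
        n1 = (n - s1) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = float("nan")
    if df_ag > 0:
        n2 = (s1 - s2) / df_ag
        n3 = (n - s3) / df_ag
        ms_ag = ss_ag / df_ag
        b_term = 0.0 if np.isnan(sigma_b) else n2 * sigma_b
        sigma_a = (ms_ag - sigma_c - b_term) / n3
    else:
        sigma_a = float("nan")
    return sigma_a, sigma_b, sigma_c, detail


def amova(
    genotypes: np.ndarray,
    type_labels: Sequence,
    region_labels: Sequence,
    permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: types / regions within types / within regions.

    Components with a single unit at their level are reported as NaN (not
    estimable).  Permutation schemes: F_ST permutes individuals among
    regions regardless of type; F_SR permutes individuals among regions
    within their type; F_RT permutes whole regions among types.
    """
    type_labels = np.asarray(type_labels)
    region_labels = np.asarray(region_labels)
    d2 = gene_distance_matrix(genotypes)
    sigma_a, sigma_b, sigma_c, detail = _amova_components(
        d2, _expand_labels(type_labels), _expand_labels(region_labels)
    )
    total = (0.0 if np.isnan(sigma_a) else sigma_a) + (
        0.0 if np.isnan(sigma_b) else sigma_b
    ) + sigma_c
    f_rt = sigma_a / total if not np.isnan(sigma_a) else float("nan")
    f_sr = sigma_b / (sigma_b + sigma_c) if not np.isnan(sigma_b) else float("nan")
    f_st = (
        ((0.0 if np.isnan(sigma_a) else sigma_a) + (0.0 if np.isnan(sigma_b) else sigma_b))
        / total
    )
    ss_ag, ss_ap, ss_wp, ss_total = detail["ss"]
    df_ag, df_ap, df_wp = detail["df"]
    comp_vals = [sigma_a, sigma_b, sigma_c]
    components = pd.DataFrame(
        {
            "source": [
                "Among types",
                "Among regions within types",
                "Within regions",
                "Total",
            ],
            "df": [df_ag, df_ap, df_wp, df_ag + df_ap + df_wp],
            "SS": [ss_ag, ss_ap, ss_wp, ss_total],
            "variance": comp_vals + [total],
            "percent": [
                100.0 * v / total if not np.isnan(v) else float("nan")
                for v in comp_vals
            ]
            + [100.0],
        }
    )
    p_values: dict[str, float] = {}
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = len(type_labels)  # individuals; gene copies move in pairs
        ge_st = ge_sr = ge_rt = 0
        # region unit list for the F_RT scheme
        combo = np.array([f"{t}::{r}" for t, r in zip(type_labels, region_labels)])
        region_ids = pd.unique(combo)
        region_type = {r: r.split("::", 1)[0] for r in region_ids}
        region_members = {r: np.flatnonzero(combo == r) for r in region_ids}
        type_of_region = np.array([region_type[r] for r in region_ids])
        for _ in range(permutations):
            # F_ST: permute individuals anywhere
            perm = rng.permutation(n)
            try:
                sa, sb, sc, _ = _amova_components(
                    d2,
                    _expand_labels(type_labels[perm]),
                    _expand_labels(region_labels[perm]),
                )
                tot = (0 if np.isnan(sa) else sa) + (0 if np.isnan(sb) else sb) + sc
                if ((0 if np.isnan(sa) else sa) + (0 if np.isnan(sb) else sb)) / tot >= f_st:
                    ge_st += 1
            except ValueError:
                ge_st += 1
            # F_SR: permute individuals within type
            perm = np.arange(n)
            for t in pd.unique(type_labels):
                idx = np.flatnonzero(type_labels == t)
                perm[idx] = idx[rng.permutation(len(idx))]
            sa, sb, sc, _ = _amova_components(
                d2, _expand_labels(type_labels), _expand_labels(region_labels[perm])
            )
            if not np.isnan(sigma_b) and sb / (sb + sc) >= f_sr:
                ge_sr += 1
            # F_RT: permute whole regions among types
            shuffled = type_of_region[rng.permutation(len(region_ids))]
            t_perm = np.empty(n, dtype=type_labels.dtype)
            for r, t in zip(region_ids, shuffled):
                t_perm[region_members[r]] = t
            sa, sb, sc, _ = _amova_components(
                d2, _expand_labels(t_perm), _expand_labels(region_labels)
            )
            tot = (0 if np.isnan(sa) else sa) + (0 if np.isnan(sb) else sb) + sc
            if not np.isnan(sigma_a) and tot > 0 and sa / tot >= f_rt:
                ge_rt += 1
        p_values = {
            "F_ST": (ge_st + 1) / (permutations + 1),
            "F_SR": (ge_sr + 1) / (permutations + 1) if not np.isnan(sigma_b) else float("nan"),
            "F_RT": (ge_rt + 1) / (permutations + 1) if not np.isnan(sigma_a) else float("nan"),
        }
    return AmovaResult(
        components=components,
        f_rt=f_rt,
        f_sr=f_sr,
        f_st=f_st,
        p_values=p_values,
    )


def pairwise_fst(
    pop_a: np.ndarray,
    pop_b: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-population F_ST from the molecular-variance framework, with a
    permutation test shuffling individuals between the populations.

    Raises if the pooled data are monomorphic (F_ST undefined).
    """
    pop_a, pop_b = np.asarray(pop_a), np.asarray(pop_b)
    if pop_a.shape[0] < 2 or pop_b.shape[0] < 2:
        raise ValueError("each population needs >= 2 individuals")
    geno = np.concatenate([pop_a, pop_b], axis=0)
    labels = np.array([0] * pop_a.shape[0] + [1] * pop_b.shape[0])
    d2 = gene_distance_matrix(geno)
    _, _, fst = _two_level_components(d2, _expand_labels(labels))
    if permutations <= 0:
        return fst, float("nan")
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(permutations):
        perm = rng.permutation(len(labels))
        try:
            _, _, f = _two_level_components(d2, _expand_labels(labels[perm]))
        except ValueError:
            f = np.inf
        if f >= fst:
            ge += 1
    return fst, (ge + 1) / (permutations + 1)


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST matrix with permutation p-values."""

    labels: list[str]
    fst: pd.DataFrame
    p_values: pd.DataFrame

    def lower_triangle_table(self) -> pd.DataFrame:
        """Survey-table layout: F_ST below the diagonal, p above."""
        out = pd.DataFrame(
            np.zeros((len(self.labels), len(self.labels))),
            index=self.labels,
            columns=self.labels,
        )
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i > j:
                    out.iloc[i, j] = self.fst.loc[a, b]
                elif i < j:
                    out.iloc[i, j] = self.p_values.loc[a, b]
        return out


def fst_matrix(
    genotypes: np.ndarray,
    pop_labels: Sequence,
    permutations: int = 999,
    seed: int | None = None,
) -> FstMatrix:
    """All pairwise F_ST values with permutation p-values."""
    pop_labels = np.asarray(pop_labels)
    labels = list(pd.unique(pop_labels))
    k = len(labels)
    fst = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    pvals = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
    ss = np.random.SeedSequence(seed).spawn(k * k)
    for i in range(k):
        pvals.iloc[i, i] = np.nan
        for j in range(i + 1, k):
            a = genotypes[pop_labels == labels[i]]
            b = genotypes[pop_labels == labels[j]]
            f, p = pairwise_fst(
                a,
                b,
                permutations=permutations,
                seed=int(ss[i * k + j].generate_state(1)[0] % 2**31),
            )
            fst.iloc[i, j] = fst.iloc[j, i] = f
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return FstMatrix(labels=[str(x) for x in labels], fst=fst, p_values=pvals)


# ---------------------------------------------------------------------------
# frequency-based theta and the ENA null-allele correction
# ---------------------------------------------------------------------------


def _theta_locus_terms(
    freqs: list[dict[int, float]],
    n_ind: np.ndarray,
    het: list[dict[int, float]],
) -> tuple[float, float]:
    """Per-locus (numerator, denominator) of the Weir-Cockerham theta.

    ``freqs`` holds one allele-frequency map per population, ``n_ind`` the
    called individuals behind it, ``het`` the per-allele observed
    heterozygote frequency (fraction of individuals carrying the allele
    exactly once).  The a/b/c variance components follow the standard
    moment estimator; the multilocus theta is the ratio of their sums.
    """
    ok = n_ind > 0
    if ok.sum() < 2:
        return 0.0, 0.0
    freqs = [f for f, o in zip(freqs, ok) if o]
    het = [h for h, o in zip(het, ok) if o]
    n = n_ind[ok].astype(float)
    r = len(freqs)
    n_bar = n.mean()
    if n_bar <= 1:
        return 0.0, 0.0
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    alleles = sorted(set().union(*[set(f) for f in freqs]))
    num = den = 0.0
    for al in alleles:
        p = np.array([f.get(al, 0.0) for f in freqs])
        h = np.array([hh.get(al, 0.0) for hh in het])
        p_bar = (n * p).sum() / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n * h).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        num += a
        den += a + b + c
    return num, den


def theta_frequency(
    pop_freqs: Sequence[list[dict[int, float]]],
    pop_n_ind: Sequence[Sequence[float]],
    pop_het: Sequence[list[dict[int, float]]],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Multilocus Weir-Cockerham F_ST (ratio of summed a components to
    summed a+b+c over loci and alleles).

    ``pop_freqs[p][l]`` is the allele-frequency map of population p at
    locus l, ``pop_n_ind[p][l]`` the called individuals behind it, and
    ``pop_het[p][l]`` the per-allele heterozygote frequencies.  Returns
    (theta, per-locus numerators, per-locus denominators) so callers can
    bootstrap over loci.
    """
    n_loci = len(pop_freqs[0])
    nums = np.zeros(n_loci)
    dens = np.zeros(n_loci)
    for l in range(n_loci):
        freqs_l = [pf[l] for pf in pop_freqs]
        n_l = np.array([pn[l] for pn in pop_n_ind], dtype=float)
        het_l = [ph[l] for ph in pop_het]
        nums[l], dens[l] = _theta_locus_terms(freqs_l, n_l, het_l)
    if dens.sum() <= 0:
        raise ValueError("theta undefined: no variance at any locus")
    return float(nums.sum() / dens.sum()), nums, dens


def _pop_frequency_inputs(
    genotypes: np.ndarray, corrected: bool
) -> tuple[list[dict[int, float]], list[float], list[dict[int, float]]]:
    """Per-locus (freqs, n individuals, het frequencies) for one population.

    ``corrected=False`` (INA) uses observed allele and heterozygote
    frequencies.  ``corrected=True`` (ENA) replaces them with the EM
    null-allele-corrected visible frequencies and their Hardy-Weinberg
    expected heterozygote frequencies ``2 p (1 - p)`` -- excluding the
    null allele's footprint from both terms.
    """
    geno = np.sort(np.asarray(genotypes, dtype=np.int64), axis=2)
    freqs: list[dict[int, float]] = []
    n_ind: list[float] = []
    het: list[dict[int, float]] = []
    for l in range(geno.shape[1]):
        col = geno[:, l, :]
        called = col[:, 0] > 0
        n = float(called.sum())
        n_ind.append(n)
        if corrected:
            _, vis, _ = null_allele_em(col)
            freqs.append(vis)
            het.append({a: 2.0 * p * (1.0 - p) for a, p in vis.items()})
        else:
            sub = col[called]
            cnt: dict[int, float] = {}
            hcnt: dict[int, float] = {}
            for a, b in sub:
                cnt[int(a)] = cnt.get(int(a), 0.0) + 1.0
                cnt[int(b)] = cnt.get(int(b), 0.0) + 1.0
                if a != b:
                    hcnt[int(a)] = hcnt.get(int(a), 0.0) + 1.0
                    hcnt[int(b)] = hcnt.get(int(b), 0.0) + 1.0
            freqs.append({a: c / (2 * n) for a, c in cnt.items()} if n else {})
            het.append({a: hcnt.get(a, 0.0) / n for a in cnt} if n else {})
    return freqs, n_ind, het


def fst_ena(
    genotypes: np.ndarray,
    pop_labels: Sequence,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> dict:
    """Pairwise F_ST including (INA) and excluding (ENA) null alleles.

    For every population pair both matrices come from the frequency-based
    theta; the ENA variant replaces observed allele frequencies with the
    EM null-allele-corrected visible frequencies.  Percentile 95%
    confidence intervals per pair come from ``bootstrap_reps`` resamples of
    loci with replacement.  When the estimated null frequencies are all
    zero the two matrices coincide.
    """
    geno = np.asarray(genotypes)
    if geno.shape[1] < 2:
        raise ValueError("locus bootstrap needs >= 2 loci")
    pop_labels = np.asarray(pop_labels)
    labels = list(pd.unique(pop_labels))
    inputs_ina = {}
    inputs_ena = {}
    for lab in labels:
        sub = geno[pop_labels == lab]
        inputs_ina[lab] = _pop_frequency_inputs(sub, corrected=False)
        inputs_ena[lab] = _pop_frequency_inputs(sub, corrected=True)
    k = len(labels)
    ina = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    ena = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    ci_ina: dict[tuple, tuple[float, float]] = {}
    ci_ena: dict[tuple, tuple[float, float]] = {}
    rng = np.random.default_rng(seed)
    n_loci = geno.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            pair = (labels[i], labels[j])
            for inputs, mat, cis in (
                (inputs_ina, ina, ci_ina),
                (inputs_ena, ena, ci_ena),
            ):
                pf = [inputs[labels[i]][0], inputs[labels[j]][0]]
                pn = [inputs[labels[i]][1], inputs[labels[j]][1]]
                ph = [inputs[labels[i]][2], inputs[labels[j]][2]]
                theta, nums, dens = theta_frequency(pf, pn, ph)
                mat.iloc[i, j] = mat.iloc[j, i] = theta
                if bootstrap_reps > 0:
                    reps = np.empty(bootstrap_reps)
                    picks = rng.integers(0, n_loci, size=(bootstrap_reps, n_loci))
                    for b in range(bootstrap_reps):
                        d = dens[picks[b]].sum()
                        reps[b] = nums[picks[b]].sum() / d if d > 0 else 0.0
                    cis[pair] = (
                        float(np.percentile(reps, 2.5)),
                        float(np.percentile(reps, 97.5)),
                    )
    return {
        "labels": [str(x) for x in labels],
        "ina": ina,
        "ena": ena,
        "ina_ci": ci_ina,
        "ena_ci": ci_ena,
    }
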