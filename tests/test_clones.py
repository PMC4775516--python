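"""Multilocus genotype/lineage calling, P_SEX and clonal diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonalpop.clones import (
    assign_lineages,
    clonal_richness,
    cluster_mlls,
    count_mlgs,
    genotype_mismatch_loci,
    p_gen,
    p_sex,
    representative_genotype,
    resolve_recurrent_mlgs,
)


def g(*pairs):
    """Genotype literal: g((a,b),(c,d),...) -> (n_loci, 2) array."""
    return np.array(pairs, dtype=np.int64)


# ---------------------------------------------------------------------------
# MLG counting and clustering
# ---------------------------------------------------------------------------


def test_count_mlgs_identical_and_distinct():
    same = np.stack([g((1, 2), (3, 3))] * 3)
    assert count_mlgs(same)[0] == 1
    distinct = np.stack([g((1, 2), (3, 3)), g((1, 1), (3, 3)), g((1, 2), (3, 4))])
    assert count_mlgs(distinct)[0] == 3


def test_count_mlgs_missing_matches_only_missing():
    pair = np.stack([g((0, 0), (3, 3)), g((1, 2), (3, 3))])
    assert count_mlgs(pair)[0] == 2


def test_generator_ground_truth_mlg_count(sim):
    ds, _, truth = sim(genets_per_site=5, ramet_mean=2.4, seed=3)
    G, _, _ = count_mlgs(ds.genotypes)
    assert G == truth.colonies["genet_id"].nunique()


def _random_geno(rng, n, n_loci=8):
    return rng.integers(1, 4, size=(n, n_loci, 2))


def test_one_locus_difference_merges_two_loci_splits():
    a = g(*[(1, 2)] * 8)
    b = a.copy()
    b[0] = (3, 3)  # one locus off -> clones
    c = a.copy()
    c[0] = (4, 4)
    c[1] = (5, 5)  # two loci off from both -> distinct
    labels = cluster_mlls(np.stack([a, b, c]), max_mismatch_loci=1)
    assert labels[0] == labels[1] != labels[2]


def test_single_linkage_chain_closure():
    a = g(*[(1, 1)] * 8)
    b = a.copy()
    b[0] = (2, 2)
    c = b.copy()
    c[1] = (3, 3)  # a-b differ at 1, b-c at 1, a-c at 2
    stack = np.stack([a, b, c])
    labels = cluster_mlls(stack, max_mismatch_loci=1, linkage="single")
    assert len(set(labels)) == 1
    # exhaustive pairwise component search as an independent check
    n = 3
    adj = {
        (i, j): genotype_mismatch_loci(stack[i], stack[j]) <= 1
        for i, j in itertools.combinations(range(n), 2)
    }
    comp = list(range(n))
    for (i, j), linked in adj.items():
        if linked:
            old, new = comp[j], comp[i]
            comp = [new if x == old else x for x in comp]
    assert len(set(comp)) == 1
    # strict-clique alternative refuses the chain
    clique = cluster_mlls(stack, max_mismatch_loci=1, linkage="clique")
    assert len(set(clique)) == 2


def test_zero_mismatch_reduces_to_mlgs():
    rng = np.random.default_rng(1)
    geno = _random_geno(rng, 30)
    labels = cluster_mlls(geno, max_mismatch_loci=0)
    assert len(set(labels)) == count_mlgs(geno)[0]


def test_lineage_count_monotone_in_mismatch_threshold():
    rng = np.random.default_rng(2)
    geno = _random_geno(rng, 40)
    counts = [
        len(set(cluster_mlls(geno, max_mismatch_loci=m))) for m in range(0, 4)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_mismatch_threshold_bounds():
    geno = _random_geno(np.random.default_rng(0), 4)
    with pytest.raises(ValueError):
        cluster_mlls(geno, max_mismatch_loci=8)


# ---------------------------------------------------------------------------
# representative genotypes
# ---------------------------------------------------------------------------


def test_representative_is_modal_genotype():
    g1 = g((1, 2), (3, 3), (5, 6))
    g2 = g((1, 2), (3, 4), (5, 6))
    rep = representative_genotype(np.stack([g1, g2]), counts=[2, 1])
    np.testing.assert_array_equal(rep, g1)


def test_representative_tie_zeroes_disputed_locus():
    g1 = g((1, 2), (3, 3), (5, 6))
    g2 = g((1, 2), (3, 4), (5, 6))
    rep = representative_genotype(np.stack([g1, g2]), counts=[1, 1])
    np.testing.assert_array_equal(rep[0], (1, 2))
    np.testing.assert_array_equal(rep[1], (0, 0))  # disputed -> missing
    np.testing.assert_array_equal(rep[2], (5, 6))


def test_representative_singleton():
    g1 = g((1, 2), (3, 3))
    np.testing.assert_array_equal(representative_genotype(g1[None]), g1)


# ---------------------------------------------------------------------------
# P_GEN / P_SEX
# ---------------------------------------------------------------------------


def test_p_gen_degenerate_frequency():
    assert p_gen(g((5, 5)), [{5: 1.0}], f_is=0.0) == 1.0


def test_p_gen_hardy_weinberg_heterozygote():
    # 2 * 0.5 * 0.5 by direct enumeration
    assert p_gen(g((1, 2)), [{1: 0.5, 2: 0.5}], f_is=0.0) == pytest.approx(0.5)


def test_p_gen_full_inbreeding_limit():
    # with F_IS = 1, P(aa) = f_a
    assert p_gen(g((1, 1)), [{1: 0.5, 2: 0.5}], f_is=1.0) == pytest.approx(0.5)


def test_p_gen_skips_missing_and_rejects_unknown_allele():
    assert p_gen(g((0, 0), (1, 2)), [{9: 1.0}, {1: 0.5, 2: 0.5}]) == pytest.approx(0.5)
    with pytest.raises(KeyError):
        p_gen(g((7, 7)), [{1: 1.0}])


def test_p_sex_binomial_tail():
    assert p_sex(1.0, 3, 10) == 1.0
    assert p_sex(0.0, 2, 10) == 0.0
    # 1 - 0.9^10 - 10 * 0.1 * 0.9^9, by direct binomial sum
    assert p_sex(0.1, 2, 10) == pytest.approx(0.26390107, abs=1e-8)


def test_p_sex_matches_small_monte_carlo():
    rng = np.random.default_rng(12)
    draws = rng.binomial(30, 0.05, size=200_000)
    mc = (draws >= 2).mean()
    se = np.sqrt(mc * (1 - mc) / 200_000)
    assert abs(p_sex(0.05, 2, 30) - mc) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# recurrent-MLG resolution and richness
# ---------------------------------------------------------------------------


def _stratum(rows):
    geno = np.stack(rows)
    G, mlg_index, uniq = count_mlgs(geno)
    labels = cluster_mlls(geno, max_mismatch_loci=1)
    return geno, labels, mlg_index, uniq


def test_common_recurrent_mlg_is_sexual_repeat():
    # near-monomorphic pool: the doubled common genotype is unsurprising
    # under sexual reproduction, so the copies count as separate lineages
    freqs = [{1: 0.9, 2: 0.1}] * 2
    common = g((1, 1), (1, 1))
    others = [g((1, 2), (1, 1)), g((2, 2), (1, 2)), g((1, 1), (1, 2))]
    geno, labels, mlg_index, uniq = _stratum([common, common] + others)
    n_lineages, results = resolve_recurrent_mlgs(
        labels, mlg_index, uniq, freqs, f_is=0.0, alpha=0.05
    )
    res = [r for r in results if r.n_observed == 2][0]
    assert res.decision == "sexual_repeat" and res.p_sex >= 0.05


def test_rare_recurrent_mlg_is_clonal():
    # ten-locus rare genotype: p_gen is tiny, recurrence must be clonal
    freqs = [{1: 0.1, 2: 0.9}] * 10
    rare = g(*[(1, 1)] * 10)
    others = [g(*[(2, 2)] * 10), g(*[(1, 2)] * 10)]
    geno, labels, mlg_index, uniq = _stratum([rare, rare] + others)
    n_lineages, results = resolve_recurrent_mlgs(
        labels, mlg_index, uniq, freqs, f_is=0.0, alpha=0.05
    )
    res = [r for r in results if r.n_observed == 2][0]
    assert res.decision == "clonal" and res.p_sex < 0.05
    assert n_lineages == 3


def test_low_power_stratum_treated_as_clonal():
    # a single MLG observed many times: no power, assume clonality
    freqs = [{1: 0.5, 2: 0.5}] * 8
    one = g(*[(1, 2)] * 8)
    geno, labels, mlg_index, uniq = _stratum([one] * 20)
    n_lineages, results = resolve_recurrent_mlgs(
        labels, mlg_index, uniq, freqs, min_power_genotypes=3
    )
    assert n_lineages == 1
    assert results[0].decision == "low_power_clonal"


def test_discordant_locus_excluded_from_psex():
    # the lineage carries a somatic variant at locus 0; that locus must not
    # enter the recurrent MLG's genotype probability
    freqs = [{1: 0.5, 2: 0.5}] * 9
    base = g(*[(1, 2)] * 9)
    variant = base.copy()
    variant[0] = (1, 1)
    others = [g(*[(2, 2)] * 9), g(*[(1, 1)] * 9)]
    geno, labels, mlg_index, uniq = _stratum([base, base, variant] + others)
    _, results = resolve_recurrent_mlgs(labels, mlg_index, uniq, freqs)
    res = [r for r in results if r.n_observed == 2][0]
    assert 0 not in res.loci_used
    assert res.p_gen == pytest.approx(0.5 ** 8)


@pytest.mark.parametrize(
    "n,mll,expected",
    [(53, 10, 0.17), (19, 19, 1.00), (24, 1, 0.00), (44, 7, 0.14)],
)
def test_clonal_richness_worked_examples(n, mll, expected):
    assert round(clonal_richness(n, mll), 2) == expected


def test_clonal_richness_undefined_for_single_colony():
    assert np.isnan(clonal_richness(1, 1))
    with pytest.raises(ValueError):
        clonal_richness(3, 4)


def test_assign_lineages_invariants(sim):
    ds, _, _ = sim(genets_per_site=15, ramet_mean=2.0, somatic_mu=0.002, seed=6)
    part = assign_lineages(ds.genotypes)
    n = ds.n_colonies
    G = int(part.mlg_index.max()) + 1
    assert part.n_base <= G <= n
    s = part.summary()
    assert 0.0 <= s.R <= 1.0


def test_simulated_genets_recovered_exactly(sim):
    """With no somatic mutation and well-separated genets the lineage
    partition equals the generator's genet partition."""
    ds, _, truth = sim(genets_per_site=12, ramet_mean=2.5, alleles_per_locus=12, seed=8)
    genets = pd.factorize(truth.colonies["genet_id"])[0]
    # precondition: distinct genets differ at >= 3 loci
    _, _, uniq = count_mlgs(ds.genotypes)
    reps = {}
    for i, gid in enumerate(genets):
        reps.setdefault(gid, ds.genotypes[i])
    ids = list(reps)
    for a, b in itertools.combinations(ids, 2):
        assert genotype_mismatch_loci(reps[a], reps[b]) >= 3
    labels = cluster_mlls(ds.genotypes, max_mismatch_loci=1)
    same_label = labels[:, None] == labels[None, :]
    same_genet = genets[:, None] == genets[None, :]
    np.testing.assert_array_equal(same_label, same_genet)
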