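"""Heterozygosity, rarefaction, EM null alleles and the Bayesian
null-allele/inbreeding models."""

import itertools

import numpy as np
import pytest

from clonalpop.diversity import (
    NullAlleleInbreedingModel,
    allele_frequencies,
    allelic_richness,
    compare_inbreeding_models,
    default_rarefaction_size,
    f_is_estimate,
    heterozygosity,
    hpd_interval,
    null_allele_em,
)


def geno_from_locus(pairs):
    """(n, 1, 2) genotype array from a list of allele pairs."""
    return np.array(pairs, dtype=np.int64)[:, None, :]


# ---------------------------------------------------------------------------
# frequencies and heterozygosity
# ---------------------------------------------------------------------------


def test_allele_frequency_counting():
    geno = geno_from_locus([(1, 1), (1, 2)])
    freqs, counts = allele_frequencies(geno)
    assert freqs[0] == {1: 0.75, 2: 0.25}
    assert counts[0] == {1: 3, 2: 1}


def test_all_missing_locus_flagged_empty():
    geno = geno_from_locus([(0, 0), (0, 0)])
    freqs, _ = allele_frequencies(geno)
    assert freqs[0] == {}


def test_clone_corrected_frequencies_via_representatives():
    # ten ramets of one a/b genet reduce to a single representative
    ramets = geno_from_locus([(1, 2)] * 10)
    rep = geno_from_locus([(1, 2)])
    assert allele_frequencies(rep)[0][0] == {1: 0.5, 2: 0.5}
    assert allele_frequencies(ramets)[0][0] == {1: 0.5, 2: 0.5}


def test_observed_heterozygosity_extremes():
    all_het = geno_from_locus([(1, 2), (1, 2), (1, 3)])
    assert heterozygosity(all_het)["H_O"].iloc[0] == 1.0
    mono = geno_from_locus([(1, 1), (1, 1), (1, 1)])
    assert heterozygosity(mono)["H_E"].iloc[0] == 0.0


def test_unbiased_expected_heterozygosity_closed_form():
    # n = 5 diploids, two alleles at 0.5: H_E = 0.5 * 10/9
    geno = geno_from_locus([(1, 2), (1, 2), (1, 2), (1, 1), (2, 2)])
    h = heterozygosity(geno)
    assert h["H_E"].iloc[0] == pytest.approx(0.5 * 10 / 9)
    assert h["H_E"].iloc[0] == pytest.approx(0.5556, abs=5e-5)


def test_f_is_extremes_and_recovery(sim):
    he_only = geno_from_locus([(1, 1), (2, 2), (1, 1), (2, 2)])
    fis, _ = f_is_estimate(he_only)
    assert fis == pytest.approx(1.0)
    balanced = geno_from_locus([(1, 2), (1, 2), (1, 1), (2, 2)])
    fis_b, per = f_is_estimate(balanced)
    assert fis_b == pytest.approx(1 - 0.5 / ((1 - 0.5) * 8 / 7))
    # parameter recovery: planted F_IS = 0.2 at n = 500, 8 loci
    ds, _, _ = sim(genets_per_site=500, f_is=0.2, alleles_per_locus=12, seed=13)
    fis_hat, _ = f_is_estimate(ds.genotypes)
    assert abs(fis_hat - 0.2) < 0.05


def test_f_is_undefined_when_monomorphic():
    mono = geno_from_locus([(1, 1), (1, 1)])
    fis, _ = f_is_estimate(mono)
    assert np.isnan(fis)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------


def test_rarefaction_at_full_size_is_allele_count():
    geno = geno_from_locus([(1, 2), (3, 3), (1, 4)])
    mean_ar, _ = allelic_richness(geno, g=6)
    assert mean_ar == 4.0


def test_rarefaction_exhaustive_enumeration_oracle():
    # counts (9, 1): expected distinct alleles among all C(10, 2) pairs
    pairs = [(1, 1)] * 4 + [(1, 2)]
    geno = geno_from_locus(pairs)
    mean_ar, _ = allelic_richness(geno, g=2)
    genes = [1] * 9 + [2]
    expected = np.mean(
        [len(set(c)) for c in itertools.combinations(genes, 2)]
    )
    assert mean_ar == pytest.approx(expected)
    assert mean_ar == pytest.approx(1.2)


def test_rarefaction_monomorphic_and_monotone():
    mono = geno_from_locus([(1, 1)] * 6)
    assert allelic_richness(mono, g=4)[0] == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    geno = rng.integers(1, 6, size=(20, 3, 2))
    values = [allelic_richness(geno, g)[0] for g in range(2, 40, 4)]
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        allelic_richness(geno, g=1)


def test_default_rarefaction_size():
    a = geno_from_locus([(1, 2)] * 10)
    b = geno_from_locus([(1, 2)] * 4 + [(0, 0)])
    assert default_rarefaction_size([a, b]) == 8


# ---------------------------------------------------------------------------
# EM null-allele estimator
# ---------------------------------------------------------------------------


def test_em_zero_at_exact_hardy_weinberg():
    pairs = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
    r, vis, converged = null_allele_em(np.array(pairs))
    assert converged and r < 1e-6
    assert vis[1] == pytest.approx(0.5, abs=1e-6)


def test_em_uninformative_monomorphic_locus():
    r, _, _ = null_allele_em(np.array([(1, 1)] * 30))
    assert r == 0.0


def test_em_recovers_planted_null_frequency(sim):
    ds, _, _ = sim(genets_per_site=500, null_rate=0.2, missing_rate=0.0, seed=2)
    ests = [null_allele_em(ds.genotypes[:, l, :])[0] for l in range(ds.n_loci)]
    assert abs(np.mean(ests) - 0.2) < 0.05


# ---------------------------------------------------------------------------
# Bayesian individual-inbreeding model
# ---------------------------------------------------------------------------


def test_hpd_interval_shortest():
    x = np.concatenate([np.zeros(90), np.ones(10)])
    lo, hi = hpd_interval(x, 0.9)
    assert (lo, hi) == (0.0, 0.0)


def test_gibbs_clean_data_posteriors_small(sim):
    """No nulls, no inbreeding: both posterior means stay below 0.05."""
    for seed in range(3):
        ds, _, _ = sim(genets_per_site=200, missing_rate=0.02, seed=30 + seed)
        res = NullAlleleInbreedingModel(ds.genotypes, "nfb").fit(
            burn_in=1000, cycles=6000, thin=10, seed=seed
        )
        assert res.avg_fi < 0.05
        assert res.null_freq < 0.05


def test_gibbs_fixed_seed_bit_identical(sim):
    ds, _, _ = sim(genets_per_site=60, null_rate=0.05, missing_rate=0.02, seed=5)
    m = NullAlleleInbreedingModel(ds.genotypes, "nfb")
    r1 = m.fit(burn_in=500, cycles=3000, thin=5, seed=11)
    r2 = m.fit(burn_in=500, cycles=3000, thin=5, seed=11)
    assert r1.avg_fi == r2.avg_fi and r1.dic == r2.dic
    np.testing.assert_array_equal(r1.draws["null_freq"], r2.draws["null_freq"])


def test_gibbs_chain_validation(sim):
    ds, _, _ = sim(genets_per_site=20, seed=1)
    with pytest.raises(ValueError):
        NullAlleleInbreedingModel(ds.genotypes).fit(burn_in=100, cycles=50)
    with pytest.raises(ValueError):
        NullAlleleInbreedingModel(ds.genotypes, model="bad")


def test_model_selection_prefers_nb_without_inbreeding(sim):
    """On inbreeding-free data the simpler nb model wins DIC in >= 7/10
    simulated replicates."""
    wins = 0
    for seed in range(10):
        ds, _, _ = sim(
            genets_per_site=100, null_rate=0.05, missing_rate=0.02, seed=50 + seed
        )
        nfb, nb, _ = compare_inbreeding_models(
            ds.genotypes, burn_in=800, cycles=4800, thin=10, seed=seed
        )
        wins += nb.dic <= nfb.dic
    assert wins >= 7


def test_em_and_gibbs_agree_without_inbreeding(sim):
    """Invariant: EM estimate and Gibbs posterior mean agree within 0.05
    on a large sample without inbreeding."""
    ds, _, _ = sim(genets_per_site=500, null_rate=0.1, missing_rate=0.02, seed=77)
    em = np.mean([null_allele_em(ds.genotypes[:, l, :])[0] for l in range(ds.n_loci)])
    res = NullAlleleInbreedingModel(ds.genotypes, "nb").fit(
        burn_in=800, cycles=4800, thin=10, seed=7
    )
    assert abs(em - res.null_freq) < 0.05
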