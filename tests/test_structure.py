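"""Admixture clustering, Evanno dK, replicate alignment, cross-type flags."""

import numpy as np
import pandas as pd
import pytest

from clonalpop.structure import (
    AdmixtureModel,
    align_replicates,
    evanno_delta_k,
    flag_cross_type,
    run_k_scan,
)


def _lnpd_table(means, sd_offset=np.sqrt(2) / 2):
    """Two replicates per K with per-K mean `means[K-1]` and sd exactly 1;
    the same offset pattern at every K keeps replicate-wise second
    differences equal to the means' second differences."""
    rows = []
    for k, m in enumerate(means, start=1):
        rows.append({"K": k, "replicate": 0, "lnPD": m + sd_offset})
        rows.append({"K": k, "replicate": 1, "lnPD": m - sd_offset})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evanno dK
# ---------------------------------------------------------------------------


def test_evanno_hand_arithmetic():
    # means (-100, -80, -75, -74), sd = 1: dK(2) = 15, dK(3) = 4
    table = _lnpd_table([-100.0, -80.0, -75.0, -74.0])
    dk, best = evanno_delta_k(table)
    dk = dk.set_index("K")
    assert dk.loc[2, "delta_K"] == pytest.approx(15.0)
    assert dk.loc[3, "delta_K"] == pytest.approx(4.0)
    assert np.isnan(dk.loc[1, "delta_K"]) and np.isnan(dk.loc[4, "delta_K"])
    assert best == 2


def test_evanno_linear_lnpd_gives_zero():
    table = _lnpd_table([-100.0, -90.0, -80.0, -70.0])
    dk, _ = evanno_delta_k(table)
    assert np.allclose(dk["delta_K"].dropna(), 0.0)


def test_evanno_zero_sd_names_offending_k():
    table = _lnpd_table([-10.0, -9.0, -8.0], sd_offset=0.0)
    with pytest.raises(ValueError, match="K=2"):
        evanno_delta_k(table)


def test_evanno_input_validation():
    with pytest.raises(ValueError, match="3 consecutive"):
        evanno_delta_k(_lnpd_table([-10.0, -9.0]))
    table = _lnpd_table([-10.0, -9.0, -8.0])
    with pytest.raises(ValueError, match="consecutive"):
        evanno_delta_k(table[table["K"] != 2])


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def test_k1_trivial_run(sim):
    ds, _, _ = sim(genets_per_site=15, seed=2)
    res = AdmixtureModel(ds.genotypes, K=1).fit(burn_in=100, reps=400, seed=0)
    np.testing.assert_allclose(res.Q, 1.0)
    assert np.isfinite(res.ln_pd)


def test_q_and_p_normalization(sim):
    ds, _, _ = sim(genets_per_site=20, alleles_per_locus=6, seed=3)
    model = AdmixtureModel(ds.genotypes, K=3)
    res = model.fit(burn_in=200, reps=800, seed=1)
    np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-9)
    for l in range(ds.n_loci):
        na = model.n_alleles[l]
        np.testing.assert_allclose(res.P[:, l, :na].sum(axis=1), 1.0, atol=1e-9)


def test_fixed_seed_reproducible(sim):
    ds, _, _ = sim(genets_per_site=15, seed=4)
    m = AdmixtureModel(ds.genotypes, K=2)
    r1 = m.fit(burn_in=200, reps=500, seed=9)
    r2 = m.fit(burn_in=200, reps=500, seed=9)
    np.testing.assert_array_equal(r1.Q, r2.Q)
    assert r1.ln_pd == r2.ln_pd


def test_two_cluster_recovery(sim):
    ds, _, truth = sim(
        n_types=2, genets_per_site=20, type_drift=0.2, alleles_per_locus=10, seed=11
    )
    res = AdmixtureModel(ds.genotypes, K=2).fit(burn_in=2000, reps=8000, seed=1)
    assert res.Q.max(axis=1).mean() > 0.9
    top = res.Q.argmax(axis=1)
    true = pd.factorize(truth.colonies["true_type"])[0]
    agreement = max((top == true).mean(), (top != true).mean())
    assert agreement > 0.95


def test_fit_validation(sim):
    ds, _, _ = sim(genets_per_site=5, seed=0)
    with pytest.raises(ValueError):
        AdmixtureModel(ds.genotypes, K=0)
    with pytest.raises(ValueError):
        AdmixtureModel(ds.genotypes, K=2).fit(burn_in=10, reps=0)


# ---------------------------------------------------------------------------
# replicate alignment
# ---------------------------------------------------------------------------


def test_align_identical_runs():
    rng = np.random.default_rng(0)
    q = rng.dirichlet(np.ones(3), size=12)
    perms, consensus = align_replicates([q, q.copy()])
    assert perms[1] == (0, 1, 2)
    np.testing.assert_allclose(consensus, q)
    np.testing.assert_allclose(consensus.sum(axis=1), 1.0)


def test_align_recovers_known_permutation():
    rng = np.random.default_rng(1)
    q = rng.dirichlet(np.full(4, 0.3), size=20)
    perm = (2, 0, 3, 1)
    shuffled = q[:, perm]
    perms, consensus = align_replicates([q, shuffled])
    np.testing.assert_allclose(shuffled[:, perms[1]], q)
    np.testing.assert_allclose(consensus, q)


def test_align_rejects_mismatched_runs():
    q = np.full((5, 2), 0.5)
    with pytest.raises(ValueError):
        align_replicates([q, np.full((6, 2), 0.5)])
    with pytest.raises(ValueError):
        align_replicates([q])


# ---------------------------------------------------------------------------
# cross-type flagging
# ---------------------------------------------------------------------------


def test_flagging_rules():
    # individuals 0-3 mtL in cluster 0; 4-7 mtS in cluster 1; individual 8
    # is labelled mtL but sits in the mtS cluster with high ancestry
    q = np.array(
        [[0.95, 0.05]] * 4 + [[0.05, 0.95]] * 4 + [[0.10, 0.90]]
    )
    mito = ["mtL"] * 4 + ["mtS"] * 4 + ["mtL"]
    flags, cmap = flag_cross_type(q, mito, q_flag=0.5)
    assert cmap == {0: "mtL", 1: "mtS"}
    assert list(flags) == [False] * 8 + [True]


def test_flagging_respects_threshold():
    q = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]] * 3 + [[0.45, 0.55]])
    mito = ["mtL"] * 3 + ["mtS"] * 3 + ["mtL"]
    flags, _ = flag_cross_type(q, mito, q_flag=0.6)
    assert not flags[-1]  # 0.55 below the 0.6 ancestry threshold


def test_flagging_no_majority_raises():
    q = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    mito = ["mtL", "mtS", "mtL", "mtS"]
    with pytest.raises(ValueError, match="majority"):
        flag_cross_type(q, mito)


def test_planted_mislabels_are_flagged(sim):
    ds, _, truth = sim(
        n_types=2,
        genets_per_site=25,
        type_drift=0.25,
        alleles_per_locus=10,
        n_mislabeled=2,
        seed=21,
    )
    res = AdmixtureModel(ds.genotypes, K=2).fit(burn_in=2000, reps=8000, seed=2)
    flags, _ = flag_cross_type(
        res.Q, ds.colonies["mito_type"].to_numpy(), q_flag=0.5
    )
    expected = truth.colonies["mislabeled"].to_numpy()
    np.testing.assert_array_equal(flags, expected)


# ---------------------------------------------------------------------------
# K scan
# ---------------------------------------------------------------------------


def test_k_scan_produces_delta_k_table(sim):
    ds, _, _ = sim(n_types=2, genets_per_site=15, type_drift=0.2, seed=6)
    table = run_k_scan(
        ds.genotypes, [1, 2, 3], replicates=2, burn_in=300, reps=1200, seed=5
    )
    assert len(table.ln_pd_table) == 6
    assert table.delta_k is not None and table.best_k in (2,)
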