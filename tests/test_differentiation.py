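"""AMOVA, pairwise F_ST permutation tests and the ENA correction."""

import numpy as np
import pandas as pd
import pytest

from clonalpop.differentiation import (
    amova,
    fst_ena,
    fst_matrix,
    gene_distance_matrix,
    mismatch_distance_matrix,
    pairwise_fst,
)


def geno(rows):
    return np.array(rows, dtype=np.int64)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_genotypic_distance_scale():
    a = geno([[(1, 1)], [(1, 2)], [(2, 2)], [(2, 3)], [(3, 4)]])
    d = mismatch_distance_matrix(a, metric="codominant")
    assert d[0, 1] == 1  # aa vs ab
    assert d[0, 2] == 4  # aa vs bb
    assert d[0, 3] == 3  # aa vs bc
    assert d[1, 3] == 1  # ab vs bc
    assert d[1, 4] == 2  # ab vs cd
    dm = mismatch_distance_matrix(a, metric="mismatch")
    assert dm[0, 2] == 2 and dm[0, 1] == 1


def test_pairwise_deletion_of_missing_loci():
    a = geno([[(1, 1), (5, 5)], [(2, 2), (0, 0)]])
    d = mismatch_distance_matrix(a)
    assert d[0, 1] == 4  # only the called locus contributes


# ---------------------------------------------------------------------------
# brute-force nested-ANOVA oracle
# ---------------------------------------------------------------------------


def brute_force_amova(genotypes, types, regions):
    """Spreadsheet-style evaluation of the three-level decomposition on
    gene copies: one-hot allele vectors, sums of squares from deviations
    about group centroids, variance components from the expected
    mean-square identities written out longhand."""
    genotypes = np.asarray(genotypes)
    n_ind, n_loci = genotypes.shape[0], genotypes.shape[1]
    # gene units: vector per gene copy, one-hot over alleles, scaled so the
    # squared distance between two genes equals the allele mismatch count
    alleles = [
        sorted({int(a) for a in genotypes[:, l, :].ravel() if a > 0})
        for l in range(n_loci)
    ]
    vecs, t_lab, r_lab = [], [], []
    for i in range(n_ind):
        for c in range(2):
            v = []
            for l in range(n_loci):
                one = [0.0] * len(alleles[l])
                a = genotypes[i, l, c]
                if a > 0:
                    one[alleles[l].index(int(a))] = 1.0
                v.extend(x / np.sqrt(2.0) for x in one)
            vecs.append(v)
            t_lab.append(types[i])
            r_lab.append(f"{types[i]}::{regions[i]}")
    vecs = np.array(vecs)
    n = len(vecs)

    def ss_about_centroid(idx):
        sub = vecs[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    all_idx = list(range(n))
    type_groups = {t: [i for i in all_idx if t_lab[i] == t] for t in set(t_lab)}
    region_groups = {r: [i for i in all_idx if r_lab[i] == r] for r in set(r_lab)}
    ss_total = ss_about_centroid(all_idx)
    ss_wg = sum(ss_about_centroid(ix) for ix in type_groups.values())
    ss_wp = sum(ss_about_centroid(ix) for ix in region_groups.values())
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    a_count, p_count = len(type_groups), len(region_groups)
    df_ag, df_ap, df_wp = a_count - 1, p_count - a_count, n - p_count
    sigma_c = ss_wp / df_wp
    # unequal-size coefficients, written out
    s1 = 0.0
    for t, tg in type_groups.items():
        sizes = [len(ix) for r, ix in region_groups.items() if r.startswith(f"{t}::")]
        s1 += sum(x * x for x in sizes) / len(tg)
    s2 = sum(len(ix) ** 2 for ix in region_groups.values()) / n
    s3 = sum(len(ix) ** 2 for ix in type_groups.values()) / n
    n1 = (n - s1) / df_ap
    n2 = (s1 - s2) / df_ag
    n3 = (n - s3) / df_ag
    sigma_b = (ss_ap / df_ap - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return {
        "SS": (ss_ag, ss_ap, ss_wp, ss_total),
        "df": (df_ag, df_ap, df_wp),
        "var": (sigma_a, sigma_b, sigma_c),
    }


def test_amova_toy_matches_brute_force_oracle():
    """Six-individual toy with unequal group sizes: every sum of squares
    and variance component agrees with the longhand evaluation to 1e-9."""
    g6 = geno(
        [
            [(1, 1), (3, 4)],
            [(1, 2), (3, 3)],
            [(2, 2), (4, 4)],
            [(1, 2), (5, 5)],
            [(2, 2), (4, 5)],
            [(1, 1), (5, 5)],
        ]
    )
    types = np.array(["A", "A", "A", "B", "B", "B"])
    regions = np.array(["r1", "r1", "r2", "r3", "r3", "r4"])
    res = amova(g6, types, regions, permutations=0)
    oracle = brute_force_amova(g6, types, regions)
    comp = res.components
    for row, ss in zip(range(3), oracle["SS"][:3]):
        assert comp["SS"].iloc[row] == pytest.approx(ss, abs=1e-9)
    assert comp["SS"].iloc[3] == pytest.approx(oracle["SS"][3], abs=1e-9)
    for row, v in zip(range(3), oracle["var"]):
        assert comp["variance"].iloc[row] == pytest.approx(v, abs=1e-9)
    assert list(comp["df"][:3]) == list(oracle["df"])


def test_amova_percent_sum_and_df():
    rng = np.random.default_rng(4)
    g = rng.integers(1, 5, size=(24, 4, 2))
    types = np.repeat(["A", "B"], 12)
    regions = np.tile(np.repeat(["x", "y"], 6), 2)
    res = amova(g, types, regions, permutations=49, seed=0)
    assert res.components["percent"][:3].sum() == pytest.approx(100.0, abs=0.01)
    assert res.components["df"].iloc[3] == 2 * 24 - 1
    for p in res.p_values.values():
        assert 0 < p <= 1


def test_panmictic_pool_gives_near_zero_components():
    rng = np.random.default_rng(8)
    g = rng.integers(1, 10, size=(80, 8, 2))
    types = np.repeat(["A", "B"], 40)
    regions = np.tile(np.repeat(["x", "y"], 20), 2)
    res = amova(g, types, regions, permutations=99, seed=1)
    assert abs(res.f_st) < 0.02
    assert res.p_values["F_ST"] > 0.05


def test_two_level_amova_reproduces_pairwise_fst():
    rng = np.random.default_rng(5)
    a = rng.integers(1, 4, size=(10, 3, 2))
    b = rng.integers(2, 6, size=(12, 3, 2))
    fst, _ = pairwise_fst(a, b, permutations=0)
    g = np.concatenate([a, b])
    types = np.array(["only"] * 22)
    regions = np.array(["A"] * 10 + ["B"] * 12)
    res = amova(g, types, regions, permutations=0)
    assert res.f_sr == pytest.approx(fst, abs=1e-9)


# ---------------------------------------------------------------------------
# pairwise F_ST
# ---------------------------------------------------------------------------


def test_identical_populations_fst_near_zero():
    rng = np.random.default_rng(7)
    pool = rng.integers(1, 8, size=(30, 8, 2))
    fst, p = pairwise_fst(pool[:15], pool[15:], permutations=99, seed=2)
    assert abs(fst) < 0.05
    assert p > 0.05


def test_fixed_populations_fst_is_one():
    a = np.tile([[1, 1]], (8, 5, 1))
    b = np.tile([[2, 2]], (8, 5, 1))
    fst, _ = pairwise_fst(a, b, permutations=0)
    assert fst == pytest.approx(1.0)


def test_monomorphic_data_raise():
    a = np.tile([[1, 1]], (5, 3, 1))
    with pytest.raises(ValueError):
        pairwise_fst(a, a.copy(), permutations=0)


def test_fst_matrix_symmetry_and_pvalues():
    rng = np.random.default_rng(9)
    g = rng.integers(1, 6, size=(30, 4, 2))
    labels = np.repeat(["a", "b", "c"], 10)
    mat = fst_matrix(g, labels, permutations=49, seed=3)
    f = mat.fst.to_numpy()
    np.testing.assert_allclose(f, f.T)
    assert np.all(np.diag(f) == 0)
    off = ~np.eye(3, dtype=bool)
    assert ((mat.p_values.to_numpy()[off] > 0) & (mat.p_values.to_numpy()[off] <= 1)).all()


def test_planted_fst_recovered(sim):
    ests = []
    for seed in range(6):
        ds, _, _ = sim(
            regions_per_type=2,
            genets_per_site=150,
            region_drift=0.05,
            alleles_per_locus=10,
            seed=200 + seed,
        )
        r = ds.colonies["region"].to_numpy()
        f, _ = pairwise_fst(ds.genotypes[r == "R1"], ds.genotypes[r == "R2"], permutations=0)
        ests.append(f)
    assert abs(np.mean(ests) - 0.05) < 0.03


# ---------------------------------------------------------------------------
# ENA / INA
# ---------------------------------------------------------------------------


def _exact_hw_pop(f, n, alleles=(1, 2), loci=2):
    n_aa = int(round(f * f * n))
    n_bb = int(round((1 - f) * (1 - f) * n))
    n_ab = n - n_aa - n_bb
    pairs = [(alleles[0],) * 2] * n_aa + [alleles] * n_ab + [(alleles[1],) * 2] * n_bb
    return np.array([[p] * loci for p in pairs], dtype=np.int64)


def test_ena_equals_ina_without_nulls():
    a = _exact_hw_pop(0.5, 100)
    b = _exact_hw_pop(0.4, 100)
    g = np.concatenate([a, b])
    labels = np.array(["a"] * 100 + ["b"] * 100)
    res = fst_ena(g, labels, bootstrap_reps=50, seed=0)
    np.testing.assert_allclose(
        res["ena"].to_numpy(), res["ina"].to_numpy(), atol=1e-6
    )


def test_bootstrap_ci_contains_point_estimate():
    rng = np.random.default_rng(11)
    g = rng.integers(1, 6, size=(60, 8, 2))
    g[30:] += 1  # shift one population's allele pool
    labels = np.repeat(["a", "b"], 30)
    res = fst_ena(g, labels, bootstrap_reps=400, seed=4)
    lo, hi = res["ina_ci"][("a", "b")]
    assert lo <= res["ina"].loc["a", "b"] <= hi
    lo, hi = res["ena_ci"][("a", "b")]
    assert lo <= res["ena"].loc["a", "b"] <= hi


def test_bootstrap_needs_two_loci():
    g = np.random.default_rng(0).integers(1, 4, size=(20, 1, 2))
    with pytest.raises(ValueError):
        fst_ena(g, np.repeat(["a", "b"], 10))


def test_ena_reacts_to_null_alleles(sim):
    """Under planted nulls the corrected and uncorrected matrices differ
    (the seed-aggregated closeness-to-truth comparison lives in the
    acceptance suite)."""
    ds, _, _ = sim(
        regions_per_type=2,
        genets_per_site=100,
        region_drift=0.1,
        null_rate=0.15,
        missing_rate=0.01,
        alleles_per_locus=10,
        seed=3,
    )
    r = ds.colonies["region"].to_numpy()
    res = fst_ena(ds.genotypes, r, bootstrap_reps=0, seed=0)
    assert res["ena"].iloc[0, 1] != res["ina"].iloc[0, 1]
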