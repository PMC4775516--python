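"""Synthetic microsatellite metapopulations with full ground truth.

Emulates the sampling design of a multi-site coral survey: mitochondrial
types whose nuclear gene pools diverged under a correlated-drift (F-model)
hierarchy (ancestral -> type -> region), colonies organized genets ->
ramets with rare stepwise somatic mutation, inbreeding, null alleles,
genotyping failures, and fragment-analysis peak tables with occasional
heteroplasmy -- so every pipeline stage can be tested against known truth
without any external data.

The default configuration mirrors the study design this package targets:
3 mitochondrial types, 4 geographic regions, 8 microsatellite loci, a low
inbreeding coefficient and moderate null-allele and heteroplasmy rates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    MITO_PEAK_SIZES,
    MT_L,
    MT_LPLUS,
    MT_S,
    GenotypeDataset,
    Locus,
    PeakTable,
    call_mito_type,
    write_genalex_csv,
    write_genepop,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_metapopulation", "table1_like_fixture", "write_simulation"]

_TYPE_NAMES = (MT_L, MT_S, MT_LPLUS)

#: bp distance between adjacent alleles (dinucleotide repeat unit)
_STEP = 2


@dataclass
class SimConfig:
    """Parameters of the synthetic metapopulation.

    Drift parameters are F-model coancestry coefficients in (0, 1): the
    expected differentiation of a daughter gene pool from its parent, so
    ``region_drift`` is the planted region-level F_ST within a type and
    ``type_drift`` the planted divergence among types.  ``ramet_mean`` is
    the mean number of colonies per genet (1 = no clonality);
    ``somatic_mu`` is the per-locus probability that a ramet carries a
    stepwise (+/- one repeat unit) somatic mutation.  Null alleles
    segregate as one hidden allele per locus at frequency ``null_rate``;
    ``missing_rate`` blanks a genotype independently (genotyping failure).
    ``heteroplasmy_rate`` colonies show a minor peak of the other
    mitochondrial type at 5%-50% of the main height, exercising both
    branches of the one-tenth peak rule; ``n_mislabeled`` colonies emit
    the opposite type's peak while keeping their true nuclear background.
    """

    n_types: int = 3
    regions_per_type: int = 4
    sites_per_region: int = 2
    genets_per_site: int = 8
    ramet_mean: float = 2.0
    n_loci: int = 8
    alleles_per_locus: int = 12
    ancestral_conc: float = 1.0
    type_drift: float = 0.05
    region_drift: float = 0.015
    f_is: float = 0.05
    null_rate: float = 0.08
    missing_rate: float = 0.01
    somatic_mu: float = 0.001
    heteroplasmy_rate: float = 0.03
    n_mislabeled: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_is", "null_rate", "missing_rate", "somatic_mu", "heteroplasmy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_types", "regions_per_type", "sites_per_region", "genets_per_site", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.type_drift < 1.0 or not 0.0 <= self.region_drift < 1.0:
            raise ValueError("drift parameters must lie in [0, 1)")
        if self.alleles_per_locus < 2 and (self.type_drift > 0 or self.region_drift > 0):
            raise ValueError("need >= 2 alleles per locus when drift > 0")
        if self.ramet_mean < 1.0:
            raise ValueError("ramet_mean must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    colonies: pd.DataFrame  # colony_id, site, region, genet_id, true_type,
    #                         heteroplasmic, mislabeled
    true_genotypes: np.ndarray  # (n, n_loci, 2) allele sizes; -1 = null allele
    ancestral_freqs: list[np.ndarray]
    type_freqs: dict[str, list[np.ndarray]]
    region_freqs: dict[tuple[str, str], list[np.ndarray]]
    planted_type_fst: float
    planted_region_fst: float
    config: SimConfig


def _drift_child(parent: np.ndarray, drift: float, rng: np.random.Generator) -> np.ndarray:
    """Draw daughter frequencies around the parent under the F-model."""
    if drift <= 0.0:
        return parent.copy()
    conc = parent * (1.0 - drift) / drift
    child = rng.dirichlet(np.maximum(conc, 1e-6))
    return np.maximum(child, 1e-12) / np.maximum(child, 1e-12).sum()


def _locus_sizes(l: int, n_alleles: int) -> np.ndarray:
    base = 100 + 20 * l
    return base + _STEP * np.arange(n_alleles)


def _draw_genet(
    freqs: list[np.ndarray], f_is: float, rng: np.random.Generator, n_loci: int
) -> np.ndarray:
    """Diploid genotype as allele indices; the last index is the null."""
    geno = np.empty((n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        a = rng.choice(len(freqs[l]), p=freqs[l])
        if f_is > 0 and rng.random() < f_is:
            b = a  # identical by descent
        else:
            b = rng.choice(len(freqs[l]), p=freqs[l])
        geno[l] = (a, b)
    return geno


def simulate_metapopulation(
    config: SimConfig,
) -> tuple[GenotypeDataset, dict[str, PeakTable], GroundTruth]:
    """Generate a full synthetic survey with ground truth.

    All randomness flows from ``config.seed``; a fixed seed gives
    byte-identical outputs.  Mitochondrial types in the emitted dataset
    are *called* from the generated peak tables (so heteroplasmic and
    mislabeled colonies surface exactly as they would in real data).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_loci, n_all = cfg.n_loci, cfg.alleles_per_locus
    sizes = [_locus_sizes(l, n_all) for l in range(n_loci)]
    ancestral = [rng.dirichlet(np.full(n_all, cfg.ancestral_conc)) for _ in range(n_loci)]
    # the hidden null allele is an ordinary allele of the hierarchy (last
    # index): it drifts between types and regions like any visible allele
    if cfg.null_rate > 0:
        ancestral = [
            np.concatenate([f * (1.0 - cfg.null_rate), [cfg.null_rate]])
            for f in ancestral
        ]
    type_names = [
        _TYPE_NAMES[t] if t < len(_TYPE_NAMES) else f"type{t + 1}" for t in range(cfg.n_types)
    ]
    regions = [f"R{r + 1}" for r in range(cfg.regions_per_type)]
    type_freqs = {
        t: [_drift_child(ancestral[l], cfg.type_drift, rng) for l in range(n_loci)]
        for t in type_names
    }
    region_freqs = {
        (t, r): [_drift_child(type_freqs[t][l], cfg.region_drift, rng) for l in range(n_loci)]
        for t in type_names
        for r in regions
    }

    rows = []
    true_geno = []
    obs_geno = []
    peaks: dict[str, PeakTable] = {}
    genet_counter = 0
    for r in regions:
        for s in range(cfg.sites_per_region):
            site = f"{r}-s{s + 1}"
            for t in type_names:
                ext = region_freqs[(t, r)]  # last index = null when present
                for _ in range(cfg.genets_per_site):
                    genet_counter += 1
                    genet_id = f"g{genet_counter:05d}"
                    geno_idx = _draw_genet(ext, cfg.f_is, rng, n_loci)
                    n_ramets = 1 + rng.poisson(cfg.ramet_mean - 1.0)
                    for m in range(n_ramets):
                        cid = f"{site}-{t}-{genet_id}-{m + 1}"
                        true = np.empty((n_loci, 2), dtype=np.int64)
                        obs = np.empty((n_loci, 2), dtype=np.int64)
                        for l in range(n_loci):
                            pair = []
                            for c in range(2):
                                idx = geno_idx[l, c]
                                if idx == n_all:  # null allele
                                    pair.append(-1)
                                    continue
                                size = int(sizes[l][idx])
                                if cfg.somatic_mu > 0 and rng.random() < cfg.somatic_mu:
                                    size += _STEP * (1 if rng.random() < 0.5 else -1)
                                pair.append(size)
                            true[l] = sorted(pair)
                            visible = [p for p in pair if p > 0]
                            if not visible or (
                                cfg.missing_rate > 0 and rng.random() < cfg.missing_rate
                            ):
                                obs[l] = (0, 0)
                            elif len(visible) == 1:
                                obs[l] = (visible[0], visible[0])
                            else:
                                obs[l] = sorted(visible)
                        hetero = rng.random() < cfg.heteroplasmy_rate
                        rows.append(
                            {
                                "colony_id": cid,
                                "site": site,
                                "region": r,
                                "genet_id": genet_id,
                                "true_type": t,
                                "heteroplasmic": hetero,
                                "mislabeled": False,
                            }
                        )
                        true_geno.append(true)
                        obs_geno.append(obs)
    truth_df = pd.DataFrame(rows)
    n = len(truth_df)
    if cfg.n_mislabeled > 0:
        pick = rng.choice(n, size=min(cfg.n_mislabeled, n), replace=False)
        truth_df.loc[pick, "mislabeled"] = True
        truth_df.loc[pick, "heteroplasmic"] = False

    # fragment peaks: label type is the true type, except mislabeled colonies
    # emit the opposite common type's peak
    for i in range(n):
        row = truth_df.iloc[i]
        label_type = row["true_type"]
        if row["mislabeled"]:
            label_type = MT_S if label_type == MT_L else MT_L
        main_size = MITO_PEAK_SIZES.get(label_type, 460.0)
        main_h = float(rng.uniform(500, 2000))
        plist = [(main_size, main_h)]
        if row["heteroplasmic"]:
            minor_type = MT_S if label_type != MT_S else MT_L
            ratio = float(rng.uniform(0.05, 0.50))
            plist.append((MITO_PEAK_SIZES[minor_type], main_h * ratio))
        peaks[row["colony_id"]] = PeakTable(row["colony_id"], tuple(plist))

    colonies = truth_df[["colony_id", "site", "region"]].copy()
    colonies["mito_type"] = [
        call_mito_type(peaks[cid]) for cid in colonies["colony_id"]
    ]
    loci = [
        Locus(f"L{l + 1:02d}", allele_size_range=(1, 999)) for l in range(n_loci)
    ]
    dataset = GenotypeDataset(
        loci=loci, genotypes=np.array(obs_geno), colonies=colonies
    )
    truth = GroundTruth(
        colonies=truth_df,
        true_genotypes=np.array(true_geno),
        ancestral_freqs=ancestral,
        type_freqs=type_freqs,
        region_freqs=region_freqs,
        planted_type_fst=cfg.type_drift,
        planted_region_fst=cfg.region_drift,
        config=cfg,
    )
    return dataset, peaks, truth


# ---------------------------------------------------------------------------
# survey-shaped fixture
# ---------------------------------------------------------------------------


def table1_like_fixture(
    seed: int = 0,
) -> tuple[GenotypeDataset, dict[str, PeakTable], GroundTruth]:
    """A fixed-seed dataset shaped like the target survey.

    17 sites in four regions (3 + 3 + 3 + 8); two common types everywhere
    plus a rare third type confined to two sites (10 colonies at one, 1 at
    the other); and exactly 21 planted unanalyzable colonies -- 14 showing
    distinct dual peaks (heteroplasmic, typed ``both``) and 7 with an
    unrecognizable fragment size (typed ``unknown``) -- so the exclusion
    filter removes exactly 21.
    """
    rng = np.random.default_rng(seed)
    n_loci, n_all = 8, 12
    sizes = [_locus_sizes(l, n_all) for l in range(n_loci)]
    ancestral = [rng.dirichlet(np.full(n_all, 1.0)) for _ in range(n_loci)]
    regions = {"R1": 3, "R2": 3, "R3": 3, "R4": 8}
    common = [MT_L, MT_S]
    type_freqs = {
        t: [_drift_child(ancestral[l], 0.06, rng) for l in range(n_loci)]
        for t in [*common, MT_LPLUS]
    }
    region_freqs = {
        (t, r): [_drift_child(type_freqs[t][l], 0.015, rng) for l in range(n_loci)]
        for t in [*common, MT_LPLUS]
        for r in regions
    }
    rows, true_geno, obs_geno = [], [], []
    peaks: dict[str, PeakTable] = {}
    genet_counter = 0

    def add_colonies(site, region, t, n_genets, ramet_mean, hetero=False, unknown=False):
        nonlocal genet_counter
        ext = [
            np.concatenate([f * (1.0 - 0.06), [0.06]])
            for f in region_freqs[(t, region)]
        ]
        for _ in range(n_genets):
            genet_counter += 1
            gid = f"g{genet_counter:05d}"
            geno_idx = _draw_genet(ext, 0.05, rng, n_loci)
            n_ram = 1 + rng.poisson(ramet_mean - 1.0)
            for m in range(n_ram):
                cid = f"{site}-{t}-{gid}-{m + 1}"
                true = np.empty((n_loci, 2), dtype=np.int64)
                obs = np.empty((n_loci, 2), dtype=np.int64)
                n_miss = 0  # capped so retained colonies never look failed
                for l in range(n_loci):
                    pair = []
                    for c in range(2):
                        idx = geno_idx[l, c]
                        pair.append(-1 if idx == n_all else int(sizes[l][idx]))
                    true[l] = sorted(pair)
                    visible = [p for p in pair if p > 0]
                    if not visible or (n_miss < 2 and rng.random() < 0.01):
                        obs[l] = (0, 0)
                        n_miss += 1
                    elif len(visible) == 1:
                        obs[l] = (visible[0], visible[0])
                    else:
                        obs[l] = sorted(visible)
                main_h = float(rng.uniform(500, 2000))
                if unknown:
                    plist = [(300.0, main_h)]
                elif hetero:
                    minor = MT_S if t != MT_S else MT_L
                    plist = [
                        (MITO_PEAK_SIZES[t], main_h),
                        (MITO_PEAK_SIZES[minor], main_h * float(rng.uniform(0.15, 0.5))),
                    ]
                else:
                    plist = [(MITO_PEAK_SIZES[t], main_h)]
                peaks[cid] = PeakTable(cid, tuple(plist))
                rows.append(
                    {
                        "colony_id": cid,
                        "site": site,
                        "region": region,
                        "genet_id": gid,
                        "true_type": t,
                        "heteroplasmic": hetero,
                        "mislabeled": False,
                    }
                )
                true_geno.append(true)
                obs_geno.append(obs)

    site_list = []
    for r, n_sites in regions.items():
        for s in range(n_sites):
            site_list.append((f"{r}-s{s + 1}", r))
    for site, r in site_list:
        add_colonies(site, r, MT_L, n_genets=int(rng.integers(3, 8)), ramet_mean=2.0)
        add_colonies(site, r, MT_S, n_genets=int(rng.integers(3, 8)), ramet_mean=1.5)
    # rare third type: 10 colonies at one site, 1 at another
    add_colonies(site_list[4][0], site_list[4][1], MT_LPLUS, n_genets=10, ramet_mean=1.0)
    add_colonies(site_list[7][0], site_list[7][1], MT_LPLUS, n_genets=1, ramet_mean=1.0)
    # plant exactly 21 unanalyzable colonies: 14 dual-peak, 7 unknown
    for j in range(14):
        site, r = site_list[j % len(site_list)]
        add_colonies(site, r, MT_L, n_genets=1, ramet_mean=1.0, hetero=True)
    for j in range(7):
        site, r = site_list[(j + 5) % len(site_list)]
        add_colonies(site, r, MT_S, n_genets=1, ramet_mean=1.0, unknown=True)

    truth_df = pd.DataFrame(rows)
    colonies = truth_df[["colony_id", "site", "region"]].copy()
    colonies["mito_type"] = [call_mito_type(peaks[cid]) for cid in colonies["colony_id"]]
    loci = [Locus(f"L{l + 1:02d}") for l in range(n_loci)]
    dataset = GenotypeDataset(loci=loci, genotypes=np.array(obs_geno), colonies=colonies)
    cfg = SimConfig(seed=seed)
    truth = GroundTruth(
        colonies=truth_df,
        true_genotypes=np.array(true_geno),
        ancestral_freqs=ancestral,
        type_freqs=type_freqs,
        region_freqs=region_freqs,
        planted_type_fst=0.06,
        planted_region_fst=0.015,
        config=cfg,
    )
    return dataset, peaks, truth


def write_simulation(
    dataset: GenotypeDataset,
    peaks: dict[str, PeakTable],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write the generated data as plain-text files: GENEPOP, GenAlEx CSV,
    peak-table TSV, ground-truth TSV and the configuration as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genepop(dataset, outdir / "genotypes.gen")
    write_genalex_csv(dataset, outdir / "genotypes.csv")
    with open(outdir / "peaks.tsv", "w") as fh:
        fh.write("colony_id\tfragment_size\theight\n")
        for cid in dataset.colonies["colony_id"]:
            for size, height in peaks[cid].peaks:
                fh.write(f"{cid}\t{size:g}\t{height:.2f}\n")
    truth.colonies.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(truth.config), fh, sort_keys=False)
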