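"""End-to-end study workflow.

``run_study`` executes the full analysis on one dataset: mitochondrial
typing -> exclusion filtering -> multilocus-lineage calling with P_SEX ->
clone-corrected diversity (including the Bayesian null-allele/inbreeding
models) -> hierarchical AMOVA, permutation F_ST and the ENA null-allele
correction -> admixture clustering with the Evanno dK scan -> cross-type
flagging, followed by a second pass of the downstream statistics with the
flagged lineages excluded.  All randomness flows from one master seed
through named substreams, so a re-run with the same configuration
reproduces every report byte-identically.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clones import assign_lineages, clonal_richness
from .differentiation import amova, fst_ena, fst_matrix
from .diversity import (
    allele_frequencies,
    default_rarefaction_size,
    f_is_estimate,
    population_diversity,
)
from .io import (
    GenotypeDataset,
    PeakTable,
    call_mito_type,
    filter_analyzable,
    read_genalex_csv,
    read_genepop,
    read_site_region_map,
)
from .simulate import SimConfig, simulate_metapopulation, table1_like_fixture
from .structure import align_replicates, flag_cross_type, run_k_scan

__all__ = ["RunConfig", "StudyReport", "run_study", "call_clones", "summarize_clonal", "read_peaks_tsv"]


def read_peaks_tsv(path: str | Path) -> dict[str, PeakTable]:
    """Read a (colony_id, fragment_size, height) TSV into peak tables."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, PeakTable] = {}
    for cid, grp in df.groupby("colony_id", sort=False):
        out[str(cid)] = PeakTable(
            str(cid),
            tuple(zip(grp["fragment_size"].astype(float), grp["height"].astype(float))),
        )
    return out


@dataclass
class RunConfig:
    """Thresholds, chain settings and inputs of one study run.

    Exactly one input source is used: ``genalex_path`` (or
    ``genepop_path``), ``simulate`` (a :class:`SimConfig`) or
    ``fixture_seed`` (the bundled survey-shaped fixture).  Chain lengths
    and permutation counts default to desk-scale values that finish in
    minutes; production-scale settings are simply larger numbers here.
    """

    # inputs
    genalex_path: str | None = None
    genepop_path: str | None = None
    region_map_path: str | None = None
    peaks_path: str | None = None
    simulate: SimConfig | None = None
    fixture_seed: int | None = None
    # thresholds
    max_failed_loci: int = 2
    max_mismatch_loci: int = 1
    linkage: str = "single"
    alpha: float = 0.05
    min_power_genotypes: int = 3
    q_flag: float = 0.5
    pool_threshold: int = 15
    rarefaction_g: int | None = None
    # sampler / resampling settings (desk scale)
    run_inest: bool = True
    inest_burn_in: int = 2_000
    inest_cycles: int = 12_000
    inest_thin: int = 10
    run_clustering: bool = True
    k_min: int = 1
    k_max: int = 5
    cluster_replicates: int = 3
    cluster_burn_in: int = 1_000
    cluster_reps: int = 4_000
    flag_k: int | None = None
    permutations: int = 199
    bootstrap_reps: int = 200
    # bookkeeping
    seed: int = 0
    outdir: str = "clonalpop_run"


@dataclass
class StudyReport:
    """In-memory handles to everything ``run_study`` wrote."""

    dataset: GenotypeDataset
    exclusions: pd.DataFrame
    assignments: pd.DataFrame
    clonal_summary: pd.DataFrame
    representatives: GenotypeDataset
    diversity: pd.DataFrame | None
    amova: object
    fst: object
    ena: dict | None
    cluster_table: object | None
    best_k: int | None
    cross_type_flags: pd.DataFrame | None
    rerun: dict = field(default_factory=dict)
    outdir: Path | None = None


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# clone calling over all strata
# ---------------------------------------------------------------------------


def call_clones(
    dataset: GenotypeDataset,
    max_mismatch_loci: int = 1,
    linkage: str = "single",
    alpha: float = 0.05,
    min_power_genotypes: int = 3,
):
    """Assign multilocus lineages within every (site, type) stratum.

    Allele frequencies and F_IS for P_SEX are clone-corrected (one
    representative per lineage) and pooled at the region x type level.
    Returns (assignment table, clonal summary table, representatives
    dataset) where the representatives dataset has one colony per lineage
    labelled by site/region/type.
    """
    from .clones import resolve_recurrent_mlgs  # local to keep import tidy

    first_pass = {}
    for (site, mito), sub in dataset.strata(("site", "mito_type")):
        part = assign_lineages(
            sub.genotypes,
            allele_freqs=None,
            max_mismatch_loci=max_mismatch_loci,
            linkage=linkage,
        )
        first_pass[(site, mito)] = (sub, part)

    # region x type clone-corrected frequency pools
    pool_geno: dict[tuple[str, str], list[np.ndarray]] = {}
    for (site, mito), (sub, part) in first_pass.items():
        region = sub.colonies["region"].iloc[0]
        pool_geno.setdefault((region, mito), []).append(part.representatives)
    pool_stats = {}
    for key, reps in pool_geno.items():
        geno = np.concatenate(reps, axis=0)
        freqs, counts = allele_frequencies(geno)
        fis, _ = f_is_estimate(geno)
        pool_stats[key] = (freqs, counts, 0.0 if np.isnan(fis) else fis)

    assign_rows = []
    summary_rows = []
    rep_rows = []
    rep_geno = []
    for (site, mito), (sub, part) in sorted(first_pass.items()):
        region = sub.colonies["region"].iloc[0]
        freqs, counts, fis = pool_stats[(region, mito)]
        n_lineages, psex = part.n_base, []
        if len(sub.genotypes) > 1:
            # frequency pool must cover every allele of the tested MLGs
            aug_counts = [dict(c) for c in counts]
            for mlg in part.unique_mlgs:
                for l in range(len(aug_counts)):
                    for a in mlg[l]:
                        if a > 0 and int(a) not in aug_counts[l]:
                            aug_counts[l][int(a)] = 1
            aug = [
                {a: c / sum(cnt.values()) for a, c in cnt.items()} if cnt else {}
                for cnt in aug_counts
            ]
            n_lineages, psex = resolve_recurrent_mlgs(
                part.labels,
                part.mlg_index,
                part.unique_mlgs,
                aug,
                f_is=fis,
                alpha=alpha,
                min_power_genotypes=min_power_genotypes,
            )
        psex_of_mlg = {r.mlg_id: r for r in psex}
        seen_lineage = set()
        for i in range(len(sub.genotypes)):
            lin = int(part.labels[i])
            res = psex_of_mlg.get(int(part.mlg_index[i]))
            assign_rows.append(
                {
                    "colony_id": sub.colonies["colony_id"].iloc[i],
                    "site": site,
                    "region": region,
                    "mito_type": mito,
                    "mll_id": f"{site}:{mito}:{lin}",
                    "representative": lin not in seen_lineage,
                    "p_sex": res.p_sex if res else np.nan,
                    "psex_decision": res.decision if res else "",
                }
            )
            seen_lineage.add(lin)
        n = len(sub.genotypes)
        g = int(part.mlg_index.max()) + 1
        summary_rows.append(
            {
                "region": region,
                "site": site,
                "mito_type": mito,
                "N": n,
                "G": g,
                "MLL": n_lineages,
                "R": clonal_richness(n, min(n_lineages, n)) if n > 1 else np.nan,
            }
        )
        for lin in range(part.n_base):
            rep_rows.append(
                {
                    "colony_id": f"{site}:{mito}:{lin}",
                    "site": site,
                    "region": region,
                    "mito_type": mito,
                }
            )
            rep_geno.append(part.representatives[lin])
    assignments = pd.DataFrame(assign_rows)
    summary = pd.DataFrame(summary_rows)
    representatives = GenotypeDataset(
        loci=list(dataset.loci),
        genotypes=np.array(rep_geno),
        colonies=pd.DataFrame(rep_rows),
    )
    return assignments, summary, representatives


def summarize_clonal(clonal_summary: pd.DataFrame) -> pd.DataFrame:
    """Survey-table-shaped clonal report with per-type totals.

    One row per site x type with N, G, MLL and R (NaN, printed as a dash,
    for absent or singleton strata), plus one TOTAL row per type holding
    the column sums of N, G and MLL.
    """
    out = clonal_summary.copy().sort_values(["mito_type", "region", "site"])
    totals = (
        out.groupby("mito_type")[["N", "G", "MLL"]]
        .sum()
        .reset_index()
        .assign(region="", site="TOTAL", R=np.nan)
    )
    return pd.concat([out, totals], ignore_index=True)[
        ["region", "site", "mito_type", "N", "G", "MLL", "R"]
    ]


# ---------------------------------------------------------------------------
# populations for diversity / differentiation
# ---------------------------------------------------------------------------


def _population_labels(reps: GenotypeDataset, pool_threshold: int) -> np.ndarray:
    """Region x type population labels; rare types (fewer lineages than
    ``pool_threshold`` in total) are pooled into one population."""
    type_counts = reps.colonies["mito_type"].value_counts()
    labels = []
    for _, row in reps.colonies.iterrows():
        t = row["mito_type"]
        if type_counts[t] < pool_threshold:
            labels.append(f"{t}")
        else:
            labels.append(f"{t}:{row['region']}")
    return np.array(labels)


def _downstream(
    reps: GenotypeDataset,
    cfg: RunConfig,
    ss: np.random.SeedSequence,
) -> dict:
    """Diversity + differentiation on a clone-corrected dataset."""
    seeds = ss.spawn(4)
    pop_labels = _population_labels(reps, cfg.pool_threshold)
    pops = {lab: reps.genotypes[pop_labels == lab] for lab in pd.unique(pop_labels)}
    out: dict = {"population_labels": pop_labels}
    # diversity table
    if cfg.run_inest:
        g = cfg.rarefaction_g or default_rarefaction_size(list(pops.values()))
        div_seeds = seeds[0].spawn(len(pops))
        rows = []
        for (lab, geno), s in zip(pops.items(), div_seeds):
            d = population_diversity(
                lab,
                geno,
                g=g,
                burn_in=cfg.inest_burn_in,
                cycles=cfg.inest_cycles,
                thin=cfg.inest_thin,
                seed=_sub_seed(s),
            )
            rows.append(
                {
                    "population": d.population,
                    "A_R": round(d.A_R, 2),
                    "H_O": round(d.H_O, 3),
                    "H_E": round(d.H_E, 3),
                    "F_IS": round(d.F_IS, 3),
                    "null_freq": round(d.null_freq, 3),
                    "avg_fi": round(d.avg_fi, 3),
                    "avg_fi_hpd_low": round(d.avg_fi_hpd[0], 3),
                    "avg_fi_hpd_high": round(d.avg_fi_hpd[1], 3),
                    "DIC_nfb": round(d.dic_nfb, 3),
                    "DIC_nb": round(d.dic_nb, 3),
                    "best_model": d.best_model,
                }
            )
        out["diversity"] = pd.DataFrame(rows)
    else:
        out["diversity"] = None
    # AMOVA over type -> region (pooled types keep one pooled "region")
    types = reps.colonies["mito_type"].to_numpy()
    regions = np.array(
        [
            lab if ":" not in lab else lab.split(":", 1)[1]
            for lab in pop_labels
        ]
    )
    out["amova"] = amova(
        reps.genotypes,
        types,
        regions,
        permutations=cfg.permutations,
        seed=_sub_seed(seeds[1]),
    )
    out["fst"] = fst_matrix(
        reps.genotypes,
        pop_labels,
        permutations=cfg.permutations,
        seed=_sub_seed(seeds[2]),
    )
    out["ena"] = fst_ena(
        reps.genotypes,
        pop_labels,
        bootstrap_reps=cfg.bootstrap_reps,
        seed=_sub_seed(seeds[3]),
    )
    return out


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def _load_input(cfg: RunConfig):
    if cfg.simulate is not None:
        return simulate_metapopulation(cfg.simulate)[:2]
    if cfg.fixture_seed is not None:
        ds, peaks, _ = table1_like_fixture(cfg.fixture_seed)
        return ds, peaks
    if cfg.genalex_path:
        ds = read_genalex_csv(cfg.genalex_path)
    elif cfg.genepop_path:
        region_map = (
            read_site_region_map(cfg.region_map_path) if cfg.region_map_path else None
        )
        ds = read_genepop(cfg.genepop_path, region_map=region_map)
    else:
        raise ValueError("no input source configured")
    peaks = read_peaks_tsv(cfg.peaks_path) if cfg.peaks_path else None
    return ds, peaks


def run_study(cfg: RunConfig) -> StudyReport:
    """Execute the whole workflow and write every report to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = dict(
        zip(
            ("clones", "downstream", "cluster", "rerun"),
            master.spawn(4),
        )
    )
    log: list[str] = [
        f"clonalpop {__version__}",
        f"python {sys.version.split()[0]}",
        f"seed {cfg.seed}",
        f"config {cfg!r}",
    ]

    def stage(name):
        log.append(f"stage: {name}")

    try:
        stage("load")
        dataset, peaks = _load_input(cfg)
        if peaks is not None:
            mito = [
                call_mito_type(peaks[cid]) if cid in peaks else "unknown"
                for cid in dataset.colonies["colony_id"]
            ]
            dataset.colonies["mito_type"] = mito
        stage("filter")
        dataset, exclusions = filter_analyzable(dataset, cfg.max_failed_loci)
        stage("clones")
        assignments, clonal, reps = call_clones(
            dataset,
            max_mismatch_loci=cfg.max_mismatch_loci,
            linkage=cfg.linkage,
            alpha=cfg.alpha,
            min_power_genotypes=cfg.min_power_genotypes,
        )
        clonal_report = summarize_clonal(clonal)
        stage("diversity+differentiation")
        first = _downstream(reps, cfg, stage_seeds["downstream"])
        cluster_table = best_k = None
        flags_df = None
        rerun: dict = {}
        if cfg.run_clustering:
            stage("clustering")
            ks = list(range(cfg.k_min, cfg.k_max + 1))
            cluster_table = run_k_scan(
                reps.genotypes,
                ks,
                replicates=cfg.cluster_replicates,
                burn_in=cfg.cluster_burn_in,
                reps=cfg.cluster_reps,
                seed=_sub_seed(stage_seeds["cluster"]),
            )
            best_k = cluster_table.best_k
            flag_k = cfg.flag_k or best_k
            if flag_k and flag_k >= 2:
                stage("cross-type flagging")
                qs = [
                    cluster_table.runs[(flag_k, r)].Q
                    for r in range(cfg.cluster_replicates)
                ]
                _, consensus = align_replicates(qs)
                try:
                    flags, cluster_map = flag_cross_type(
                        consensus,
                        reps.colonies["mito_type"].to_numpy(),
                        q_flag=cfg.q_flag,
                    )
                except ValueError as exc:
                    log.append(f"cross-type flagging skipped: {exc}")
                    flags, cluster_map = np.zeros(reps.n_colonies, dtype=bool), {}
                flags_df = pd.DataFrame(
                    {
                        "mll_id": reps.colonies["colony_id"],
                        "mito_type": reps.colonies["mito_type"],
                        "flagged": flags,
                        "top_ancestry": consensus.max(axis=1),
                    }
                )
                if flags.any():
                    stage("second pass without flagged lineages")
                    reps2 = reps.subset(~flags)
                    rerun = _downstream(reps2, cfg, stage_seeds["rerun"])
                    rerun["n_excluded"] = int(flags.sum())
    except Exception as exc:
        raise RuntimeError(f"run_study failed at {log[-1]}: {exc}") from exc

    report = StudyReport(
        dataset=dataset,
        exclusions=exclusions,
        assignments=assignments,
        clonal_summary=clonal_report,
        representatives=reps,
        diversity=first["diversity"],
        amova=first["amova"],
        fst=first["fst"],
        ena=first["ena"],
        cluster_table=cluster_table,
        best_k=best_k,
        cross_type_flags=flags_df,
        rerun=rerun,
        outdir=outdir,
    )
    _write_report(report, first, log, outdir, cfg)
    return report


def _write_report(report: StudyReport, first: dict, log: list[str], outdir: Path, cfg: RunConfig) -> None:
    def tsv(df, name, **kw):
        if df is not None:
            df.to_csv(outdir / name, sep="\t", index=kw.pop("index", False), **kw)

    tsv(report.exclusions, "exclusions.tsv")
    tsv(report.assignments, "mll_assignments.tsv")
    tsv(report.clonal_summary.round({"R": 2}), "clonal_summary.tsv")
    tsv(report.diversity, "diversity.tsv")
    tsv(report.amova.summary().round(3), "amova.tsv")
    tsv(report.fst.fst.round(4), "fst.tsv", index=True)
    tsv(report.fst.p_values.round(4), "fst_pvalues.tsv", index=True)
    if report.ena:
        tsv(report.ena["ina"].round(4), "fst_ina.tsv", index=True)
        tsv(report.ena["ena"].round(4), "fst_ena.tsv", index=True)
    if report.cluster_table is not None:
        tsv(report.cluster_table.ln_pd_table.round(3), "lnpd.tsv")
        if report.cluster_table.delta_k is not None:
            tsv(report.cluster_table.delta_k.round(3), "delta_k.tsv")
    tsv(report.cross_type_flags, "cross_type_flags.tsv")
    if report.rerun:
        tsv(report.rerun.get("diversity"), "rerun_diversity.tsv")
        tsv(report.rerun["amova"].summary().round(3), "rerun_amova.tsv")
        tsv(report.rerun["fst"].fst.round(4), "rerun_fst.tsv", index=True)
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
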