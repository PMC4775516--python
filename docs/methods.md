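# Methods

This note records the statistical models behind `clonalpop`, the defaults
and why they are set where they are, and what the synthetic-data tests do
and do not establish.

## Mitochondrial typing

Colonies are typed from fragment-analysis peaks of the noncoding region
between *cyt* b and *nad* 2. Each peak is matched to the nearest
diagnostic size — 460 bp (mt-L), 170 bp (mt-S), 463 bp (mt-L+) — within a
tolerance of ±2 bp (capillary sizing jitter; configurable). When peaks of
two types co-occur, the call is the taller peak's type if the minor peak
is below one tenth of the main height, and `both` (heteroplasmy)
otherwise. `both` and `unknown` colonies, and colonies with more than
`max_failed_loci = 2` of 8 loci missing (a conservative, configurable
cut-off), are excluded before analysis. The call is invariant to peak
order and to uniform rescaling of heights.

## Clones: MLGs, MLLs and P_SEX

Within one site and type, exact-match multilocus genotypes (MLGs) are
linked whenever they differ at ≤ `max_mismatch_loci = 1` locus — the
allowance for somatic mutation and scoring error. Lineages (MLLs) are the
connected components of this relation (single linkage); a strict-clique
variant is available because the literature does not say whether the rule
is applied transitively. A lineage's representative is its modal MLG;
when the mode ties, loci where the tied genotypes disagree are zeroed so
the ambiguity drops out downstream. Missing-vs-called counts as a
mismatch for clustering (conservative on clone calling) but the locus is
skipped in genotype probabilities (unbiased on probability).

A recurrent MLG observed n times among N colonies is screened with
`P_SEX = P(X ≥ n)`, `X ~ Binomial(N, p_gen)`, where `p_gen` multiplies
per-locus genotype probabilities under inbreeding. `P_SEX < α = 0.05`
rejects independent sexual origin — the copies remain one lineage; a
non-significant `P_SEX` means the repeat is plausibly sexual and each
extra copy counts as an additional lineage. Loci at which the lineage is
internally discordant (somatic variants) are excluded from that MLG's
`p_gen`. Strata with fewer than `min_power_genotypes = 3` distinct MLGs
skip the test (no power) and treat recurrences as clonal. Allele
frequencies and `F_IS` for `p_gen` are clone-corrected (one representative
per lineage) and pooled at the region × type level; a frequency pool is
augmented with one gene copy of any tested allele it lacks, so zeroed
representative loci cannot produce undefined probabilities. Clonal
diversity is reported as `R = (MLL − 1)/(N − 1)`, undefined (a dash) for
single-colony strata.

## Diversity statistics

`H_E` is Nei's unbiased estimator `(1 − Σf²)·2n/(2n−1)`; multilocus `H_O`
and `H_E` are unweighted locus means and `F_IS = 1 − H_O/H_E` (the ratio
of locus means, matching the spreadsheet-toolkit convention; per-locus
values are also reported). Allelic richness is the rarefaction expectation
of distinct alleles in `g` gene copies; the default `g` is the smallest
called-gene count over all loci and compared populations.

### Null alleles and inbreeding

The EM estimator treats the locus as carrying one hidden null allele under
Hardy–Weinberg over the extended allele set: observed homozygote excess is
reapportioned into visible/null heterozygotes and (optionally) blanks into
null homozygotes; convergence at 1e-8 or 10⁴ iterations. Because EM
approaches the boundary r = 0 only sublinearly, the estimate snaps to the
boundary when the no-null model fits at least as well (only evaluated when
no blanks are present).

The Bayesian model (`nfb`: null alleles + genotyping failures +
individual inbreeding; `nb`: without inbreeding) is sampled by
data-augmentation Gibbs: per cell the latent state (identical-by-descent
vs outbred; true homozygote vs visible/null heterozygote; blank as
failure vs null homozygote vs IBD null) is imputed, after which per-locus
null frequencies, visible allele frequencies, the failure rate β, the
spike-and-slab individual coefficients `F_i` (zero with probability
1 − π, else uniform; π ~ Beta(1,1)) all have conjugate updates. A
mode-swap Metropolis step on the latent-marginalized posterior trades
null-frequency mass against slab inbreeding, because the two explanations
of homozygote excess form a ridge that coordinate updates cross slowly.
Reported quantities: posterior means of the mean null frequency and
`Avg Fi = mean_i F_i` with a 95% highest-posterior-density interval, and
`DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`. Models within |ΔDIC| < 1 are flagged
indistinguishable. Production chain lengths default to 50,000 burn-in /
500,000 cycles, thinning 50; the tests and pipeline run desk-scale chains
(≈1,000–2,000 burn-in, 6,000–12,000 cycles), which the recovery tests
show are adequate for the summaries they check.

**Known limitation.** With little or no missing data, locus-level null
alleles and individual-level inbreeding are nearly confounded: the
individual-inbreeding explanation spends ~n free parameters against the
null model's ~L, and the marginal posterior legitimately prefers the
null-allele mode unless blanks (null homozygotes) tip the balance.
Planted-inbreeding simulations therefore surface as elevated null
frequencies with small `Avg Fi` — matching the empirical pattern such
surveys report — and `Avg Fi` should be read as a lower bound in
blank-free data.

## Differentiation

The molecular-variance decomposition runs on gene copies (2N units), with
the squared distance between two gene copies the allele mismatch
indicator summed over loci (pairwise deletion of missing loci). This
makes the two-level estimator identical to the gene-level frequency ANOVA
θ and keeps the textbook degrees of freedom (total 2N − 1). Three levels:
among types, among regions within types, within regions; variance
components from the unequal-sample-size expected-mean-square
coefficients; `F_RT = σ²_a/σ²_tot`, `F_SR = σ²_b/(σ²_b+σ²_c)`,
`F_ST = (σ²_a+σ²_b)/σ²_tot`. Significance by the standard nested schemes
— individuals anywhere (F_ST), individuals within type (F_SR), whole
regions among types (F_RT) — with `p = (#{≥ observed}+1)/(perm+1)`
(999 permutations by default), so p-values are never zero. Genotype-level
distances (Smouse–Peakall codominant and plain mismatch) are retained as
utilities but not used for F-statistics: an individual-level two-level
decomposition estimates ≈ 2F/(1+F) rather than F. Components at a level
with a single unit are reported as not estimable (NaN). Rare types whose
total lineage count falls below `pool_threshold = 15` enter the analyses
as one pooled population rather than per-region units.

The INA/ENA pair uses the full Weir–Cockerham θ (a/b/c components with
the observed heterozygosity term). ENA substitutes the EM-corrected
visible allele frequencies and their Hardy–Weinberg expected
heterozygosities `2p̃(1−p̃)`, excising the null allele's footprint from
both terms; the null-driven het deficit is what biases INA upward.
Per-pair 95% CIs come from a percentile bootstrap over loci (1,000
replicates by default; refused below 2 loci).

## Bayesian clustering and ΔK

The admixture sampler follows the classic model for unlinked codominant
loci: latent cluster origins per allele copy, individual ancestries
`Q_i ~ Dirichlet(α,…,α)` with α random-walk updated under a uniform(0,10)
prior (step 0.05), and cluster allele frequencies with the
correlated-frequencies prior `Dirichlet(p_A(1−F_k)/F_k)` whose ancestral
frequencies `p_A` are fixed at pooled sample frequencies (an
empirical-Bayes simplification of samplers that update them; the drift
parameters `F_k` are sampled with uniform priors). `lnPD` is the usual
`mean(ln L) − var(ln L)/2` over post-burn-in sweeps. The inner loop is
numba-compiled; a fixed seed is bit-reproducible. Production defaults are
100,000 burn-in / 1,000,000 replications with K scanned 1–11 across types
and 1–5 within type; desk-scale runs (2,000 / 10,000, 5 replicates) are
what the recovery tests use and recover 3 planted clusters in ≥ 4/5
experiments.

`ΔK(K) = mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd_r L(K)` over
replicate chains, defined for interior K only; zero replicate variance is
an error naming the offending K. The ΔK and alignment machinery accepts
any externally produced (K, replicate, lnPD) table — e.g. from an
inbreeding-aware sampler, which is deliberately not re-implemented here.
Replicate runs at fixed K are merged by exhaustive label-permutation
search (greedy above K = 8) against the first run, and the consensus is
the mean aligned Q. A lineage is flagged cross-type when its top-ancestry
cluster maps (by majority membership) to a different mitochondrial type
and that ancestry exceeds `q_flag = 0.5`; flagged lineages are excluded
and the downstream statistics re-run, mirroring the two-pass design of
the motivating survey.

## Synthetic data

The generator draws ancestral allele frequencies per locus from a
Dirichlet, then type- and region-level frequencies by the F-model
(`Dirichlet(p(1−F)/F)`), so `type_drift` and `region_drift` are the
planted F_ST values at their levels. Genets are drawn with per-locus
identity-by-descent probability `f_is`; ramets copy genets with
`1 + Poisson(ramet_mean − 1)` copies and per-locus stepwise (±1
dinucleotide repeat) somatic mutations at rate `somatic_mu`. The null
allele is an ordinary allele of the hierarchy (it drifts like any other);
carriers appear homozygous, null homozygotes blank; `missing_rate` blanks
cells independently. Peak tables emit the type-diagnostic fragment with
heteroplasmic minor peaks at 5–50 % of the main height, exercising both
branches of the one-tenth rule. Defaults mirror the motivating survey
design: 3 types, 4 regions, 8 loci, 12 alleles per locus, `f_is = 0.05`,
`null_rate = 0.08`, moderate clonality (`ramet_mean = 2`). A fixed-seed
fixture reproduces the survey's shape: 17 sites in four regions (3+3+3+8),
a rare third type at exactly two sites (10 + 1 colonies), and exactly 21
planted unanalyzable colonies (14 dual-peak heteroplasmic, 7 unscorable).

What the generator does **not** emulate: linkage between loci, allele-size
homoplasy structure beyond a flat Dirichlet, isolation-by-distance within
regions, scoring artefacts other than symmetric stepwise error, and
spatially clustered clones. Passing tests therefore demonstrate correct
statistics under the stated sampling models, not robustness to every
artefact of real electropherograms.

## Problem sizes and numerical conventions

The test and acceptance suites run at desk scale: permutation calibration
uses 200 null datasets of 2 × 30 individuals with 199 permutations;
estimator recovery uses n = 500 per population (F_ST, EM) and 20 seeds;
cluster recovery uses n = 120 over K = 1–6 with 5 replicate chains of
2,000 + 10,000 sweeps. Seeds are fixed everywhere; all pipeline
randomness derives from one master seed through named `SeedSequence`
substreams, and derived seeds stay below 2³¹. Reports round R and
F-statistics to 2–3 decimals while machine-readable outputs keep full
precision. Probabilities are clamped to [0, 1]; likelihoods use a 1e-300
floor before logs; Dirichlet draws are floored at 1e-12 and renormalized.
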