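# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generator does and does not emulate, and
the known limitations.

## Synthetic cohort generator (`simhyb`)

The generator realizes the data-generating process the analyses assume.

**Population model.** Two parental gene pools, lessonae (L) and ridibundus
(R). Each locus is generated as a *diagnostic* fixed difference
(L-pool allele frequency 1, R-pool 0) with probability `prop_diagnostic`
(default 0.3), otherwise as a shared polymorphism with a single frequency
drawn from Beta(`beta_a`, `beta_b`) (default Beta(2,2), a mild bump at
intermediate frequencies so that a reasonable fraction of loci survive the
MAF ≥ 0.1 filter). Individuals carry genome copies by group: L = 2 L-pool
copies, R = 2 R-pool copies, E2 = 1+1, E3_LLR = 2 L + 1 R,
E3_LRR = 1 L + 2 R. Each copy draws its allele independently from its pool
frequency. There is no linkage or coalescent structure within pools: loci
are exchangeable, which is adequate for the per-locus analyses tested here
and is a deliberate simplification.

**Default cohort.** 11 L, 12 R, 13 diploid hybrids, 8 LLR and 1 LRR
triploid — the composition of the mixed population the package targets.

**Sequencing model.** Per site and sample, total depth ~ Poisson(λ = 40 by
default, the coverage scale of target-capture experiments in this setting;
a negative-binomial option adds overdispersion). Given true L-allele dosage
fraction f = d/m, the L-supporting read count is
Binomial(depth, f(1−ε) + (1−f)ε) with symmetric per-read error ε (default
0.005, a typical post-filter Illumina error rate).

**Genotype caller.** Every sample is called *as diploid*, whatever its true
ploidy: the call is the maximum-likelihood genotype among hom/het/hom with
expected L-read fractions {1−ε, 1/2, ε} under the binomial read model;
GQ is the Phred-scaled likelihood ratio of best to second-best genotype,
capped at 99; depth-0 sites are emitted as missing. Calling triploids as
diploids is intentional — it reproduces the upstream pipelines these data
come from, and is the mechanism of the ancestry-bias artifact below. A
config flag (`emit_true_ploidy_gt`) emits true genotypes (including
3-allele GTs) for round-trip tests only.

**Coverage tracks.** Per marker, a capture efficiency is drawn: with
probability `prop_poor_markers` (default 0.3, matching the roughly
one-third of bait-set markers that perform poorly on taxa outside the
design clade) a near-zero efficiency Uniform(0, 0.05), otherwise
lognormal(0, 0.4). Depths are Poisson counts at rate `mean_depth × eff`
smoothed by a 25 bp moving average to mimic the autocorrelation of real
pileups.

**What passing tests do not show.** The generator omits reference/capture
bias toward either parental genome, mapping error, indel context, batch
effects and within-pool relatedness. Results on simulated data therefore
validate the *estimators* under their stated model, not robustness to
those real-data artifacts.

## Filter chain and thinning (`vcf_io`)

Records survive only if they are biallelic SNPs with no missing genotype,
per-sample DP ≥ 10 and GQ ≥ 20 *in every individual*, and minor allele
frequency ≥ 0.1 computed over called alleles (maf_min = 0 disables the MAF
rule). The DP rule uses the DP field, not sum(AD), matching standard VCF
filtering tools. Rules are checked in a fixed order (indel, multiallelic,
missing, depth, GQ, MAF) and the first violation is logged per record, so
filter logs are deterministic. The chain is idempotent.

Thinning keeps the lowest-position SNP of each reference marker. Markers
in target capture are short reference sequences, so "one SNP per marker"
removes within-marker linkage without needing a distance parameter; the
first-SNP rule is chosen for determinism.

## Diagnostic panel (`panel`)

A locus is diagnostic when all called alleles in L samples are one state
and all called alleles in R samples are the other. Hybrid and unknown
samples play no role. Loci where either group contains a heterozygote or
missing call are excluded (post-filter these cannot occur, but the check
is kept defensively). The panel stores per-locus L/R allele orientation;
every downstream statistic is computed in that orientation, which makes the
L↔R relabeling symmetries exact (hybrid index ↦ 1−h, ratios ↦ 1−r).

## Triangle coordinates (`triangle`)

hybrid_index = (R-pool alleles)/(called alleles at panel loci);
interclass_het = (loci with one allele from each pool)/(panel loci with a
call). Genotypes are used exactly as called — triploids scored through
their diploid calls land at (≈0.5, ≈1) like diploid hybrids, which is the
behavior to reproduce, not a bug to fix. Loci carrying an allele that
matches neither panel allele (a third allele) are dropped from that
sample's denominator. The HWE boundary is 2h(1−h).

## Dosage from allele-depth ratios (`dosage`)

r_i = AD(L-allele) / (AD(L) + AD(R)) at each panel locus with summed depth
≥ `min_total_depth` (default 1). Ratios use AD directly and ignore the
genotype call, so they remain unbiased where the caller fails.
Classification is nearest-center over {0.5, 2/3, 1/3} with an ambiguity
margin of 0.07: the margin is set below half the gap between adjacent
centers (|2/3 − 1/2|/2 ≈ 0.083) so the classes cannot overlap, while
tolerating the sampling noise of a mean over ≥50 sites (the default
`min_sites`). This mirrors reading peaks off per-sample ratio histograms
but is deterministic; the GMM module is the formal test.

## GMM ploidy selection (`ploidy_gmm`)

**Site selection.** Alt-allele balance at biallelic SNPs with summed AD ≥
20, GQ ≥ 20 and balance strictly inside (0.1, 0.9) — heterozygous-like
sites only, across *all* SNPs, not just the diagnostic panel. The depth
cutoff 20 keeps binomial noise in the balance (SD ≤ 0.11) well below the
mode separation; the bounds exclude the homozygous clusters at 0/1. The
GQ knob exists because the upstream tool's second quality flag is not
fully documented; it is exposed as configuration rather than guessed.

**Denoising.** A mixture of Uniform(0,1) plus a free 3-component Gaussian
mixture is fitted by EM; each site's posterior probability of belonging to
the Gaussian part becomes its weight in all downstream fits, and the
uniform mixing proportion is reported as `noise_fraction`.

**Models.** All mixtures share one common variance (floored at 1e-4, i.e.
σ ≥ 0.01, against degenerate collapse); the free model has 3 free means
and free weights; the fixed model for ploidy p pins means at k/p,
k = 1..p−1, with *uniform* weights and free variance. Uniform rather than
free weights in the fixed models is an identifiability requirement: with
free weights the tetraploid hypothesis {1/4, 1/2, 3/4} contains the
diploid one {1/2} as a special case (weight 1 on the middle component) and
its two spare components absorb stray tail density, so smallest-Δ selection
would systematically prefer tetraploid even on perfectly diploid data.
With uniform weights each hypothesis predicts a distinct balance
distribution and the selection is well posed. Each fixed model still lies
in the free model's parameter space, so logL_free ≥ logL_fixed(p) holds for
every p.

**EM details.** Weighted EM, monotone by construction; free-model
initialization from the canonical {1/4, 1/2, 3/4}, five seeded random
restarts, plus one start at each converged fixed model (last mean repeated
with its weight split, leaving the density unchanged) — the latter
guarantees the free optimum dominates every fixed optimum up to EM
tolerance (1e-8 on the weighted log-likelihood, ≤500 iterations).
Selection is argmin_p Δ(p) with ties broken toward lower ploidy. R² is
computed between the chosen fixed model's predicted bin masses and the
weighted empirical histogram on 100 bins over (0,1); 100 bins is a stated
choice, fine enough to resolve the modes at typical site counts.

A minimum of 100 usable sites (configurable) is required: parental
samples, with far fewer heterozygous-like sites than hybrids, often fall
below it and are skipped by the pipeline with a warning rather than fitted
unreliably.

## Ancestry (`ancestry`)

**Supervised.** With a diagnostic panel, pool frequencies are exactly 1/0
by construction and the binomial likelihood is maximized in closed form by
the L-allele dosage fraction. Without a panel, pool frequencies are
estimated from labelled parentals with pseudocount
p̂ = (count + 0.5)/(2n + 1) (avoiding log 0 at fixed loci) and q is fitted
by bounded scalar optimization to 1e-6.

**Unsupervised.** Standard admixture EM at K = 2 over pool frequencies and
per-sample q, 25 seeded replicates by default, best likelihood kept; pools
are aligned to L/R by the labelled parentals when available (otherwise the
orientation of q is arbitrary). K ≠ 2 is rejected: the study system has
exactly two ancestral nuclear lineages.

**Bias artifact.** Because LLR triploids are called as diploids, sites with
read ratios far from 1/2 (likely at low depth) are miscalled homozygous
for the doubled genome; the supervised q̂ of LLR triploids therefore
exceeds 0.5, with the excess growing as depth falls (≈ +0.001 at 40×,
≈ +0.05 at 10× under the default generator). The package measures this
artifact; it does not correct it.

**PCA.** Alt-dosage matrix, columns centered at 2p̂ and scaled by
√(p̂(1−p̂)); monomorphic columns dropped; SVD coordinates with variance
fractions relative to the retained matrix.

## Coverage windows (`covwin`)

best_window_min = max over all contiguous 100 bp windows of the
within-window minimum depth, computed in O(n) with a monotone deque;
markers shorter than the window use the whole-marker minimum (capture
markers start near 100 bp, so this is an explicit edge convention rather
than a drop rule). Summaries: per-marker median across samples, ranking by
summed coverage, and counts of markers above 100× / below 10× medians.
Input is 0-based 3-column TSV or 1-based samtools-depth text; positions
absent from sparse input are zero-filled.

## Determinism and problem sizes

Every stochastic component (generator, EM restarts, pipeline per-sample
seeds) flows from explicit integer seeds; two runs with the same config
produce byte-identical outputs, including plots. Tests and the acceptance
script use desk-scale sizes chosen to keep estimator standard errors well
inside the asserted tolerances: 150–500 markers, cohorts of 6–80
individuals, 300–400 diagnostic sites per dosage/ploidy check, and 40
replicates per ploidy class for the recovery rate.

## Known limitations

- No reference or capture bias toward either parental genome is modelled;
  real ratio asymmetries beyond genome dosage are out of model.
- Parental pools are frequency pools without drift, linkage or pedigree
  structure; later-generation hybrid classes (F2, backcrosses) can be
  constructed from genotypes but are not generated natively.
- The ploidy GMM assumes at most tetraploidy and a unimodal-per-dosage
  balance distribution; heavy mapping-bias tails are handled only through
  the uniform noise component.
- The dosage classifier is a mean-based rule; individuals with mixed or
  mosaic ploidy would be flagged ambiguous rather than decomposed.
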