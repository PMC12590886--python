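# Methods

## The statistical model

Every association in the pipeline is a variant of one ordinary
least-squares fit. For a gene's normalized expression `g` (or the trait)
and a SNP dosage `S` coded as the alternative-allele count 0/1/2,

    g = β·S + γ_bw·bw + Σ γ_se + Σ γ_ba + ε,

with carcass weight `bw` (kg) continuous, sex `se` and slaughter batch
`ba` dummy-coded fixed effects (first level as reference), and `ε` an
i.i.d. residual. `β` is the allele-substitution effect; its t statistic
on the residual degrees of freedom (n − rank of the design) gives a
two-sided p-value. Rank-deficient designs (e.g. a batch perfectly
confounded with sex) drop the collinear dummies with a warning; the SNP
column itself collinear with the covariates aborts the pair. Missing
dosages are mean-imputed per SNP by default (keeping n constant across
pairs); a complete-case mode exists. The p-values are exact under
normal errors and asymptotically calibrated otherwise; the suite
verifies a 5% type-I rate and KS-uniformity on 10,000 null pairs at
n = 79.

Cis/trans classification uses the transcription start site — the gene
start on '+' strands, the gene end on '−' strands — with an inclusive
1 Mb window: |pos − TSS| ≤ 1,000,000 on the same chromosome is cis. The
genome-wide (p < 5×10⁻⁸) and suggestive (p < 5×10⁻⁶) flags are strict
inequalities, and Benjamini–Hochberg q-values are computed once over
all fitted cis pairs (a single testing family).

## Expression preprocessing

Genes count as expressed when their FPKM exceeds 0.1 in a strict
majority of samples (both comparisons strict: a gene at exactly 0.1
everywhere is dropped; 40 of 80 samples is not a majority, 41 is).
Retained genes are rescaled to TPM (column sums forced to 10⁶) and each
gene is rank-inverse-normal transformed across samples,
Φ⁻¹((r − 0.5)/n) with average ranks for ties, so an all-tied gene maps
to zeros and the eQTL scan is invariant to any strictly monotone
per-gene abundance transform. The offset 0.5 is the default; Blom's 3/8
is available through the `offset` argument. The FPKM filter is applied
before TPM ranking because filtering is a detection question (FPKM
scale) while ranking only needs a monotone abundance.

## GWAS side

The single-SNP trait scan reuses the same linear model with the trait
as response. One unit of −log₁₀(p) is treated as one LOD unit; the
support interval retains SNPs with LOD strictly above the chromosome
peak minus 2 and spans the contiguous retained run containing the peak.
The chromosome-wide literal reading ("all SNPs above the threshold") is
available via `span_all=True`; the contiguous default is what makes the
reported interval a single span. LD r² is the squared Pearson
correlation of dosage vectors (composite LD) — deterministic, no EM
haplotype phasing — and blocks are greedy maximal contiguous runs in
map order where every pair satisfies r² > 0.90; only blocks of two or
more SNPs are reported, and monomorphic SNPs are excluded with a
warning.

Permutation association is Freedman–Lane style: the observed statistic
is |t| from trait ~ S + covariates; covariate-adjusted trait residuals
are permuted and the model refitted, preserving the covariate
structure. Empirical p-values use the add-one estimator
(1 + #{perm ≥ obs})/(n_perm + 1), pointwise and family-wise
(per-permutation max |t| over the SNP set), so p is never zero and the
family-wise p dominates the pointwise p. The genotype-stratified
comparison reports raw (unadjusted) per-dosage trait means with
SE = sd/√n and an unpaired two-tailed t-test between the two largest
classes; singleton classes are reported mean-only.

## Co-expression stage

The network stage is a from-scratch implementation of the weighted
co-expression recipe, with three deliberate simplifications relative to
the reference tool, each chosen for determinism and testability:

- **Outlier samples.** Average-linkage clustering on Euclidean distance
  of expression profiles, cut at a height, largest cluster retained.
  The default height is data-driven: the cut is placed inside the
  largest gap of the sorted merge heights above the median, but only
  when that gap exceeds half the median height — outliers join the tree
  far above the bulk, while homogeneous cohorts have no such gap and
  are fully retained. (A fixed quantile rule such as median + 3·IQR
  misbehaves here: average-linkage merge heights are right-skewed by
  construction, so it cuts healthy data.) The height is config-exposed.
- **Soft power.** Unsigned adjacency |cor|^β. The power is the smallest
  candidate (1–20) whose scale-free fit R² — the r² of log₁₀(freq)
  versus log₁₀(k) over binned connectivity, signed to zero when the
  slope is positive — reaches 0.8, restricted to powers where the
  median connectivity stays ≥ 5: below that the typical gene is
  isolated and the apparent scale-free fit is an artifact of an empty
  graph (a well-connected core can keep the *mean* connectivity high,
  which is why the floor is on the median). When no admissible power
  reaches the target — the norm for strongly modular expression, whose
  degree distribution is not scale-free — the stage uses the standard
  unsigned-network default of 6 rather than the R² argmax, which
  otherwise drifts to degenerate powers ≥ 15 and fragments modules.
- **Module detection.** Topological overlap
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), average
  linkage on 1 − TOM, and a *static* height cut (default 0.98) instead
  of dynamic tree cut; clusters under 30 genes are unassigned, and
  modules whose eigengenes correlate above 0.75 (merge height 0.25) are
  merged iteratively. On planted three-module data this recovers the
  partition exactly (ARI 1.0 across 200 sweep runs); dynamic cut's
  extra machinery buys nothing at this problem scale.

The module eigengene is the first right singular vector of the
gene-standardized module matrix, unit norm, sign fixed so its mean
correlation with member genes is positive. Module–trait relationship
(MTR), gene significance (GS) and module membership (MM) are Pearson
correlations with t-distribution p-values; critical genes have GS p and
MM p below 0.01 inside modules with MTR p below 0.01. Enrichment-based
module triage (external databases) is out of scope; an explicit
critical-module list can be supplied instead, defaulting to all
MTR-significant modules.

## Correlation screen

Expression enters as log₂(FPKM + 1); the pseudocount of 1 avoids −∞ at
zero and is config-exposed. The trait is adjusted once globally on
[1, dummy(sex), dummy(batch), weight] and reused for every gene; each
gene is adjusted the same way and the Pearson correlation of the two
residual vectors is tested with n − 2 degrees of freedom (plain Pearson
on residuals; the conservative n − 2 − k alternative is a documented
flag away). Significance is q ≤ 0.05 after BH across all genes.

## Evidence integration

Four gene sets — suggestive cis-eQTL genes, colocalized genes (those
whose significant cis-eQTLs fall inside the pQTL support interval,
inclusive ends), critical-module genes, and correlation-significant
genes — are intersected exactly. The report ranks genes by tier (number
of supporting streams), then correlation q, then id, and carries the
exclusive Venn region counts whose inclusion–exclusion sums reproduce
each stream's size. Every run writes a provenance manifest (thresholds,
seeds, versions) next to the per-stage tables.

## The synthetic cohort

The generator is a forward model of everything the analysis assumes,
with defaults chosen to emulate the motivating cohort:

| parameter | default | meaning |
|---|---|---|
| n_samples | 79 | cohort size |
| sex_proportions | 58:21 | two sexes |
| n_batches | 11 | slaughter batches (uniform) |
| weight_mean/sd | 100 / 8 kg | carcass weight |
| chromosomes × blocks | 4 × 20 | 5-SNP LD blocks, 300 kb apart |
| ld_within_r | 0.99 | haplotype-copy fidelity within a block |
| maf_range | 0.20–0.45 | block allele frequency (clear of the 0.05 QC bound) |
| missing_rate | 0.01 | genotype missingness (written VCF only) |
| module_sizes | 100,100,100 | latent-factor co-expression modules |
| noise_sd | 0.5 | residual latent-expression noise |
| planted cis β | 1.6 (regulator), 1.2 (others) | latent-scale allele effects |
| regulator_effect | −1.5 | trait slope per latent log unit of the regulator |
| trait_noise_sd | 0.8 | residual trait noise |

Genotypes: each block draws an allele frequency, each haplotype copies
a master allele with flip probability (1 − ld_within_r)/2 — giving
tunable pairwise r² (exactly 1 at ld_within_r = 1) without a coalescent
simulator — and blocks are independent. Blocks carrying planted effects
are redrawn (bounded retries) if the planted SNP realizes MAF < 0.05,
so QC never silently removes a planted effect. Expression is generated
on a latent log scale (module factor + planted β·S + covariate terms +
noise) and mapped to an FPKM-like scale by the invertible transform
exp(0.5·latent + 3); 20 additional genes are written far below the
0.1-FPKM detection bound so the expressed-gene filter has work to do.
The trait is intercept 5 + regulator_effect·(regulator latent) +
covariate terms + noise, yielding an IMF-like percent spread of roughly
1–9 with strong genotype stratification. The regulator's cis effect
sizes were set for reliable single-run detection at n = 79 (the
planted pair clears the suggestive threshold with a ~3σ margin);
weaker settings are one config field away. All randomness flows from
the single seed through tagged substreams, so equal configs are
byte-identical, stage by stage.

What the generator does **not** emulate: population structure and
relatedness, realistic recombination maps or allele-frequency spectra,
count-level sampling noise (expression is Gaussian on the log scale),
batch effects that are not mean shifts, and trait values are not
truncated at zero. Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed model, not robustness to
those real-data violations. Optional outlier samples (a global latent
shift on `n_outliers` samples, default 0) exercise the outlier-removal
stage; they are off by default because such artificial global shifts
would corrupt the correlation stream in ways real outliers need not.

## Numerical choices and degenerate inputs

BH q-values use mergesort ordering (stable under ties) with a
cumulative minimum from the largest p. Empirical p-values are never 0.
Constant SNPs, constant traits, rank-0 modules, empty expression
matrices, p-values outside (0, 1], all-singleton sample dendrograms and
empty sample intersections raise informative errors rather than
propagating NaNs; monomorphic SNPs are excluded from LD blocks with a
warning. Interval coordinates are 1-based inclusive internally (the VCF
convention); only BED export converts to 0-based half-open. Duplicate
GWAS records at one position keep the first occurrence with a warning.

## Problem sizes

Default analyses use 79 samples, 400 SNPs (80 blocks), 420 genes
(~12,800 cis pairs), 10,000–100,000 permutations, and the acceptance
measurements use 10,000 null pairs, 1,000 random vectors/profiles for
the oracles, 20 module-recovery seeds and 100 regulator-recovery seeds
— sizes at which every quantity of interest is stable while a complete
run of suite plus acceptance script finishes in a few minutes on one
core.

## Known limitations

- The scan is marginal per pair: no conditional analysis, no
  mixed-model kinship correction, no PEER-style latent factors.
- Colocalization is positional overlap, not a Bayesian shared-variant
  posterior.
- The static module cut depends on a height parameter; extremely
  unequal module densities could require adjusting it where dynamic
  tree cut would adapt.
- LD blocks use composite (genotype) LD; at r² thresholds far below
  0.9 phased haplotype methods would differ.
- The `--all` (trans) scan mode is quadratic in genes × SNPs and is not
  exercised by the default pipeline.
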