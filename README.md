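# imfscan

Integrative genome–transcriptome scan for nominating genes that regulate a
quantitative trait — written around the design of intramuscular fat (IMF)
mapping in a small pig cohort, where a gene is called a candidate only when
four independent lines of evidence converge on it:

1. **cis-eQTL mapping** — SNPs within 1 Mb of a gene's transcription start
   site are tested against its rank-normalized expression under the
   additive covariate-adjusted linear model

   `g = β·S + bw + se + ba + ε`

   with `S` the allele dosage (0/1/2), `bw` carcass weight, `se` sex and
   `ba` slaughter batch as fixed effects. Pairs are flagged at genome-wide
   (p < 5×10⁻⁸) and suggestive (p < 5×10⁻⁶) thresholds with
   Benjamini–Hochberg q-values.
2. **pQTL colocalization** — the trait GWAS is summarized as a LOD profile
   (LOD ≈ −log₁₀ p); the 2-LOD drop rule gives a support interval around
   the peak, LD blocks (all pairwise dosage r² > 0.90) are mapped inside
   it, and each gene's significant cis-eQTLs are intersected with it.
   Trait association of the colocalized cis-eQTLs is confirmed by
   covariate-adjusted permutation and a raw genotype-stratified comparison.
3. **co-expression module criticality** — a from-scratch weighted network
   stage (soft-thresholded |cor|^β adjacency, topological overlap, module
   eigengenes): genes with gene-significance and module-membership p < 0.01
   inside modules whose eigengene correlates with the trait (p < 0.01).
4. **adjusted trait correlation** — Pearson correlation between
   covariate-adjusted log₂ expression and the covariate-adjusted trait,
   significant at q ≤ 0.05.

The intersection of the four gene sets (the Venn logic) is the candidate
report. A synthetic-cohort simulator (`imfscan.synthio`) generates data
with exactly the structure this analysis assumes — LD-blocked genotypes,
planted cis effects, covariate effects, co-expression modules, and one
regulator gene whose expression negatively drives the trait — so every
stage is testable without external data, and the whole pipeline can be
validated by whether it re-discovers the planted regulator.

## Worked example

The numbered scripts under `analysis/` run the study as a narrative; the
same thing is available as one command (`imfscan run --simulate --out
results/run` or `run_pipeline` in Python):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_normalize_expression.py
python analysis/03_map_cis_eqtls.py
python analysis/04_pqtl_colocalization.py
python analysis/05_coexpression_modules.py
python analysis/06_trait_correlation.py
python analysis/07_integrate_evidence.py
```

Output of the run at seed 1 (abridged):

```
retained 400 of 420 genes (FPKM > 0.1 in a strict majority of 79 samples)
12804 cis pairs fitted; 18 genome-wide, 20 suggestive (4 genes with a suggestive cis-eQTL)
pQTL support interval (2-LOD drop): 9:25400000-25420000 (peak LOD 10.7)
top colocalized gene: G0001 (5 cis-eQTLs inside the interval)
strongest trait association among them: snp_9_18_0 (permutation p = 1.00e-05, 100000 permutations)
  dosage 0: trait 7.69 +/- 0.37 (n=26)
  dosage 2: trait 2.29 +/- 0.52 (n=13)
  M3: 100 genes, MTR r=-0.72 p=1.2e-13 *
104 of 400 genes significant at q <= 0.05
  G0001: r=-0.93, q=8.60e-34
4-way candidates: ['G0001']
```

Reading: the expressed-gene filter dropped the 20 near-silent genes; the
cis scan found the four planted effects; the GWAS support interval on
chromosome 9 contains exactly the regulator's LD block; carriers of more
regulator-raising alleles have markedly lower trait values (7.69% vs
2.29%); module M3 is the trait-linked module; the correlation screen puts
the regulator first with a strong negative coefficient; and only the
planted regulator `G0001` is supported by all four streams.

## Layout

```
src/imfscan/       library: dataio, synthio, exprnorm, eqtl, pqtl,
                   coexpr, correl, integrate, cli
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, parameters, design choices, limitations
```
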