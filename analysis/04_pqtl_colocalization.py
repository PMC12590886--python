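#!/usr/bin/env python
"""Build the GWAS support interval and colocalize it with cis-eQTLs.

The trait GWAS summary is turned into a per-chromosome LOD profile
(LOD = -log10 p); the 2-LOD drop rule yields the pQTL support interval
around the peak. LD blocks (all pairwise dosage r^2 > 0.90) are
reported inside the interval, significant cis-eQTLs are intersected
with it per gene, the cis-eQTLs of the top colocalized gene are tested
against the trait by covariate-adjusted permutation, and the
best-associated SNP gets a raw genotype-stratified trait comparison.

Input:  results/data/, results/eqtl.tsv
Output: results/pqtl_interval.bed, results/ld_blocks.tsv,
        results/coloc.tsv, results/permutation.tsv,
        results/stratified.json
"""

import argparse
import json

import numpy as np
import pandas as pd

from imfscan import dataio, eqtl, pqtl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    ap.add_argument("--n-perm", type=int, default=100_000)
    ap.add_argument("--perm-seed", type=int, default=2024)
    args = ap.parse_args()

    geno = dataio.read_genotypes(f"{args.data}/genotypes.vcf")
    cov = dataio.read_covariates(f"{args.data}/covariates.tsv")
    geno, cov = dataio.align_samples(geno, cov)
    geno_qc, _ = eqtl.qc_genotypes(geno)
    gwas = dataio.read_gwas(f"{args.data}/gwas_summary.tsv")
    eqtl_table = pd.read_csv(f"{args.out}/eqtl.tsv", sep="\t",
                             dtype={"chrom_snp": str, "chrom_gene": str})

    peak_chrom = str(gwas.chrom[int(np.argmin(gwas.p_value))])
    profile = pqtl.lod_profile_from_summary(gwas, peak_chrom)
    interval = pqtl.lod_drop_interval(profile, drop=2)
    print(f"pQTL support interval (2-LOD drop): "
          f"{interval.chrom}:{interval.start}-{interval.end} "
          f"(peak LOD {profile.lod.max():.1f})")
    dataio.write_intervals([interval], f"{args.out}/pqtl_interval.bed")

    blocks = pqtl.find_ld_blocks(geno_qc, region=interval, r2_min=0.90)
    pd.DataFrame(
        [{"chrom": b.chrom, "start": b.start, "end": b.end, "n_snps": b.n_snps,
          "min_r2": b.min_r2, "snp_ids": ",".join(b.snp_ids)} for b in blocks]
    ).to_csv(f"{args.out}/ld_blocks.tsv", sep="\t", index=False)
    print(f"{len(blocks)} LD block(s) with all pairwise r^2 > 0.90 in the interval")

    coloc = pqtl.colocalize(interval, eqtl_table)
    coloc.to_csv(f"{args.out}/coloc.tsv", sep="\t", index=False)
    if coloc.empty or coloc.iloc[0].n_eqtls_in_interval == 0:
        print("no gene's significant cis-eQTLs overlap the interval")
        return
    top = coloc.iloc[0]
    print(f"top colocalized gene: {top.gene_id} "
          f"({top.n_eqtls_in_interval} cis-eQTLs inside the interval)")

    snp_ids = top.snp_ids.split(",")
    snp_idx = [geno_qc.snp_ids.index(s) for s in snp_ids]
    perm = pqtl.permutation_assoc(geno_qc, snp_idx, cov,
                                  n_perm=args.n_perm, seed=args.perm_seed)
    perm.to_csv(f"{args.out}/permutation.tsv", sep="\t", index=False)
    best = perm.iloc[int(np.argmin(perm.p_perm))]
    print(f"strongest trait association among them: {best.snp_id} "
          f"(permutation p = {best.p_perm:.2e}, {args.n_perm} permutations)")

    strat = pqtl.genotype_stratified_test(
        geno_qc.dosage[:, geno_qc.snp_ids.index(best.snp_id)], cov.trait
    )
    strat["snp_id"] = best.snp_id
    with open(f"{args.out}/stratified.json", "w") as fh:
        json.dump(strat, fh, indent=1)
    for g, c in strat["classes"].items():
        se = "n/a" if c["se"] is None else f"{c['se']:.2f}"
        print(f"  dosage {g}: trait {c['mean']:.2f} +/- {se} (n={c['n']})")
    print(f"  two largest classes differ with p = {strat['p']:.2e}")


if __name__ == "__main__":
    main()
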