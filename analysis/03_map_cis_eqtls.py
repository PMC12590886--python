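#!/usr/bin/env python
"""Map cis-eQTLs under the additive covariate-adjusted linear model.

Genotypes pass sample/SNP QC (individual missing rate <= 0.1, MAF >=
0.05, SNP missing rate <= 0.1, chromosomal contigs only); each SNP
within 1 Mb of a gene's TSS is then tested against the rank-normalized
expression with sex, slaughter batch and carcass weight as covariates.
Pairs are flagged at the genome-wide (p < 5e-8) and suggestive
(p < 5e-6) thresholds, with BH q-values over all fitted cis pairs.

Input:  results/data/, results/normalized_expression.tsv
Output: results/eqtl.tsv
"""

import argparse

from imfscan import dataio, eqtl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    geno = dataio.read_genotypes(f"{args.data}/genotypes.vcf")
    expr = dataio.read_expression(f"{args.out}/normalized_expression.tsv",
                                  annotation=f"{args.data}/annotation.tsv",
                                  scale="normalized")
    cov = dataio.read_covariates(f"{args.data}/covariates.tsv")
    geno, expr, cov = dataio.align_samples(geno, expr, cov)

    geno_qc, qc = eqtl.qc_genotypes(geno)
    print(f"QC: {qc.n_snps_out}/{qc.n_snps_in} SNPs retained, "
          f"{qc.n_samples_out}/{qc.n_samples_in} samples retained")
    table = eqtl.run_scan(expr, geno_qc, cov)
    table.to_csv(f"{args.out}/eqtl.tsv", sep="\t", index=False, float_format="%.8g")
    n_gw = int(table.significant_gw.sum())
    n_sugg = int(table.significant_sugg.sum())
    genes_sugg = table.loc[table.significant_sugg, "gene_id"].nunique()
    print(f"{len(table)} cis pairs fitted; {n_gw} genome-wide, {n_sugg} suggestive "
          f"({genes_sugg} genes with a suggestive cis-eQTL)")


if __name__ == "__main__":
    main()
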