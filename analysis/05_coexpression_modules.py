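#!/usr/bin/env python
"""Detect co-expression modules and their trait relationships.

On log2(FPKM+1) of the expressed genes: outlier samples are removed at
a dendrogram cut, a soft-threshold power is chosen, modules come from a
static cut of the 1-TOM dendrogram with eigengene merging, and
module-trait relationships (MTR), gene significance (GS) and module
membership (MM) identify critical genes (GS p and MM p < 0.01 inside
modules with MTR p < 0.01).

Input:  results/data/      Output: results/gene_modules.tsv,
        results/module_trait.tsv, results/critical_genes.txt
"""

import argparse

import pandas as pd

from imfscan import coexpr, correl, dataio, exprnorm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    fpkm = dataio.read_expression(f"{args.data}/expression.tsv",
                                  annotation=f"{args.data}/annotation.tsv")
    cov = dataio.read_covariates(f"{args.data}/covariates.tsv")
    fpkm, cov = dataio.align_samples(fpkm, cov)
    kept, _ = exprnorm.filter_expressed(fpkm)
    log2 = correl.log2_transform(kept)

    assignment, stats_table, crit, info = coexpr.coexpression_analysis(log2, cov.trait)
    n_out = fpkm.n_samples - len(info["retained_samples"])
    print(f"outliers removed: {n_out} (cut height {info['outlier_cut_height']:.1f}); "
          f"soft power {info['soft_power']}; {info['n_modules']} modules")
    stats_table.to_csv(f"{args.out}/gene_modules.tsv", sep="\t", index=False,
                       float_format="%.6g")
    mtr = pd.DataFrame(
        [{"module": m, "n_genes": len(assignment.members(m)),
          "mtr_r": assignment.mtr[m][0], "mtr_p": assignment.mtr[m][1]}
         for m in assignment.modules]
    )
    mtr.to_csv(f"{args.out}/module_trait.tsv", sep="\t", index=False,
               float_format="%.4g")
    for row in mtr.itertuples():
        flag = " *" if row.mtr_p < 0.01 else ""
        print(f"  {row.module}: {row.n_genes} genes, MTR r={row.mtr_r:+.2f} "
              f"p={row.mtr_p:.1e}{flag}")
    with open(f"{args.out}/critical_genes.txt", "w") as fh:
        fh.write("\n".join(crit) + "\n")
    print(f"{len(crit)} critical genes (GS & MM p < 0.01 in trait-linked modules)")


if __name__ == "__main__":
    main()
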