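#!/usr/bin/env python
"""Covariate-adjusted expression-trait correlation screen.

Both the trait and each gene's log2(FPKM+1) are adjusted for sex,
slaughter batch and carcass weight; Pearson correlation of the
residuals with a BH q across genes flags trait-linked genes (q <= 0.05).

Input:  results/data/      Output: results/correlation.tsv
"""

import argparse

from imfscan import correl, dataio, exprnorm


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

    table = correl.correlate_all(correl.log2_transform(kept), cov)
    table.to_csv(f"{args.out}/correlation.tsv", sep="\t", index=False,
                 float_format="%.6g")
    sig = table[table.significant]
    print(f"{len(sig)} of {len(table)} genes significant at q <= 0.05")
    print("strongest associations:")
    for row in table.head(5).itertuples():
        print(f"  {row.gene_id}: r={row.r:+.2f}, q={row.q:.2e}")


if __name__ == "__main__":
    main()
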