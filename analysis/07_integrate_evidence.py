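#!/usr/bin/env python
"""Intersect the four evidence streams into the candidate-gene report.

Streams: genes with a suggestive cis-eQTL; genes whose significant
cis-eQTLs lie inside the pQTL support interval; critical genes of
trait-linked co-expression modules; genes correlated with the trait
after adjustment. Candidates are ranked by how many streams support
them; the 4-way intersection is the headline call.

Input:  results/eqtl.tsv, results/coloc.tsv, results/critical_genes.txt,
        results/correlation.tsv
Output: results/candidates.tsv, results/venn.json
"""

import argparse
import json

import pandas as pd

from imfscan.integrate import intersect_evidence


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    eqtl_table = pd.read_csv(f"{args.out}/eqtl.tsv", sep="\t")
    coloc = pd.read_csv(f"{args.out}/coloc.tsv", sep="\t")
    corr = pd.read_csv(f"{args.out}/correlation.tsv", sep="\t")
    crit = [l.strip() for l in open(f"{args.out}/critical_genes.txt") if l.strip()]

    eqtl_genes = set(eqtl_table.loc[eqtl_table.significant_sugg, "gene_id"])
    coloc_genes = set(coloc.loc[coloc.n_eqtls_in_interval > 0, "gene_id"])
    corr_genes = set(corr.loc[corr.significant, "gene_id"])
    report = intersect_evidence(eqtl_genes, coloc_genes, crit, corr_genes,
                                corr_table=corr)
    report.table.to_csv(f"{args.out}/candidates.tsv", sep="\t", index=False)
    with open(f"{args.out}/venn.json", "w") as fh:
        json.dump(report.venn, fh, indent=1, sort_keys=True)

    print(f"stream sizes: cis-eQTL {len(eqtl_genes)}, colocalized {len(coloc_genes)}, "
          f"critical-module {len(crit)}, correlation {len(corr_genes)}")
    print(f"4-way candidates: {report.four_way or 'none'}")
    tiers = report.table.tier.value_counts().sort_index(ascending=False)
    for tier, n in tiers.items():
        print(f"  tier {tier}: {n} gene(s)")


if __name__ == "__main__":
    main()
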