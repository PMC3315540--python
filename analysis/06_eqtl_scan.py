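#!/usr/bin/env python
"""Gene-centric cis-eQTL scan: Spearman correlation of each identified
gene's expression with SNPs in a 2-Mb window, retained at p<0.05 and
crossed with the trend-model disease log-odds into r/u, r/d, p/u, p/d
direction labels. Writes results/eqtl.tsv.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from gbascan import io
from gbascan.eqtl import cis_eqtl_scan

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    dataset = io.read_genotypes(data / "clean.ped", data / "clean.map")
    genes = io.read_gene_table(data / "genes.tsv")
    expr = io.read_expression(ROOT / "expression.tsv")
    de = pd.read_csv(ROOT / "diffexpr.tsv", sep="\t")
    de_genes = [g for g in genes
                if g.gene_id in set(de.loc[de["p_group"] < 0.05, "feature_id"])]
    sbas = pd.read_csv(ROOT / "sbas.tsv", sep="\t")
    beta = dict(sbas.loc[(sbas["model"] == "CLR_C") & sbas["converged"],
                         ["snp_id", "beta1"]].itertuples(index=False))
    recs = cis_eqtl_scan(expr, dataset, de_genes, alpha=0.05, clr_beta=beta)
    table = pd.DataFrame([asdict(r) for r in recs])
    table.to_csv(ROOT / "eqtl.tsv", sep="\t", index=False)
    if table.empty:
        print("no cis-eQTL below alpha")
        return
    counts = table["direction"].value_counts().to_dict()
    print(f"{len(table)} cis-eQTL records on "
          f"{table['gene_id'].nunique()} genes; directions: {counts}")


if __name__ == "__main__":
    main()
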