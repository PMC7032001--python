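#!/usr/bin/env python
"""Call cis co-location between DE lncRNAs and protein-coding genes.

A lncRNA and an mRNA on the same chromosome within 100 kb (overlap counts
as distance 0) form a cis pair — the proximity proxy for cis regulation.
Writes the per-genotype cis-pair tables and prints, for each of the three
highest-degree DE lncRNAs, its co-located genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from lncnet import io as lio
from lncnet.expression import call_de, compute_fpkm
from lncnet.genome import cis_pair_table, read_gff3


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/cis")
    ap.add_argument("--window", type=int, default=100_000)
    args = ap.parse_args()
    study, outdir = Path(args.study), Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = lio.read_counts(study / "counts.tsv")
    design = lio.read_design(study / "design.tsv")
    loci = read_gff3(study / "features.gff3")
    lengths = pd.Series({l.feature_id: l.end - l.start + 1 for l in loci}).reindex(counts.index)
    biotype = pd.Series({l.feature_id: l.biotype for l in loci}).reindex(counts.index)
    fpkm = compute_fpkm(counts, lengths, design.set_index("sample_id")["library_size"])

    for geno in sorted(design["genotype"].unique()):
        de = call_de(counts, fpkm, design, geno)
        de_lnc = de.table.index[(de.table["call"] != "not_de") & (biotype == "lncRNA")]
        table = cis_pair_table(loci, window=args.window, lnc_ids=de_lnc)
        table.to_csv(outdir / f"cis_pairs_{geno}.tsv", sep="\t", index=False)
        print(f"{geno}: {len(table)} cis pairs for {table['lncrna_id'].nunique()} DE lncRNAs "
              f"(window {args.window/1000:.0f} kb)")
        top = table["lncrna_id"].value_counts().head(3)
        for lnc, n in top.items():
            genes = table.loc[table["lncrna_id"] == lnc].nsmallest(4, "distance_bp")
            desc = ", ".join(f"{g.gene_id} ({g.distance_bp} bp)" for g in genes.itertuples())
            print(f"  {lnc}: {n} co-located genes, nearest: {desc}")


if __name__ == "__main__":
    main()
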