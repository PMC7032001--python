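#!/usr/bin/env python
"""Profile differentially expressed transcription factors across genotypes.

Classifies each DE TF as genotype-specific, co-expressed (same direction in
both genotypes) or conversely expressed, tallies families per class, and
extracts the network edges whose mRNA endpoint is a TF (TF-lncRNA
co-expression pairs).
"""

import argparse
from pathlib import Path

import pandas as pd

from lncnet import io as lio
from lncnet.expression import DETable, call_de, compute_fpkm
from lncnet.genome import read_gff3
from lncnet.network import build_network
from lncnet.tf import classify_tf_expression, tf_lncrna_pairs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/tf")
    args = ap.parse_args()
    study, outdir = Path(args.study), Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = lio.read_counts(study / "counts.tsv")
    design = lio.read_design(study / "design.tsv")
    tf_table = lio.read_tf_table(study / "tf_table.tsv")
    loci = read_gff3(study / "features.gff3")
    lengths = pd.Series({l.feature_id: l.end - l.start + 1 for l in loci}).reindex(counts.index)
    biotype = pd.Series({l.feature_id: l.biotype for l in loci}).reindex(counts.index)
    fpkm = compute_fpkm(counts, lengths, design.set_index("sample_id")["library_size"])
    lnc_idx = counts.index[biotype == "lncRNA"]
    mrna_idx = counts.index[biotype == "mRNA"]

    genos = sorted(design["genotype"].unique())
    de = {g: call_de(counts, fpkm, design, g) for g in genos}
    cls = classify_tf_expression(
        DETable(genos[0], de[genos[0]].table.loc[mrna_idx]),
        DETable(genos[1], de[genos[1]].table.loc[mrna_idx]),
        tf_table,
    )
    cls.records.to_csv(outdir / "tf_classes.tsv", sep="\t", index=False)
    cls.family_counts.to_csv(outdir / "tf_family_counts.tsv", sep="\t")
    sizes = cls.class_sizes()
    print(f"DE TFs: {sum(sizes.values())} total — "
          f"{sizes['shared_same']} co-expressed in both genotypes, "
          f"{sizes['converse']} conversely expressed, "
          f"{sizes['A_specific']} {genos[0]}-specific, "
          f"{sizes['B_specific']} {genos[1]}-specific")
    for cls_name in ("A_specific", "B_specific"):
        fams = cls.family_counts[cls_name]
        fams = fams[fams > 0].sort_values(ascending=False)
        if len(fams):
            top = ", ".join(f"{fam} ({n})" for fam, n in fams.head(5).items())
            print(f"  {cls_name}: {len(fams)} families, top: {top}")

    for geno in genos:
        net = build_network(
            DETable(geno, de[geno].table.loc[lnc_idx]),
            DETable(geno, de[geno].table.loc[mrna_idx]),
            fpkm, design, geno,
        )
        pairs = tf_lncrna_pairs(net, tf_table)
        pairs.edges.to_csv(outdir / f"tf_lncrna_pairs_{geno}.tsv", sep="\t", index=False)
        print(f"{geno}: {pairs.n_tfs} TFs from {pairs.n_families} families co-expressed "
              f"with {pairs.n_lncrnas} DE lncRNAs ({len(pairs.edges)} pairs)")


if __name__ == "__main__":
    main()
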