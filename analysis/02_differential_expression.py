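#!/usr/bin/env python
"""Call RW-vs-DS differential expression per genotype and compare genotypes.

Reads the study bundle written by 01_simulate_study.py, quantifies FPKM,
runs the NB Wald test with BH correction (q <= 0.05, |log2 ratio| >= 1),
writes per-genotype DE tables, and prints the two-genotype direction
partition (shared up/down, conversely expressed, genotype-specific).
"""

import argparse
from pathlib import Path

from lncnet import io as lio
from lncnet.expression import call_de, compare_genotypes, compute_fpkm, DETable
from lncnet.genome import read_gff3
import pandas as pd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/de")
    args = ap.parse_args()
    study = Path(args.study)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = lio.read_counts(study / "counts.tsv")
    design = lio.read_design(study / "design.tsv")
    loci = read_gff3(study / "features.gff3")
    lengths = pd.Series({l.feature_id: l.end - l.start + 1 for l in loci}).reindex(counts.index)
    biotype = pd.Series({l.feature_id: l.biotype for l in loci}).reindex(counts.index)
    fpkm = compute_fpkm(counts, lengths, design.set_index("sample_id")["library_size"])

    tables = {}
    for geno in sorted(design["genotype"].unique()):
        de = call_de(counts, fpkm, design, geno)
        de.table.to_csv(outdir / f"de_{geno}.tsv", sep="\t")
        tables[geno] = de
        for bt in ("mRNA", "lncRNA"):
            sub = de.table[biotype == bt]
            up, down = (sub["call"] == "up").sum(), (sub["call"] == "down").sum()
            print(f"{geno} {bt}: {up + down} DE ({down} down-regulated, {up} up-regulated)")

    genos = sorted(tables)
    lnc_idx = counts.index[biotype == "lncRNA"]
    part = compare_genotypes(
        DETable(genos[0], tables[genos[0]].table.loc[lnc_idx]),
        DETable(genos[1], tables[genos[1]].table.loc[lnc_idx]),
    )
    s = part.sizes()
    shared = s["shared_up"] + s["shared_down"] + s["up_a_down_b"] + s["down_a_up_b"]
    print(f"\nlncRNAs DE in both genotypes: {shared} "
          f"({s['shared_down']} down, {s['shared_up']} up in both; "
          f"{s['up_a_down_b'] + s['down_a_up_b']} conversely expressed)")
    print(f"{genos[0]}-specific: {s['a_only']}; {genos[1]}-specific: {s['b_only']}")


if __name__ == "__main__":
    main()
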