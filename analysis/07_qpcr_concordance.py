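#!/usr/bin/env python
"""Quantify RNA-seq vs qPCR log2 fold-change concordance.

Joins the qPCR-derived log2(mean RW / mean DS) per probe and genotype with
the RNA-seq log2 FPKM ratio of the same features and fits RNA-seq (y) on
qPCR (x) by ordinary least squares, reporting the slope and R^2.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lncnet import io as lio
from lncnet.expression import call_de, compute_fpkm
from lncnet.genome import read_gff3
from lncnet.qpcr import concordance, qpcr_log2fc


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/qpcr")
    args = ap.parse_args()
    study, outdir = Path(args.study), Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = lio.read_counts(study / "counts.tsv")
    design = lio.read_design(study / "design.tsv")
    qpcr = lio.read_qpcr(study / "qpcr.tsv")
    loci = read_gff3(study / "features.gff3")
    lengths = pd.Series({l.feature_id: l.end - l.start + 1 for l in loci}).reindex(counts.index)
    fpkm = compute_fpkm(counts, lengths, design.set_index("sample_id")["library_size"])

    de = {g: call_de(counts, fpkm, design, g) for g in sorted(design["genotype"].unique())}
    lfc = qpcr_log2fc(qpcr)
    rnaseq = [
        de[g].table.loc[p, "log2_ratio"] if p in de[g].table.index else np.nan
        for p, g in zip(lfc["probe_id"], lfc["genotype"])
    ]
    merged = lfc.assign(rnaseq_log2fc=rnaseq).dropna()
    merged.to_csv(outdir / "concordance_points.tsv", sep="\t", index=False)
    res = concordance(merged["rnaseq_log2fc"], merged["qpcr_log2fc"])
    (outdir / "concordance.json").write_text(json.dumps(res.as_dict(), indent=2, sort_keys=True))
    print(f"{res.n_points} probe x genotype points "
          f"({merged['probe_id'].nunique()} lncRNA probes)")
    print(f"RNA-seq vs qPCR: R^2 = {res.r2:.5f}, slope = {res.slope:.5f}, "
          f"intercept = {res.intercept:.3f}")


if __name__ == "__main__":
    main()
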