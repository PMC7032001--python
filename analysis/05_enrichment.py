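#!/usr/bin/env python
"""GO/KEGG over-representation of the mRNAs co-expressed with DE lncRNAs.

The study set is each genotype's network mRNAs; the population is the
expressed mRNA universe of that genotype.  Runs both the central
hypergeometric test and the length-bias-corrected Wallenius variant and
writes both tables, flagging terms with corrected p < 0.05.
"""

import argparse
from pathlib import Path

import pandas as pd

from lncnet import io as lio
from lncnet.enrichment import hypergeom_enrich, length_weights, wallenius_enrich
from lncnet.expression import DETable, call_de, compute_fpkm
from lncnet.genome import read_gff3
from lncnet.network import build_network


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/enrichment")
    args = ap.parse_args()
    study, outdir = Path(args.study), Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = lio.read_counts(study / "counts.tsv")
    design = lio.read_design(study / "design.tsv")
    loci = read_gff3(study / "features.gff3")
    lengths = pd.Series({l.feature_id: l.end - l.start + 1 for l in loci}).reindex(counts.index)
    biotype = pd.Series({l.feature_id: l.biotype for l in loci}).reindex(counts.index)
    fpkm = compute_fpkm(counts, lengths, design.set_index("sample_id")["library_size"])
    term_maps = {
        "GO": lio.read_term_map(study / "terms_go.tsv"),
        "KEGG": lio.read_term_map(study / "terms_kegg.tsv"),
    }
    lnc_idx = counts.index[biotype == "lncRNA"]
    mrna_idx = counts.index[biotype == "mRNA"]

    for geno in sorted(design["genotype"].unique()):
        de = call_de(counts, fpkm, design, geno)
        net = build_network(
            DETable(geno, de.table.loc[lnc_idx]),
            DETable(geno, de.table.loc[mrna_idx]),
            fpkm, design, geno,
        )
        samples = list(design.loc[design["genotype"] == geno, "sample_id"])
        population = set(mrna_idx[(fpkm.loc[mrna_idx, samples] > 0).any(axis=1)])
        study_set = net.mrna_nodes & population
        print(f"{geno}: {len(study_set)} co-expressed mRNAs against "
              f"{len(population)} expressed mRNAs")
        de_flags = pd.Series({f: f in study_set for f in sorted(population)})
        weights = length_weights(lengths.reindex(de_flags.index), de_flags)
        for ns, tm in sorted(term_maps.items()):
            hyper = hypergeom_enrich(study_set, population, tm)
            wall = wallenius_enrich(study_set, population, tm, weights)
            hyper.table.to_csv(outdir / f"{geno}_{ns}_hypergeometric.tsv", sep="\t", index=False)
            wall.table.to_csv(outdir / f"{geno}_{ns}_wallenius.tsv", sep="\t", index=False)
            sig = hyper.table[hyper.table["p_corrected"] < 0.05]
            print(f"  {ns}: {len(sig)} significant terms (corrected p < 0.05)")
            for row in sig.head(3).itertuples():
                print(f"    {row.term_id}: k/K = {row.k}/{row.K}, "
                      f"rich factor {row.rich_factor:.2f}, corrected p {row.p_corrected:.2e}")


if __name__ == "__main__":
    main()
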