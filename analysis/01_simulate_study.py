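#!/usr/bin/env python
"""Generate the synthetic drought/re-watering study and write its bundle.

Produces counts, design, GFF3 annotation, GO/KEGG term maps, the TF family
table, the qPCR table and the planted-truth table under results/study/.
Downstream drivers (02-07) read these files, exercising the same TSV
interfaces a real study would use.
"""

import argparse

from lncnet.simulate import SimulationConfig, generate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/study")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    bundle = generate_study(cfg)
    paths = bundle.write(args.outdir)

    truth = bundle.truth
    n_de = truth.groupby("genotype")["is_de"].sum().astype(int)
    print(f"study written to {args.outdir}")
    print(f"  features: {cfg.n_mrna} mRNA + {cfg.n_lncrna} lncRNA on {cfg.n_chromosomes} chromosomes")
    print(f"  design: 2 genotypes x 2 treatments x {cfg.n_replicates} replicates "
          f"= {len(bundle.design)} libraries")
    print(f"  planted DE features per genotype: {dict(n_de)}")
    print(f"  planted modules: {cfg.n_modules} x ({cfg.module_size[0]} lncRNA, "
          f"{cfg.module_size[1]} mRNA)")
    print("  files:", ", ".join(p.name for p in paths.values()))


if __name__ == "__main__":
    main()
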