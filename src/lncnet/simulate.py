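"""Synthetic two-genotype drought/re-watering RNA-seq study generator.

Emulates the 2 genotype x 2 treatment (drought stress DS, re-watering RW)
x 3 replicate bulk RNA-seq design: negative-binomial fragment counts with
planted differential-expression effects, planted correlated lncRNA-mRNA
co-expression modules (shared per-sample latent factors), genomic
coordinates with module lncRNAs placed cis to a partner mRNA, GO/KEGG term
maps with one planted enriched pathway, a transcription-factor family
table, and a noisy qPCR relative-expression table.  A TruthTable records
every planted effect so downstream recovery is testable.

All randomness flows from a single integer seed through a named
numpy Generator; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

TF_FAMILIES = (
    "MYB", "bHLH", "ERF", "WRKY", "PIF", "GATA", "DIVARICATA", "HSF", "NAC", "NFY",
)

GENOTYPES = ("tolerant", "sensitive")
TREATMENTS = ("DS", "RW")
PATHWAY_TERM = "KEGG:hormone_signal"  # planted enriched pathway term


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the generator's study conditions: a desk-scale transcriptome
    (2000 mRNAs, 300 lncRNAs) with 10% of features differentially expressed
    per genotype at |log2 fold change| in [1.5, 2.5], and three 5-lncRNA x
    20-mRNA co-expression modules.

    Biological replicate variability is modelled per feature: non-module
    features carry it as NB overdispersion (``dispersion``, a squared
    biological CV of 0.4 by default), while module members' biological
    variability is instead a per-sample log2-scale factor shared by the
    whole module (``module_latent_sd``, the co-expression driver), on top
    of a small residual technical dispersion
    (``module_residual_dispersion``).  The two sources are alternatives,
    not additive: a co-expression module is coherent precisely because the
    shared regulator accounts for its members' replicate-to-replicate
    variation.  Module fold changes are drawn per module (one magnitude and
    direction for all members) so planted pairs share their expression
    trend.
    """

    n_mrna: int = 2000
    n_lncrna: int = 300
    n_chromosomes: int = 5
    n_replicates: int = 3
    frac_de: float = 0.10
    lfc_range: tuple[float, float] = (1.5, 2.5)
    module_lfc_range: tuple[float, float] = (1.5, 2.5)
    dispersion: float = 0.05
    module_residual_dispersion: float = 0.01
    base_mean_log_range: tuple[float, float] = (1.5, 2.5)  # log10 FPKM
    n_modules: int = 3
    module_size: tuple[int, int] = (5, 20)  # (lncRNAs, mRNAs) per module
    module_latent_sd: float = 1.5  # log2 units
    noise_sd: float = 0.25  # qPCR log2 noise
    library_size_range: tuple[int, int] = (15_000_000, 25_000_000)
    cis_gap_range: tuple[int, int] = (1_000, 50_000)  # lncRNA-partner gap, bp
    n_go_terms: int = 30
    n_kegg_terms: int = 15
    n_tf: int = 150
    n_qpcr_probes: int = 9
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_mrna=self.n_mrna, n_lncrna=self.n_lncrna,
            n_chromosomes=self.n_chromosomes, n_replicates=self.n_replicates,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not (0 <= self.frac_de < 1):
            raise ValueError("frac_de must lie in [0, 1)")
        for name, rng in (("lfc_range", self.lfc_range), ("module_lfc_range", self.module_lfc_range)):
            if self.n_modules > 0 or name == "lfc_range":
                if rng[0] > rng[1]:
                    raise ValueError(f"{name} must be (lo, hi) with lo <= hi")
                if self.frac_de > 0 and rng[0] < 1:
                    # planted effects must clear the |log2 ratio| >= 1 call filter
                    raise ValueError(f"{name} minimum must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_modules * self.module_size[0] > self.n_lncrna:
            raise ValueError("module lncRNAs exceed n_lncrna")
        if self.n_modules * self.module_size[1] > self.n_mrna:
            raise ValueError("module mRNAs exceed n_mrna")
        if self.n_tf > self.n_mrna:
            raise ValueError("n_tf exceeds n_mrna")


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: SimulationConfig
    counts: pd.DataFrame          # features x samples, integer fragments
    design: pd.DataFrame          # sample_id, genotype, treatment, replicate, library_size
    annotation: pd.DataFrame      # feature_id, chrom, start, end, strand, biotype, length
    term_maps: dict               # namespace -> DataFrame(feature_id, term_id)
    tf_table: pd.DataFrame        # feature_id, family
    qpcr: pd.DataFrame            # probe_id, genotype, treatment, replicate, relative_expression
    truth: pd.DataFrame           # feature_id, genotype, true_log2fc, is_de, module_id, tf_family

    @property
    def feature_lengths(self) -> pd.Series:
        return self.annotation.set_index("feature_id")["length"].reindex(self.counts.index)

    def write(self, outdir: str | Path) -> dict:
        """Write the bundle as TSV/GFF3 files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "design": outdir / "design.tsv",
            "gff3": outdir / "features.gff3",
            "tf_table": outdir / "tf_table.tsv",
            "qpcr": outdir / "qpcr.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.counts.rename_axis("feature_id").to_csv(paths["counts"], sep="\t")
        self.design.to_csv(paths["design"], sep="\t", index=False)
        write_gff3(self.annotation, paths["gff3"])
        self.tf_table.to_csv(paths["tf_table"], sep="\t", index=False)
        # %.17g keeps float columns bit-exact across a write/read cycle
        self.qpcr.to_csv(paths["qpcr"], sep="\t", index=False, float_format="%.17g")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
        for ns, tmap in self.term_maps.items():
            p = outdir / f"terms_{ns.lower()}.tsv"
            tmap.to_csv(p, sep="\t", index=False)
            paths[f"terms_{ns.lower()}"] = p
        return paths


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write feature loci as GFF3 (1-based inclusive, biotype in column 3)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tlncnet_sim\t{row.biotype}\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.feature_id}\n"
            )


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for geno in GENOTYPES:
        for trt in TREATMENTS:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{trt}_{geno}_{rep}",
                        "genotype": geno,
                        "treatment": trt,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _plant_effects(config: SimulationConfig, rng: np.random.Generator,
                   mrna_ids: list, lnc_ids: list) -> pd.DataFrame:
    """Truth table: per feature x genotype, planted log2FC and module id.

    Module members are DE in both genotypes with a module-wide direction so
    planted co-expression pairs share their expression trend; background DE
    features are drawn independently per genotype.
    """
    all_ids = mrna_ids + lnc_ids
    n_lnc_m, n_mrna_m = config.module_size
    module_of = {}
    lnc_pool = rng.permutation(lnc_ids)
    mrna_pool = rng.permutation(mrna_ids)
    for m in range(config.n_modules):
        for f in lnc_pool[m * n_lnc_m:(m + 1) * n_lnc_m]:
            module_of[f] = m
        for f in mrna_pool[m * n_mrna_m:(m + 1) * n_mrna_m]:
            module_of[f] = m
    module_dir = rng.choice([-1.0, 1.0], size=max(config.n_modules, 1))
    module_beta = rng.uniform(*config.module_lfc_range, size=max(config.n_modules, 1))

    frames = []
    for geno in GENOTYPES:
        lfc = np.zeros(len(all_ids))
        is_de = np.zeros(len(all_ids), dtype=bool)
        # background DE, independent per genotype
        n_bg = int(round(config.frac_de * len(all_ids)))
        bg = rng.choice(len(all_ids), size=n_bg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_bg)
        lfc[bg] = signs * rng.uniform(*config.lfc_range, size=n_bg)
        is_de[bg] = True
        # module members override: DE in every genotype with one module-wide
        # magnitude and direction (a module tracks a single regulator)
        for i, f in enumerate(all_ids):
            m = module_of.get(f)
            if m is not None:
                lfc[i] = module_dir[m] * module_beta[m]
                is_de[i] = True
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": all_ids,
                    "genotype": geno,
                    "true_log2fc": lfc,
                    "is_de": is_de,
                    "module_id": [module_of.get(f, -1) for f in all_ids],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _place_features(config: SimulationConfig, rng: np.random.Generator,
                    mrna_ids: list, lnc_ids: list, lengths: pd.Series,
                    truth: pd.DataFrame) -> pd.DataFrame:
    """Lay features on chromosomes; module lncRNAs sit within the cis gap of
    a partner module mRNA so co-location has planted positives."""
    mod = truth[truth["genotype"] == GENOTYPES[0]].set_index("feature_id")["module_id"]
    partner_after = {}  # mrna id -> lnc id to insert right after it
    placed_lnc = set()
    for m in sorted(set(mod[mod >= 0])):
        mod_lnc = [f for f in lnc_ids if mod.get(f, -1) == m]
        mod_mrna = [f for f in mrna_ids if mod.get(f, -1) == m]
        partners = rng.choice(mod_mrna, size=len(mod_lnc), replace=False)
        for lnc, mrna in zip(mod_lnc, partners):
            partner_after[mrna] = lnc
            placed_lnc.add(lnc)

    # blocks keep a module lncRNA on the same chromosome as its partner
    blocks = []
    free_lnc = iter([f for f in lnc_ids if f not in placed_lnc])
    interleave = rng.permutation(mrna_ids)
    for i, f in enumerate(interleave):
        block = [f]
        if f in partner_after:
            block.append(partner_after[f])
        blocks.append(block)
        if i % 7 == 3:  # sprinkle non-module lncRNAs between genes
            nxt = next(free_lnc, None)
            if nxt is not None:
                blocks.append([nxt])
    blocks.extend([f] for f in free_lnc)

    block_chrom = np.sort(rng.integers(1, config.n_chromosomes + 1, size=len(blocks)))
    order = [f for b in blocks for f in b]
    chrom_of = np.concatenate(
        [np.full(len(b), c) for b, c in zip(blocks, block_chrom)]
    )
    rows = []
    pos = {}
    lo_gap, hi_gap = config.cis_gap_range
    for f, c in zip(order, chrom_of):
        start = pos.get(c, 0) + int(rng.integers(lo_gap, hi_gap))
        end = start + int(lengths[f]) - 1
        pos[c] = end
        rows.append(
            {
                "feature_id": f,
                "chrom": f"chr{c}",
                "start": start,
                "end": end,
                "strand": str(rng.choice(["+", "-"])),
                "biotype": "lncRNA" if f in set(lnc_ids) else "mRNA",
                "length": int(lengths[f]),
            }
        )
    return pd.DataFrame(rows)


def generate_study(config: SimulationConfig) -> StudyBundle:
    """Generate one full synthetic study from a config.

    Counts are NB(mu, phi) with Var = mu + phi*mu^2.  The expected count of
    feature f in sample s is fpkm_f * 2^(lfc_f * I[RW]) * 2^(z_{m,s}) *
    length_f * library_size_s / 1e9, where z is the module latent factor
    (zero for non-module features).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mrna_ids = [f"MRNA_{i:05d}" for i in range(1, config.n_mrna + 1)]
    lnc_ids = [f"LNC_{i:04d}" for i in range(1, config.n_lncrna + 1)]
    all_ids = mrna_ids + lnc_ids
    n_feat = len(all_ids)

    lengths = pd.Series(
        np.concatenate(
            [
                rng.integers(600, 6000, size=config.n_mrna),
                rng.integers(400, 2000, size=config.n_lncrna),
            ]
        ),
        index=all_ids,
    )

    truth = _plant_effects(config, rng, mrna_ids, lnc_ids)
    annotation = _place_features(config, rng, mrna_ids, lnc_ids, lengths, truth)

    design = _sample_ids(config)
    target_depth = rng.integers(*config.library_size_range, size=len(design))

    base_fpkm = 10 ** rng.uniform(*config.base_mean_log_range, size=n_feat)

    lfc_wide = truth.pivot(index="feature_id", columns="genotype", values="true_log2fc").reindex(all_ids)
    mod_wide = truth[truth["genotype"] == GENOTYPES[0]].set_index("feature_id")["module_id"].reindex(all_ids)

    # shared latent factor per (module, genotype, sample), log2 scale
    latent = {
        (m, geno): rng.normal(0.0, config.module_latent_sd, size=config.n_replicates * 2)
        for m in range(config.n_modules)
        for geno in GENOTYPES
    }

    counts = np.zeros((n_feat, len(design)), dtype=np.int64)
    has_mod = mod_wide.to_numpy() >= 0
    for geno in GENOTYPES:
        cols = design.index[design["genotype"] == geno]
        for j, col in enumerate(cols):
            trt = design.loc[col, "treatment"]
            depth = target_depth[col]
            shift = lfc_wide[geno].to_numpy() * (trt == "RW")
            z = np.zeros(n_feat)
            if has_mod.any():
                z[has_mod] = np.array(
                    [latent[(int(m), geno)][j] for m in mod_wide.to_numpy()[has_mod]]
                )
            fpkm_exp = base_fpkm * 2.0 ** (shift + z)
            mu = fpkm_exp * lengths.to_numpy() * depth / 1e9
            # module members: biological variability lives in the shared
            # factor z, leaving only residual dispersion; others carry it
            # as gene-wise NB overdispersion
            draw = _nb_draw(rng, mu, config.dispersion)
            if has_mod.any():
                draw[has_mod] = _nb_draw(
                    rng, mu[has_mod], config.module_residual_dispersion
                )
            counts[:, col] = draw  # design has a RangeIndex
    counts_df = pd.DataFrame(counts, index=all_ids, columns=list(design["sample_id"]))
    design = design.assign(library_size=counts_df.sum(axis=0).to_numpy())

    de_union = set(truth.loc[truth["is_de"], "feature_id"])
    term_maps = _plant_terms(config, rng, mrna_ids, mod_wide, de_union)
    tf_table = _plant_tfs(config, rng, mrna_ids)
    truth = truth.merge(
        tf_table.rename(columns={"family": "tf_family"}), on="feature_id", how="left"
    )

    probe_pool = truth.loc[
        (truth["genotype"] == GENOTYPES[0])
        & truth["is_de"]
        & truth["feature_id"].str.startswith("LNC_"),
        "feature_id",
    ].tolist()
    n_probes = min(config.n_qpcr_probes, len(probe_pool))
    probes = sorted(rng.choice(probe_pool, size=n_probes, replace=False)) if n_probes else []
    qpcr = generate_qpcr(truth, probes, config.noise_sd,
                         seed=int(rng.integers(0, 2**31 - 1)),
                         n_replicates=config.n_replicates)

    return StudyBundle(
        config=config,
        counts=counts_df,
        design=design[["sample_id", "genotype", "treatment", "replicate", "library_size"]],
        annotation=annotation,
        term_maps=term_maps,
        tf_table=tf_table,
        qpcr=qpcr,
        truth=truth,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) draws with Var = mu + phi*mu^2; phi = 0 is Poisson."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _plant_terms(config, rng, mrna_ids, mod_wide, de_union) -> dict:
    module_mrna = [f for f in mrna_ids if mod_wide.get(f, -1) >= 0]
    maps = {}
    for ns, n_terms, size_rng in (
        ("GO", config.n_go_terms, (20, 120)),
        ("KEGG", config.n_kegg_terms, (15, 80)),
    ):
        rows = []
        for t in range(1, n_terms + 1):
            term = f"{ns}:{t:07d}"
            members = rng.choice(mrna_ids, size=int(rng.integers(*size_rng)), replace=False)
            rows.extend({"feature_id": f, "term_id": term} for f in members)
        maps[ns] = pd.DataFrame(rows).drop_duplicates(ignore_index=True)
    # planted pathway: all module mRNAs plus stress-responsive background,
    # so both the truth-driven and the called co-expression sets hit it
    non_module = [f for f in mrna_ids if f not in set(module_mrna)]
    de_bg = [f for f in non_module if f in de_union]
    other = [f for f in non_module if f not in de_union]
    extra = list(rng.choice(de_bg, size=min(20, len(de_bg)), replace=False)) + list(
        rng.choice(other, size=min(20, len(other)), replace=False)
    )
    planted = pd.DataFrame(
        {"feature_id": list(module_mrna) + extra, "term_id": PATHWAY_TERM}
    )
    maps["KEGG"] = pd.concat([maps["KEGG"], planted], ignore_index=True)
    return maps


def _plant_tfs(config, rng, mrna_ids) -> pd.DataFrame:
    tf_ids = rng.choice(mrna_ids, size=config.n_tf, replace=False)
    fams = rng.choice(TF_FAMILIES, size=config.n_tf)
    return pd.DataFrame({"feature_id": sorted(tf_ids)}).assign(
        family=pd.Series(fams, index=np.argsort(tf_ids)).sort_index().to_numpy()
    )


def truth_de_records(truth: pd.DataFrame, genotype: str, feature_ids) -> "DETable":
    """Build DE records for one genotype straight from the truth table.

    Used to drive downstream stages with perfect DE knowledge, isolating
    their recovery behaviour from the DE caller's.
    """
    from .expression import DETable

    tg = truth[truth["genotype"] == genotype].set_index("feature_id").reindex(feature_ids)
    if tg["is_de"].isna().any():
        raise KeyError("feature ids absent from truth table")
    call = np.where(
        ~tg["is_de"].astype(bool), "not_de", np.where(tg["true_log2fc"] > 0, "up", "down")
    )
    table = pd.DataFrame(
        {"log2_ratio": tg["true_log2fc"].to_numpy(), "call": call}, index=pd.Index(feature_ids)
    )
    table.index.name = "feature_id"
    return DETable(genotype=genotype, table=table)


def planted_pairs(truth: pd.DataFrame) -> set:
    """All planted same-module (lncRNA, mRNA) pairs."""
    t0 = truth[truth["genotype"] == truth["genotype"].iloc[0]]
    mod = t0[t0["module_id"] >= 0]
    pairs = set()
    for m, grp in mod.groupby("module_id"):
        lncs = [f for f in grp["feature_id"] if f.startswith("LNC_")]
        mrnas = [f for f in grp["feature_id"] if f.startswith("MRNA_")]
        pairs.update((l, r) for l in lncs for r in mrnas)
    return pairs


def module_members(truth: pd.DataFrame) -> set:
    """Feature ids of all planted module members."""
    t0 = truth[truth["genotype"] == truth["genotype"].iloc[0]]
    return set(t0.loc[t0["module_id"] >= 0, "feature_id"])


def generate_qpcr(
    truth: pd.DataFrame,
    probe_ids,
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Noisy qPCR relative-expression readouts for selected probes.

    DS replicates have relative expression 2^N(0, noise_sd); RW replicates
    2^(true_log2fc + N(0, noise_sd)).  With noise_sd = 0 the derived
    log2(mean RW / mean DS) equals the planted log2FC exactly.
    """
    known = set(truth["feature_id"])
    missing = [p for p in probe_ids if p not in known]
    if missing:
        raise KeyError(f"probe ids absent from truth table: {missing}")
    rng = np.random.default_rng(seed)
    tl = truth.set_index(["feature_id", "genotype"])["true_log2fc"]
    rows = []
    for probe in probe_ids:
        for geno in truth["genotype"].unique():
            lfc = tl.loc[(probe, geno)]
            for trt in TREATMENTS:
                base = lfc if trt == "RW" else 0.0
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "probe_id": probe,
                            "genotype": geno,
                            "treatment": trt,
                            "replicate": rep,
                            "relative_expression": float(
                                2.0 ** (base + rng.normal(0.0, noise_sd))
                            ),
                        }
                    )
    return pd.DataFrame(rows)
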