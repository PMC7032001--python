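"""End-to-end orchestration: counts -> FPKM -> DE -> network -> downstream.

The pipeline mirrors the analysis order of a two-genotype drought /
re-watering lncRNA study: quantify FPKM, call RW-vs-DS differential
expression per genotype, build the per-genotype bipartite lncRNA-mRNA
co-expression network from the DE sets, then characterise it (degree/hub
summaries, trend counts, pathway subnetworks), call cis co-location for DE
lncRNAs, run GO/KEGG enrichment on the co-expressed mRNAs, profile
transcription factors across genotypes, and score RNA-seq/qPCR
concordance.  The single report dict (written as report.json) carries
every headline count and is the machine-readable source of truth.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .expression import call_de, compare_genotypes, compute_fpkm, validate_design
from .genome import cis_pair_table, read_gff3
from .enrichment import hypergeom_enrich, length_weights, wallenius_enrich
from .network import build_network, degree_summary, export_network, subnetwork_by_term
from .qpcr import concordance, qpcr_log2fc
from .simulate import SimulationConfig, StudyBundle, generate_study
from .tf import classify_tf_expression, tf_lncrna_pairs

log = logging.getLogger("lncnet.pipeline")


@dataclass
class PipelineConfig:
    """Thresholds and inputs for one pipeline run.

    Exactly one of ``synthetic`` or ``inputs`` must be given.  Thresholds
    default to the study's printed values: q <= 0.05 and |log2 ratio| >= 1
    for DE, |PCC| >= 0.95 and p < 0.05 for edges, corrected p < 0.05 for
    enrichment, and a 100 kb cis window.
    """

    synthetic: SimulationConfig | None = None
    inputs: dict | None = None  # keys: counts, design, gff3, terms_go, terms_kegg, tf_table, qpcr
    q_max: float = 0.05
    lfc_min: float = 1.0
    epsilon: float = 0.1
    r_min: float = 0.95
    p_max: float = 0.05
    cis_window: int = 100_000
    enrichment_method: str = "hypergeometric"  # or "wallenius"
    n_length_bins: int = 20
    subnetwork_term: str | None = None
    outdir: str | None = None

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic config or input paths required")
        if not (0 < self.q_max <= 1) or self.lfc_min < 0 or self.epsilon < 0:
            raise ValueError("DE thresholds out of range")
        if not (0 <= self.r_min <= 1) or not (0 < self.p_max <= 1):
            raise ValueError("network thresholds out of range")
        if self.cis_window < 0:
            raise ValueError("cis window must be >= 0")
        if self.enrichment_method not in ("hypergeometric", "wallenius"):
            raise ValueError("enrichment_method must be hypergeometric or wallenius")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(
            synthetic=SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in syn.items()
            }) if syn else None,
            **raw,
        )
        cfg.validate()
        return cfg


def load_inputs(paths: dict):
    """Read a study from TSV/GFF3 files into in-memory tables."""
    counts = lio.read_counts(paths["counts"])
    design = lio.read_design(paths["design"])
    loci = read_gff3(paths["gff3"])
    annotation = pd.DataFrame(
        {
            "feature_id": [l.feature_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand": [l.strand for l in loci],
            "biotype": [l.biotype for l in loci],
            "length": [l.end - l.start + 1 for l in loci],
        }
    )
    term_maps = {
        "GO": lio.read_term_map(paths["terms_go"]),
        "KEGG": lio.read_term_map(paths["terms_kegg"]),
    }
    tf_table = lio.read_tf_table(paths["tf_table"])
    qpcr = lio.read_qpcr(paths["qpcr"]) if "qpcr" in paths else None
    return counts, design, annotation, term_maps, tf_table, qpcr


def validate_inputs(counts, design, annotation, term_maps, tf_table) -> list[dict]:
    """Cross-reference checks; returns a list of violations (empty = valid).

    Each violation is {"level": "error"|"warning", "message": str}.
    """
    out = []

    def err(msg):
        out.append({"level": "error", "message": msg})

    def warn(msg):
        out.append({"level": "warning", "message": msg})

    try:
        validate_design(design)
    except ValueError as exc:
        err(str(exc))
        return out
    extra = set(counts.columns) - set(design["sample_id"])
    if extra:
        err(f"samples in counts absent from design: {sorted(extra)}")
    missing = set(design["sample_id"]) - set(counts.columns)
    if missing:
        err(f"design samples absent from counts: {sorted(missing)}")
    if counts.index.duplicated().any():
        err("duplicate feature ids in counts")
    arr = counts.to_numpy()
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        err("counts must be non-negative integers")
    ann_ids = set(annotation["feature_id"])
    no_len = set(counts.index) - ann_ids
    if no_len:
        err(f"{len(no_len)} counted features missing from annotation")
    orphan = ann_ids - set(counts.index)
    if orphan:
        warn(f"{len(orphan)} annotated features missing from counts")
    for ns, tm in term_maps.items():
        unknown = set(tm["feature_id"]) - ann_ids
        if unknown:
            warn(f"{ns}: {len(unknown)} term-mapped features not annotated")
    unknown_tf = set(tf_table["feature_id"]) - ann_ids
    if unknown_tf:
        warn(f"{len(unknown_tf)} TF features not annotated")
    return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict.

    When ``config.outdir`` is set, per-stage tables and report.json are
    written there.  Identical config (and synthetic seed) gives a
    byte-identical report.
    """
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-22s %6.1fs", name, time.time() - t0)

    if config.synthetic is not None:
        bundle = generate_study(config.synthetic)
        counts, design, annotation = bundle.counts, bundle.design, bundle.annotation
        term_maps, tf_table, qpcr = bundle.term_maps, bundle.tf_table, bundle.qpcr
    else:
        bundle = None
        counts, design, annotation, term_maps, tf_table, qpcr = load_inputs(config.inputs)
    stage("load")

    violations = validate_inputs(counts, design, annotation, term_maps, tf_table)
    errors = [v for v in violations if v["level"] == "error"]
    if errors:
        raise RuntimeError(f"input validation failed: {errors}")

    lengths = annotation.set_index("feature_id")["length"].reindex(counts.index)
    lib = design.set_index("sample_id")["library_size"]
    fpkm = compute_fpkm(counts, lengths, lib)
    stage("fpkm")

    biotype = annotation.set_index("feature_id")["biotype"].reindex(counts.index)
    lnc_ids = counts.index[biotype == "lncRNA"]
    mrna_ids = counts.index[biotype == "mRNA"]
    genotypes = sorted(design["genotype"].unique())

    report: dict = {
        "genotypes": genotypes,
        "thresholds": {
            "q_max": config.q_max, "lfc_min": config.lfc_min, "epsilon": config.epsilon,
            "r_min": config.r_min, "p_max": config.p_max, "cis_window": config.cis_window,
            "enrichment_method": config.enrichment_method,
        },
        "n_features": {"mRNA": int(len(mrna_ids)), "lncRNA": int(len(lnc_ids))},
        "validation_warnings": [v["message"] for v in violations],
        "per_genotype": {},
    }

    de_lnc, de_mrna, nets = {}, {}, {}
    for geno in genotypes:
        de_all = call_de(
            counts, fpkm, design, geno,
            q_max=config.q_max, lfc_min=config.lfc_min, epsilon=config.epsilon,
        )
        de_lnc[geno] = type(de_all)(geno, de_all.table.loc[lnc_ids])
        de_mrna[geno] = type(de_all)(geno, de_all.table.loc[mrna_ids])
        if outdir:
            de_all.table.to_csv(outdir / f"de_{geno}.tsv", sep="\t")
    stage("differential expression")

    for geno in genotypes:
        net = build_network(
            de_lnc[geno], de_mrna[geno], fpkm, design, geno,
            r_min=config.r_min, p_max=config.p_max,
        )
        nets[geno] = net
        if outdir:
            net.edges.to_csv(outdir / f"edges_{geno}.tsv", sep="\t", index=False)
            (outdir / f"network_{geno}.sif").write_text(export_network(net, "SIF"))
            (outdir / f"network_{geno}.graphml").write_text(export_network(net, "GraphML"))
    stage("co-expression networks")

    part = compare_genotypes(de_lnc[genotypes[0]], de_lnc[genotypes[1]]) if len(genotypes) == 2 else None
    part_mrna = compare_genotypes(de_mrna[genotypes[0]], de_mrna[genotypes[1]]) if len(genotypes) == 2 else None

    loci = [
        row_to_locus(r) for r in annotation.itertuples(index=False)
    ]
    tf_cls = (
        classify_tf_expression(de_mrna[genotypes[0]], de_mrna[genotypes[1]], tf_table)
        if len(genotypes) == 2
        else None
    )
    if tf_cls is not None and outdir:
        tf_cls.records.to_csv(outdir / "tf_classes.tsv", sep="\t", index=False)
        tf_cls.family_counts.to_csv(outdir / "tf_family_counts.tsv", sep="\t")

    sub_term = config.subnetwork_term
    if sub_term is None and any(
        (tm["term_id"] == "KEGG:hormone_signal").any() for tm in term_maps.values()
    ):
        sub_term = "KEGG:hormone_signal"

    for geno in genotypes:
        net = nets[geno]
        summ = degree_summary(net)
        gs: dict = {
            "de_mrna": {"up": de_mrna[geno].n_up(), "down": de_mrna[geno].n_down(),
                        "total": de_mrna[geno].n_up() + de_mrna[geno].n_down()},
            "de_lncrna": {"up": de_lnc[geno].n_up(), "down": de_lnc[geno].n_down(),
                          "total": de_lnc[geno].n_up() + de_lnc[geno].n_down()},
            "network": summ.as_dict(),
        }

        # cis co-location of DE lncRNAs
        cis = cis_pair_table(loci, window=config.cis_window,
                             lnc_ids=de_lnc[geno].de_features())
        gs["cis_pairs"] = int(len(cis))
        if outdir:
            cis.to_csv(outdir / f"cis_pairs_{geno}.tsv", sep="\t", index=False)

        # enrichment of co-expressed mRNAs against the expressed universe
        geno_samples = list(design.loc[design["genotype"] == geno, "sample_id"])
        expressed = set(mrna_ids[(fpkm.loc[mrna_ids, geno_samples] > 0).any(axis=1)])
        study = net.mrna_nodes & expressed
        gs["enrichment"] = {}
        for ns, tm in sorted(term_maps.items()):
            if not study:
                gs["enrichment"][ns] = {"n_terms": 0, "n_significant": 0, "top_term": None}
                continue
            if config.enrichment_method == "wallenius":
                de_flags = pd.Series(
                    [f in study for f in sorted(expressed)], index=sorted(expressed)
                )
                wts = length_weights(
                    lengths.reindex(sorted(expressed)), de_flags, n_bins=config.n_length_bins
                )
                res = wallenius_enrich(study, expressed, tm, wts)
            else:
                res = hypergeom_enrich(study, expressed, tm)
            sig = res.table[res.table["p_corrected"] < 0.05]
            gs["enrichment"][ns] = {
                "n_terms": int(len(res.table)),
                "n_significant": int(len(sig)),
                "top_term": res.table["term_id"].iloc[0] if len(res.table) else None,
            }
            if outdir:
                res.table.to_csv(outdir / f"enrichment_{geno}_{ns}.tsv", sep="\t", index=False)

        if sub_term is not None:
            ns_map = next(tm for tm in term_maps.values() if (tm["term_id"] == sub_term).any())
            sub = subnetwork_by_term(net, ns_map, sub_term)
            gs["subnetwork"] = {
                "term": sub_term, "n_edges": sub.n_edges,
                "n_lncrna": len(sub.lncrna_nodes), "n_mrna": len(sub.mrna_nodes),
            }

        pairs = tf_lncrna_pairs(net, tf_table)
        gs["tf_lncrna"] = {
            "n_edges": int(len(pairs.edges)), "n_tfs": pairs.n_tfs,
            "n_families": pairs.n_families, "n_lncrnas": pairs.n_lncrnas,
        }
        report["per_genotype"][geno] = gs
    stage("characterisation")

    if part is not None:
        report["lncrna_genotype_comparison"] = part.sizes()
        report["mrna_genotype_comparison"] = part_mrna.sizes()
    if tf_cls is not None:
        report["tf_classes"] = tf_cls.class_sizes()

    if qpcr is not None and len(qpcr):
        qfc = qpcr_log2fc(qpcr)
        rna = []
        for r in qfc.itertuples(index=False):
            src = de_lnc if r.probe_id in set(lnc_ids) else de_mrna
            tab = src[r.genotype].table
            rna.append(tab.loc[r.probe_id, "log2_ratio"] if r.probe_id in tab.index else np.nan)
        qfc = qfc.assign(rnaseq_log2fc=rna).dropna()
        if len(qfc) >= 3 and qfc["qpcr_log2fc"].nunique() > 1:
            conc = concordance(qfc["rnaseq_log2fc"], qfc["qpcr_log2fc"])
            report["qpcr_concordance"] = conc.as_dict()
            if outdir:
                (outdir / "concordance.json").write_text(
                    json.dumps(conc.as_dict(), indent=2, sort_keys=True)
                )
    stage("qpcr concordance")

    if bundle is not None:
        report["synthetic_seed"] = bundle.config.seed

    if outdir:
        (outdir / "report.json").write_text(render_report(report))
    stage("done")
    return report


def render_report(report: dict) -> str:
    """Canonical JSON serialisation of the report (sorted keys)."""
    return json.dumps(report, indent=2, sort_keys=True, default=_json_default)


def row_to_locus(row):
    from .genome import FeatureLocus

    return FeatureLocus(
        feature_id=row.feature_id, chrom=row.chrom, start=int(row.start),
        end=int(row.end), strand=row.strand, biotype=row.biotype,
    )
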