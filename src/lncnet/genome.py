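"""Genomic context: GFF3 reading and lncRNA-gene cis co-location.

Co-location is a distance-window criterion: a lncRNA and a protein-coding
gene on the same chromosome whose interval distance is at most ``window``
bp (overlap counts as distance 0), strand-agnostic.  Coordinates are
1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

BIOTYPES = ("mRNA", "lncRNA")


@dataclass(frozen=True)
class FeatureLocus:
    feature_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."
    biotype: str = "mRNA"

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start {self.start} > end {self.end}")

    @property
    def start0(self) -> int:  # half-open 0-based
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end


class GFF3ParseError(ValueError):
    pass


def read_gff3(path: str | Path) -> list[FeatureLocus]:
    """Parse mRNA/lncRNA records from a GFF3 file; other types are skipped.

    The ID attribute becomes the feature id.  Raises GFF3ParseError with the
    offending line number on malformed records.
    """
    loci = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GFF3ParseError(f"line {lineno}: expected 9 tab-separated columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in BIOTYPES:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr:
                raise GFF3ParseError(f"line {lineno}: missing ID attribute")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from exc
            try:
                loci.append(
                    FeatureLocus(attr["ID"], chrom, s, e, strand, ftype)
                )
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: {exc}") from exc
    return loci


def interval_gap(a: FeatureLocus, b: FeatureLocus) -> int | None:
    """bp distance between two loci; 0 when they overlap; None across
    chromosomes.  For disjoint intervals this is downstream start minus
    upstream end (so immediately adjacent features are 1 bp apart)."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def co_located(
    lnc: FeatureLocus,
    genes,
    window: int = 100_000,
) -> list[tuple[FeatureLocus, int]]:
    """Protein-coding genes within ``window`` bp of a lncRNA.

    Returns (gene, distance) pairs sorted by distance then feature id.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits = []
    for g in genes:
        if g.feature_id == lnc.feature_id:
            continue
        d = interval_gap(lnc, g)
        if d is not None and d <= window:
            hits.append((g, d))
    return sorted(hits, key=lambda t: (t[1], t[0].feature_id))


def cis_pair_table(
    loci,
    window: int = 100_000,
    lnc_ids=None,
) -> pd.DataFrame:
    """All lncRNA-mRNA cis pairs within the window, as a tidy table.

    ``lnc_ids`` optionally restricts the lncRNAs scanned (e.g. the DE set).
    """
    lncs = [l for l in loci if l.biotype == "lncRNA"]
    if lnc_ids is not None:
        wanted = set(lnc_ids)
        lncs = [l for l in lncs if l.feature_id in wanted]
    genes = [l for l in loci if l.biotype == "mRNA"]
    rows = []
    for lnc in lncs:
        for g, d in co_located(lnc, genes, window=window):
            rows.append({"lncrna_id": lnc.feature_id, "gene_id": g.feature_id, "distance_bp": d})
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "distance_bp"])
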