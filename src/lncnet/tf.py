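"""Transcription-factor profiling across the two genotypes.

Differentially expressed TFs are classified by how their RW-vs-DS response
compares between genotypes: specific to one genotype, shared with the same
direction ("co-expressed"), or shared with opposite directions
("conversely expressed").  Network edges whose mRNA endpoint is a TF give
the TF-lncRNA co-expression pairs, rolled up by TF family.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import DETable
from .network import Network

TF_CLASSES = ("A_specific", "B_specific", "shared_same", "converse")


@dataclass
class TFClassification:
    records: pd.DataFrame       # feature_id, family, class, call_A, call_B
    family_counts: pd.DataFrame  # family x class counts

    def class_sizes(self) -> dict:
        return self.records["class"].value_counts().reindex(TF_CLASSES, fill_value=0).to_dict()


def classify_tf_expression(
    de_a: DETable,
    de_b: DETable,
    tf_table: pd.DataFrame,
) -> TFClassification:
    """Classify every DE transcription factor by its two-genotype pattern.

    TFs not differentially expressed in either genotype are excluded; the
    four classes partition the DE-TF universe exactly.
    """
    fam = tf_table.set_index("feature_id")["family"]
    if (fam == "").any() or fam.isna().any():
        raise ValueError("TF families must be non-empty")
    calls_a = de_a.calls()
    calls_b = de_b.calls()
    rows = []
    for tf_id, family in fam.items():
        ca = calls_a.get(tf_id, "not_de")
        cb = calls_b.get(tf_id, "not_de")
        if ca == "not_de" and cb == "not_de":
            continue
        if cb == "not_de":
            cls = "A_specific"
        elif ca == "not_de":
            cls = "B_specific"
        elif ca == cb:
            cls = "shared_same"
        else:
            cls = "converse"
        rows.append(
            {"feature_id": tf_id, "family": family, "class": cls, "call_A": ca, "call_B": cb}
        )
    records = pd.DataFrame(rows, columns=["feature_id", "family", "class", "call_A", "call_B"])
    if records.empty:
        counts = pd.DataFrame(columns=list(TF_CLASSES))
    else:
        counts = (
            records.pivot_table(
                index="family", columns="class", values="feature_id", aggfunc="count", fill_value=0
            )
            .reindex(columns=TF_CLASSES, fill_value=0)
        )
    return TFClassification(records=records, family_counts=counts)


@dataclass
class TFPairSummary:
    edges: pd.DataFrame  # network edges with a family column
    n_tfs: int
    n_families: int
    n_lncrnas: int

    def by_family(self) -> pd.Series:
        if self.edges.empty:
            return pd.Series(dtype=int)
        return self.edges.groupby("family")["mrna_id"].nunique().sort_index()


def tf_lncrna_pairs(net: Network, tf_table: pd.DataFrame) -> TFPairSummary:
    """Co-expression edges whose mRNA endpoint is a transcription factor."""
    fam = tf_table.set_index("feature_id")["family"]
    edges = net.edges[net.edges["mrna_id"].isin(fam.index)].copy()
    edges["family"] = edges["mrna_id"].map(fam)
    return TFPairSummary(
        edges=edges.reset_index(drop=True),
        n_tfs=edges["mrna_id"].nunique(),
        n_families=edges["family"].nunique(),
        n_lncrnas=edges["lncrna_id"].nunique(),
    )
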