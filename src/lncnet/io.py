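"""Tab-delimited readers for the pipeline's external inputs.

All inputs are UTF-8 TSV with a header row, as written by
:meth:`lncnet.simulate.StudyBundle.write`; real studies supply the same
layout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    if counts.index.duplicated().any():
        raise ValueError("duplicate feature ids in counts")
    return counts


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_term_map(path: str | Path) -> pd.DataFrame:
    tm = pd.read_csv(path, sep="\t")
    if not {"feature_id", "term_id"} <= set(tm.columns):
        raise ValueError("term map needs feature_id and term_id columns")
    return tm[["feature_id", "term_id"]]


def read_tf_table(path: str | Path) -> pd.DataFrame:
    tf = pd.read_csv(path, sep="\t")
    if not {"feature_id", "family"} <= set(tf.columns):
        raise ValueError("TF table needs feature_id and family columns")
    return tf


def read_qpcr(path: str | Path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"probe_id", "genotype", "treatment", "replicate", "relative_expression"}
    if not need <= set(q.columns):
        raise ValueError(f"qPCR table needs columns {sorted(need)}")
    return q
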