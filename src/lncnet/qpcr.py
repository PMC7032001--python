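"""RNA-seq vs qPCR fold-change concordance.

Per probe and genotype, the qPCR log2 fold change is log2 of the ratio of
mean relative expression after re-watering to mean relative expression
under drought.  Concordance is the ordinary least-squares regression of
the RNA-seq log2 fold change (y) on the qPCR log2 fold change (x); the
headline statistics are the slope and R^2 = (Pearson r)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def qpcr_log2fc(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per (probe, genotype) log2(mean RW / mean DS) relative expression.

    Expects the tidy qPCR table (probe_id, genotype, treatment, replicate,
    relative_expression) with positive expression values.
    """
    if (qpcr["relative_expression"] <= 0).any():
        raise ValueError("relative expression must be positive")
    means = (
        qpcr.groupby(["probe_id", "genotype", "treatment"])["relative_expression"]
        .mean()
        .unstack("treatment")
    )
    for trt in ("DS", "RW"):
        if trt not in means.columns or means[trt].isna().any():
            raise ValueError(f"every probe/genotype needs {trt} replicates")
    out = np.log2(means["RW"] / means["DS"]).rename("qpcr_log2fc").reset_index()
    return out


@dataclass
class ConcordanceResult:
    n_points: int
    slope: float
    intercept: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
        }


def concordance(rnaseq_lfc, qpcr_lfc) -> ConcordanceResult:
    """OLS of RNA-seq log2FC on qPCR log2FC with R^2 = r^2."""
    y = np.asarray(rnaseq_lfc, dtype=float)
    x = np.asarray(qpcr_lfc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("matched 1-D vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant qPCR predictor")
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        n_points=int(x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )
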