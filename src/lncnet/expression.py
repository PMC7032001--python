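"""Expression quantification and differential-expression calling.

Counts are normalised to FPKM (fragments per kilobase of exon per million
mapped fragments), replicate FPKM values are averaged per (genotype,
treatment) cell, and each genotype is tested for re-watering (RW) versus
drought-stress (DS) differential expression with a negative-binomial Wald
test on size-normalised fragment rates.  A feature is called ``up`` or
``down`` when q <= 0.05 and |log2(FPKM ratio)| >= 1 (RW over DS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DE_CALLS = ("up", "down", "not_de")

REQUIRED_DESIGN_COLS = ("sample_id", "genotype", "treatment", "replicate", "library_size")


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_DESIGN_COLS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    if (design["library_size"] <= 0).any():
        raise ValueError("library_size must be positive")
    bad = set(design["treatment"]) - {"DS", "RW"}
    if bad:
        raise ValueError(f"unknown treatments {bad}; expected DS/RW")


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """FPKM matrix from a fragment-count matrix.

    fpkm[g, s] = count[g, s] * 1e9 / (length[g] * library_size[s])

    Parameters
    ----------
    counts
        Features x samples integer fragment counts.
    lengths
        Exonic length in bp per feature (index aligned to ``counts.index``).
    library_sizes
        Total mapped fragments per sample (index aligned to ``counts.columns``).
    """
    if counts.index.duplicated().any():
        raise ValueError("duplicate feature ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every feature needs a length")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any():
        raise ValueError("every sample needs a library size")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    scale = 1e9 / np.outer(lengths.to_numpy(float), library_sizes.to_numpy(float))
    return pd.DataFrame(counts.to_numpy(float) * scale, index=counts.index, columns=counts.columns)


def condition_means(fpkm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean FPKM per feature per (genotype, treatment) cell.

    Returns a frame with a (genotype, treatment) column MultiIndex.
    """
    validate_design(design)
    missing = set(design["sample_id"]) - set(fpkm.columns)
    if missing:
        raise ValueError(f"design samples absent from expression matrix: {sorted(missing)}")
    out = {}
    for (geno, trt), sub in design.groupby(["genotype", "treatment"], sort=True):
        out[(geno, trt)] = fpkm[list(sub["sample_id"])].mean(axis=1)
    res = pd.DataFrame(out)
    res.columns = pd.MultiIndex.from_tuples(res.columns, names=["genotype", "treatment"])
    return res


def log2_ratio(
    mean_rw,
    mean_ds,
    epsilon: float = 0.1,
):
    """log2((mean_RW + eps) / (mean_DS + eps)), elementwise.

    With ``epsilon == 0`` a zero denominator yields signed infinity and a
    0/0 cell yields 0; callers should treat non-finite ratios (and the
    both-zero case) as degenerate.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rw = np.asarray(mean_rw, dtype=float)
    ds = np.asarray(mean_ds, dtype=float)
    if (rw < 0).any() or (ds < 0).any():
        raise ValueError("mean FPKM must be non-negative")
    num, den = rw + epsilon, ds + epsilon
    with np.errstate(divide="ignore"):
        out = np.where(
            (num == 0) & (den == 0),
            0.0,
            np.where(num == 0, -np.inf, np.log2(np.where(den > 0, num / den, np.inf))),
        )
    return out if out.ndim else float(out)


def nb_test(
    counts_ds: np.ndarray,
    counts_rw: np.ndarray,
    sizes_ds: np.ndarray,
    sizes_rw: np.ndarray,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Two-sided NB Wald test of RW vs DS fragment rates, per feature.

    Counts are modelled NB(mu, phi) with Var = mu + phi*mu^2; the per-sample
    rate is count/library_size.  The statistic is the difference of log mean
    rates over its model-based standard error; the dispersion phi is
    estimated per feature by pooled method of moments on counts normalised
    to the mean library size, floored at 0 (Poisson limit).

    The model variance splits into a known Poisson component and the
    estimated overdispersion component phi*(1/n1 + 1/n2); the statistic is
    referred to a t distribution whose Satterthwaite effective degrees of
    freedom reflect only the estimated share, so the reference approaches
    normal when shot noise dominates and t when overdispersion dominates.
    This keeps the small-sample type-I error near nominal across
    dispersion regimes.

    With few replicates a raw per-feature dispersion is too noisy to rank
    features; as in standard RNA-seq practice the per-feature estimate is
    moderated toward the across-feature median positive dispersion with
    ``prior_df`` prior degrees of freedom (empirical-Bayes shrinkage),
    which the t reference credits as extra degrees of freedom.  Moderation
    is a no-op when the matrix holds a single feature.

    Parameters are 2-D (features x replicates) count arrays and 1-D library
    size vectors.  Returns a p-value per feature; features with all-zero
    counts in both groups get p = 1.
    """
    c1 = np.atleast_2d(np.asarray(counts_ds, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_rw, dtype=float))
    s1 = np.asarray(sizes_ds, dtype=float)
    s2 = np.asarray(sizes_rw, dtype=float)
    n1, n2 = c1.shape[1], c2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    if (s1 <= 0).any() or (s2 <= 0).any():
        raise ValueError("library sizes must be positive")

    # dispersion: pooled MoM on counts rescaled to the mean library size
    sbar = np.concatenate([s1, s2]).mean()
    q1, q2 = c1 * (sbar / s1), c2 * (sbar / s2)
    v_pool = ((n1 - 1) * q1.var(axis=1, ddof=1) + (n2 - 1) * q2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    m_pool = (q1.sum(axis=1) + q2.sum(axis=1)) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(m_pool > 0, (v_pool - m_pool) / m_pool**2, 0.0)

    nu = n1 + n2 - 2
    if prior_df > 0 and phi_raw.size > 1:
        # prior from the unfloored estimates: the median over features is a
        # nearly unbiased centre, while the median of floored values is not
        phi_prior = max(float(np.median(phi_raw[m_pool > 0])), 0.0)
        phi = np.maximum((prior_df * phi_prior + nu * phi_raw) / (prior_df + nu), 0.0)
        df_resid = nu + prior_df
    else:
        phi = np.maximum(phi_raw, 0.0)
        df_resid = nu

    lam1 = (c1 / s1).mean(axis=1)
    lam2 = (c2 / s2).mean(axis=1)
    degenerate = (lam1 == 0) & (lam2 == 0)
    # half-a-fragment floor keeps the log finite when one group is all zero
    floor = 0.5 / sbar
    l1 = np.maximum(lam1, floor)
    l2 = np.maximum(lam2, floor)

    # Var(log lam_g) ~ (1/n^2) sum_i (1/(lam_g s_i) + phi), delta method;
    # split into the known Poisson part A and the estimated part D
    A = (1.0 / (l1[:, None] * s1)).sum(axis=1) / n1**2
    A = A + (1.0 / (l2[:, None] * s2)).sum(axis=1) / n2**2
    D = phi * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(l2) - np.log(l1)) / np.sqrt(A + D)
    z = np.where(lam1 == lam2, 0.0, z)
    with np.errstate(divide="ignore"):
        df_eff = np.where(D > 0, df_resid * (A + D) ** 2 / D**2, np.inf)
    df_eff = np.clip(df_eff, df_resid, 1e9)
    p = 2.0 * stats.t.sf(np.abs(z), df=np.where(np.isfinite(df_eff), df_eff, 1e9))
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DETable:
    """Per-genotype differential-expression results."""

    genotype: str
    table: pd.DataFrame  # feature_id idx; mean_DS, mean_RW, log2_ratio, p, q, call, degenerate

    def calls(self) -> pd.Series:
        return self.table["call"]

    def de_features(self) -> pd.Index:
        return self.table.index[self.table["call"] != "not_de"]

    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())


def call_de(
    counts: pd.DataFrame,
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    genotype: str,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
    epsilon: float = 0.1,
    min_expression_filter: bool = True,
) -> DETable:
    """Call RW-vs-DS differential expression for one genotype.

    ``up`` means higher after re-watering.  The tested universe is, by
    default, features with mean FPKM > 0 in at least one condition of the
    genotype; features outside it are reported ``not_de`` with a degenerate
    flag and excluded from the BH correction.
    """
    validate_design(design)
    sub = design[design["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"genotype {genotype!r} not present in design")
    ds = sub[sub["treatment"] == "DS"]
    rw = sub[sub["treatment"] == "RW"]
    if len(ds) < 2 or len(rw) < 2:
        raise ValueError("need >= 2 replicates in each treatment cell")

    mean_ds = fpkm[list(ds["sample_id"])].mean(axis=1)
    mean_rw = fpkm[list(rw["sample_id"])].mean(axis=1)
    lfc = pd.Series(log2_ratio(mean_rw, mean_ds, epsilon=epsilon), index=fpkm.index)

    if min_expression_filter:
        tested = (mean_ds > 0) | (mean_rw > 0)
    else:
        tested = pd.Series(True, index=fpkm.index)

    p = pd.Series(np.nan, index=fpkm.index)
    q = pd.Series(np.nan, index=fpkm.index)
    if tested.any():
        idx = fpkm.index[tested]
        p.loc[idx] = nb_test(
            counts.loc[idx, list(ds["sample_id"])].to_numpy(),
            counts.loc[idx, list(rw["sample_id"])].to_numpy(),
            ds["library_size"].to_numpy(),
            rw["library_size"].to_numpy(),
        )
        q.loc[idx] = bh_adjust(p.loc[idx].to_numpy())

    call = np.full(len(fpkm.index), "not_de", dtype=object)
    sig = tested.to_numpy() & (q.to_numpy() <= q_max) & np.isfinite(lfc.to_numpy())
    call[sig & (lfc.to_numpy() >= lfc_min)] = "up"
    call[sig & (lfc.to_numpy() <= -lfc_min)] = "down"

    table = pd.DataFrame(
        {
            "mean_DS": mean_ds,
            "mean_RW": mean_rw,
            "log2_ratio": lfc,
            "p": p,
            "q": q,
            "call": call,
            "degenerate": ~tested,
        }
    )
    table.index.name = "feature_id"
    return DETable(genotype=genotype, table=table)


@dataclass
class GenotypePartition:
    """Direction-aware partition of two genotypes' DE feature sets.

    Mirrors the Venn arithmetic used for two-genotype stress-response
    comparisons: the shared classes are disjoint and together equal the DE
    intersection.
    """

    a_only: set = field(default_factory=set)
    b_only: set = field(default_factory=set)
    shared_up: set = field(default_factory=set)
    shared_down: set = field(default_factory=set)
    up_a_down_b: set = field(default_factory=set)
    down_a_up_b: set = field(default_factory=set)

    @property
    def shared(self) -> set:
        return self.shared_up | self.shared_down | self.up_a_down_b | self.down_a_up_b

    def sizes(self) -> dict:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "shared_up": len(self.shared_up),
            "shared_down": len(self.shared_down),
            "up_a_down_b": len(self.up_a_down_b),
            "down_a_up_b": len(self.down_a_up_b),
        }


def compare_genotypes(de_a: DETable, de_b: DETable) -> GenotypePartition:
    """Partition the union of two genotypes' DE sets by direction classes."""
    calls_a = de_a.calls()
    calls_b = de_b.calls()
    a_de = {f: c for f, c in calls_a.items() if c != "not_de"}
    b_de = {f: c for f, c in calls_b.items() if c != "not_de"}
    part = GenotypePartition()
    for f, c in a_de.items():
        if f not in b_de:
            part.a_only.add(f)
        elif c == b_de[f]:
            (part.shared_up if c == "up" else part.shared_down).add(f)
        elif c == "up":
            part.up_a_down_b.add(f)
        else:
            part.down_a_up_b.add(f)
    part.b_only = {f for f in b_de if f not in a_de}
    return part
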