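"""GO/KEGG over-representation testing with optional gene-length bias
correction.

The default test is the upper-tail hypergeometric: for a term annotated to
K of N population genes, with n study genes of which k hit the term,
p = P(X >= k), X ~ Hypergeom(N, K, n).  The length-aware variant estimates
a per-gene selection weight as a monotone function of gene length (binned
detection rates smoothed by pooled-adjacent-violators) and replaces the
central hypergeometric with Wallenius' noncentral hypergeometric at the
term's weight odds — the standard correction for the fact that long genes
are more likely to be detected as differentially expressed.  Each record
also carries the rich factor k/K (the enrichment ratio of study genes to
all annotated genes in the term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .expression import bh_adjust


def wallenius_pmf(N: int, K: int, n: int, w: float) -> np.ndarray:
    """Exact pmf of Wallenius' noncentral hypergeometric by the draw
    recurrence.

    Items are drawn one at a time without replacement; a remaining success
    (K items total) is taken with probability w*K_rem / (w*K_rem + F_rem).
    Returns pmf over k = 0..min(n, K).  w = 1 is the central hypergeometric.
    The dynamic programme is O(n * K), exact up to float rounding, and
    covers every urn size used here.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not np.isfinite(w) or w <= 0:
        raise ValueError("weight odds must be positive and finite")
    kmax = min(n, K)
    f = np.zeros(kmax + 1)
    f[0] = 1.0
    for t in range(n):
        kk = np.arange(min(t, kmax) + 1)
        succ_rem = np.maximum(K - kk, 0).astype(float)
        fail_rem = np.maximum(N - K - (t - kk), 0).astype(float)
        denom = w * succ_rem + fail_rem
        p_succ = np.divide(
            w * succ_rem, denom, out=np.zeros_like(denom), where=denom > 0
        )
        g = np.zeros(kmax + 1)
        g[kk] = f[kk] * (1.0 - p_succ)
        hi = kk[p_succ > 0]
        np.add.at(g, hi + 1, f[hi] * p_succ[hi])
        f = g
    return f


def wallenius_sf(k: int, N: int, K: int, n: int, w: float) -> float:
    """Upper tail P(X >= k) of Wallenius(N, K, n, w)."""
    pmf = wallenius_pmf(N, K, n, w)
    k = max(int(k), 0)
    if k > min(n, K):
        return 0.0
    return float(min(pmf[k:].sum(), 1.0))


def _term_counts(study: set, population: set, term_map: pd.DataFrame):
    tm = term_map[term_map["feature_id"].isin(population)]
    for term, grp in tm.groupby("term_id", sort=True):
        members = set(grp["feature_id"])
        yield term, members, len(members & study), len(members)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term_id, k, K, n, N, rich_factor, p, p_corrected, method


def hypergeom_enrich(
    study,
    population,
    term_map: pd.DataFrame,
) -> EnrichmentResult:
    """Central hypergeometric over-representation test, BH-corrected across
    the terms of one namespace; records sorted by p."""
    study, population = set(study), set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    N, n = len(population), len(study)
    rows = []
    for term, _members, k, K in _term_counts(study, population, term_map):
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term, "k": k, "K": K, "n": n, "N": N,
                "rich_factor": k / K if K else np.nan,
                "p": min(p, 1.0), "method": "hypergeometric",
            }
        )
    return _finalise(rows)


def wallenius_enrich(
    study,
    population,
    term_map: pd.DataFrame,
    weights: pd.Series,
) -> EnrichmentResult:
    """Length-bias-aware over-representation test.

    Per term the weight odds w is the mean gene weight inside the term over
    the mean weight outside; the tail probability is Wallenius noncentral
    hypergeometric (N, K, n, w).  With flat weights this reduces to the
    central hypergeometric.
    """
    study, population = set(study), set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    wts = weights.reindex(sorted(population))
    if wts.isna().any():
        raise ValueError("every population gene needs a weight")
    N, n = len(population), len(study)
    rows = []
    for term, members, k, K in _term_counts(study, population, term_map):
        inside = wts.loc[wts.index.isin(members)]
        outside = wts.loc[~wts.index.isin(members)]
        if len(outside) == 0 or outside.mean() == 0:
            w = 1.0
        else:
            w = float(inside.mean() / outside.mean())
        if not np.isfinite(w) or w <= 0:
            raise ValueError(f"non-finite weight odds for term {term!r}")
        rows.append(
            {
                "term_id": term, "k": k, "K": K, "n": n, "N": N,
                "rich_factor": k / K if K else np.nan,
                "p": wallenius_sf(k, N, K, n, w), "method": "wallenius",
            }
        )
    return _finalise(rows)


def _finalise(rows) -> EnrichmentResult:
    cols = ["term_id", "k", "K", "n", "N", "rich_factor", "p", "p_corrected", "method"]
    if not rows:
        return EnrichmentResult(pd.DataFrame(columns=cols))
    table = pd.DataFrame(rows)
    table["p_corrected"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p", "term_id"], ignore_index=True)
    return EnrichmentResult(table[cols])


def length_weights(
    lengths: pd.Series,
    de_flags: pd.Series,
    n_bins: int = 20,
) -> pd.Series:
    """Per-gene detection weight as a monotone step function of gene length.

    Genes are binned into ``n_bins`` length quantiles; per-bin DE rates are
    first shrunk toward the overall rate by an empirical-Bayes factor
    1 - noise/observed bin variance (so pure sampling noise yields flat
    weights while genuine length bias passes through), then smoothed by
    pooled-adjacent-violators (isotonic, nondecreasing in length) and
    normalised to mean 1 over the population.  Degenerate inputs (all DE,
    none DE, or a single bin) give flat weights of 1.
    """
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    de = de_flags.reindex(lengths.index).astype(bool)
    if de.isna().any():
        raise ValueError("every gene needs a DE flag")
    flat = pd.Series(1.0, index=lengths.index)
    if n_bins < 2 or de.all() or not de.any():
        return flat
    n_bins = min(n_bins, lengths.nunique())
    if n_bins < 2:
        return flat
    # bin by length value (not rank) so equal lengths share a bin and the
    # resulting weight is a genuine step function of length
    bins = pd.qcut(lengths, q=n_bins, labels=False, duplicates="drop")
    rate = de.groupby(bins).mean()
    size = de.groupby(bins).size()
    centers = lengths.groupby(bins).mean()

    overall = float(de.mean())
    noise_var = float((rate * (1 - rate) / size).mean())
    obs_var = float(np.average((rate - overall) ** 2, weights=size))
    shrink = max(0.0, 1.0 - noise_var / obs_var) if obs_var > 0 else 0.0
    shrunk = overall + shrink * (rate - overall)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(centers.to_numpy(), shrunk.to_numpy(), sample_weight=size.to_numpy())
    per_bin = pd.Series(fitted, index=rate.index)
    w = bins.map(per_bin).astype(float)
    if w.mean() == 0:
        return flat
    return w / w.mean()
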