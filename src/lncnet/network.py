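"""Bipartite lncRNA-mRNA co-expression network construction and summaries.

For one genotype, every differentially expressed lncRNA is paired with
every differentially expressed mRNA and scored by the Pearson correlation
of their per-replicate FPKM profiles across that genotype's six samples
(3 DS + 3 RW).  Pairs with |PCC| >= 0.95 and p < 0.05 become edges; each
edge carries a trend label (same: both endpoints up or both down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import BytesIO

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .expression import DETable


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(stats.pearsonr(x, y).statistic)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r on n paired observations.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; |r| = 1 -> 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def classify_trend(lnc_call: str, mrna_call: str) -> str:
    """'same' when both endpoints move in the same direction, else 'opposite'."""
    if lnc_call not in ("up", "down") or mrna_call not in ("up", "down"):
        raise ValueError("trend defined only for up/down endpoints")
    return "same" if lnc_call == mrna_call else "opposite"


@dataclass
class Network:
    """Bipartite lncRNA-mRNA co-expression network for one genotype."""

    genotype: str
    edges: pd.DataFrame  # lncrna_id, mrna_id, r, p, trend

    def __post_init__(self):
        cols = ["lncrna_id", "mrna_id", "r", "p", "trend"]
        if list(self.edges.columns) != cols:
            self.edges = self.edges.reindex(columns=cols)

    @property
    def lncrna_nodes(self) -> set:
        return set(self.edges["lncrna_id"])

    @property
    def mrna_nodes(self) -> set:
        return set(self.edges["mrna_id"])

    @property
    def n_nodes(self) -> int:
        return len(self.lncrna_nodes) + len(self.mrna_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.lncrna_nodes:
            g.add_node(n, node_type="lncRNA", bipartite=0)
        for n in self.mrna_nodes:
            g.add_node(n, node_type="mRNA", bipartite=1)
        for e in self.edges.itertuples(index=False):
            g.add_edge(e.lncrna_id, e.mrna_id, r=float(e.r), p=float(e.p), trend=e.trend)
        return g


def build_network(
    de_lnc: DETable,
    de_mrna: DETable,
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    genotype: str,
    r_min: float = 0.95,
    p_max: float = 0.05,
) -> Network:
    """Score all DE-lncRNA x DE-mRNA pairs on one genotype's replicate FPKM
    profiles and keep edges with |r| >= r_min and p < p_max.

    Constant (zero-variance) profiles cannot be correlated and are dropped
    with a warning.  Isolated nodes are excluded by construction.
    """
    samples = list(design.loc[design["genotype"] == genotype, "sample_id"])
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 samples within the genotype")
    lnc_ids = [f for f in de_lnc.de_features() if f in fpkm.index]
    mrna_ids = [f for f in de_mrna.de_features() if f in fpkm.index]

    empty = pd.DataFrame(columns=["lncrna_id", "mrna_id", "r", "p", "trend"])
    if not lnc_ids or not mrna_ids:
        return Network(genotype=genotype, edges=empty)

    def usable(mat: pd.DataFrame) -> pd.DataFrame:
        const = mat.std(axis=1, ddof=0) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant expression profile(s) excluded "
                f"from correlation in genotype {genotype!r}"
            )
        return mat[~const]

    lm = usable(fpkm.loc[lnc_ids, samples])
    mm = usable(fpkm.loc[mrna_ids, samples])
    if lm.empty or mm.empty:
        return Network(genotype=genotype, edges=empty)

    def zscore(mat: pd.DataFrame) -> np.ndarray:
        a = mat.to_numpy(float)
        a = a - a.mean(axis=1, keepdims=True)
        return a / np.linalg.norm(a, axis=1, keepdims=True)

    r = zscore(lm) @ zscore(mm).T
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[np.abs(r) == 1.0] = 0.0

    keep = (np.abs(r) >= r_min) & (p < p_max)
    li, mi = np.nonzero(keep)
    lnc_calls = de_lnc.calls()
    mrna_calls = de_mrna.calls()
    edges = pd.DataFrame(
        {
            "lncrna_id": lm.index[li],
            "mrna_id": mm.index[mi],
            "r": r[li, mi],
            "p": p[li, mi],
        }
    )
    edges["trend"] = [
        classify_trend(lnc_calls[a], mrna_calls[b])
        for a, b in zip(edges["lncrna_id"], edges["mrna_id"])
    ]
    edges = edges.sort_values(["lncrna_id", "mrna_id"], ignore_index=True)
    return Network(genotype=genotype, edges=edges)


@dataclass
class DegreeSummary:
    n_nodes: int
    n_edges: int
    n_lncrna: int
    n_mrna: int
    lncrna_degree_min: int
    lncrna_degree_max: int
    mrna_degree_min: int
    mrna_degree_max: int
    hub: str | None
    hub_degree: int
    n_same_trend: int
    n_opposite_trend: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def degree_summary(net: Network) -> DegreeSummary:
    """Node/edge counts, per-side degree ranges, trend counts, and the hub
    (max-degree node over both sides; ties broken lexicographically)."""
    if net.n_edges == 0:
        return DegreeSummary(0, 0, 0, 0, 0, 0, 0, 0, None, 0, 0, 0)
    ldeg = net.edges["lncrna_id"].value_counts()
    mdeg = net.edges["mrna_id"].value_counts()
    alldeg = pd.concat([ldeg, mdeg])
    top = alldeg.max()
    hub = sorted(alldeg.index[alldeg == top])[0]
    return DegreeSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_lncrna=len(ldeg),
        n_mrna=len(mdeg),
        lncrna_degree_min=int(ldeg.min()),
        lncrna_degree_max=int(ldeg.max()),
        mrna_degree_min=int(mdeg.min()),
        mrna_degree_max=int(mdeg.max()),
        hub=hub,
        hub_degree=int(top),
        n_same_trend=int((net.edges["trend"] == "same").sum()),
        n_opposite_trend=int((net.edges["trend"] == "opposite").sum()),
    )


def subnetwork_by_term(net: Network, term_map: pd.DataFrame, term_id: str) -> Network:
    """Edges whose mRNA endpoint is annotated to ``term_id``.

    lncRNA nodes are retained only while incident to a kept edge.
    """
    if term_id not in set(term_map["term_id"]):
        raise KeyError(f"unknown term {term_id!r}")
    members = set(term_map.loc[term_map["term_id"] == term_id, "feature_id"])
    edges = net.edges[net.edges["mrna_id"].isin(members)].reset_index(drop=True)
    return Network(genotype=net.genotype, edges=edges)


def export_network(net: Network, fmt: str = "SIF") -> str:
    """Serialise the network as SIF ('lncrna coexp mrna' lines) or GraphML."""
    fmt = fmt.upper()
    if fmt == "SIF":
        return "".join(
            f"{e.lncrna_id}\tcoexp\t{e.mrna_id}\n" for e in net.edges.itertuples(index=False)
        )
    if fmt == "GRAPHML":
        buf = BytesIO()
        nx.write_graphml(net.to_graph(), buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(text: str) -> nx.Graph:
    """Read a GraphML export back into a graph (round-trip check helper)."""
    return nx.read_graphml(BytesIO(text.encode()))
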