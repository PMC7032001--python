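"""Tests for Pearson scoring, network construction, summaries, and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from xml.etree import ElementTree

from lncnet.expression import DETable
from lncnet.network import (
    Network,
    build_network,
    classify_trend,
    correlation_pvalue,
    degree_summary,
    export_network,
    import_graphml,
    pearson,
    subnetwork_by_term,
)
from lncnet.simulate import (
    SimulationConfig,
    generate_study,
    planted_pairs,
    truth_de_records,
)
from lncnet.expression import compute_fpkm


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float((cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum()))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 7.0)
        assert pearson(x, 2 * x) == pytest.approx(1.0)
        assert pearson(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        r = pearson([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 7])
        assert r == pytest.approx(0.98974, abs=5e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)


class TestCorrelationPvalue:
    def test_null_r(self):
        assert correlation_pvalue(0.0, 6) == pytest.approx(1.0)

    def test_hand_value(self):
        # t = 0.95 * sqrt(4 / (1 - 0.9025)) ~ 6.085 on 4 df
        assert correlation_pvalue(0.95, 6) == pytest.approx(0.00367, abs=5e-5)

    def test_two_sided_symmetry(self):
        for r in (0.3, 0.7, 0.99):
            assert correlation_pvalue(r, 8) == pytest.approx(correlation_pvalue(-r, 8))

    def test_perfect_correlation(self):
        assert correlation_pvalue(1.0, 5) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "a, b, expect",
        [("up", "up", "same"), ("down", "down", "same"),
         ("up", "down", "opposite"), ("down", "up", "opposite")],
    )
    def test_rules(self, a, b, expect):
        assert classify_trend(a, b) == expect

    def test_not_de_rejected(self):
        with pytest.raises(ValueError):
            classify_trend("up", "not_de")


def _net(edges):
    return Network(
        genotype="tolerant",
        edges=pd.DataFrame(
            [{"lncrna_id": l, "mrna_id": m, "r": 0.99, "p": 1e-4, "trend": "same"}
             for l, m in edges]
        ),
    )


class TestDegreeSummary:
    def test_enumerated(self):
        s = degree_summary(_net([("l1", "m1"), ("l1", "m2"), ("l2", "m1")]))
        assert (s.n_nodes, s.n_edges) == (4, 3)
        assert (s.lncrna_degree_min, s.lncrna_degree_max) == (1, 2)
        assert (s.mrna_degree_min, s.mrna_degree_max) == (1, 2)
        assert s.hub == "l1" and s.hub_degree == 2  # lexicographic tie-break vs m1

    def test_empty(self):
        s = degree_summary(_net([]))
        assert s.n_nodes == 0 and s.hub is None

    def test_handshake_identity(self, default_study):
        b = default_study
        fpkm = compute_fpkm(b.counts, b.feature_lengths,
                            b.design.set_index("sample_id")["library_size"])
        lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
        mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
        net = build_network(
            truth_de_records(b.truth, "tolerant", lnc),
            truth_de_records(b.truth, "tolerant", mrna),
            fpkm, b.design, "tolerant",
        )
        ldeg = net.edges["lncrna_id"].value_counts()
        mdeg = net.edges["mrna_id"].value_counts()
        assert ldeg.sum() == mdeg.sum() == net.n_edges


class TestBuildNetwork:
    def test_empty_without_de_lncrnas(self, small_study, small_fpkm):
        empty = DETable("tolerant", pd.DataFrame(
            {"call": [], "log2_ratio": []}, index=pd.Index([], name="feature_id")))
        mrna = small_study.counts.index[small_study.counts.index.str.startswith("MRNA_")]
        de_m = truth_de_records(small_study.truth, "tolerant", mrna)
        net = build_network(empty, de_m, small_fpkm, small_study.design, "tolerant")
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_bipartite_and_thresholds(self, small_study, small_fpkm):
        b = small_study
        lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
        mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
        net = build_network(
            truth_de_records(b.truth, "sensitive", lnc),
            truth_de_records(b.truth, "sensitive", mrna),
            small_fpkm, b.design, "sensitive",
        )
        assert net.edges["lncrna_id"].str.startswith("LNC_").all()
        assert net.edges["mrna_id"].str.startswith("MRNA_").all()
        assert (net.edges["r"].abs() >= 0.95).all() and (net.edges["p"] < 0.05).all()

    def test_threshold_monotonicity(self, small_study, small_fpkm):
        b = small_study
        lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
        mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
        de_l = truth_de_records(b.truth, "tolerant", lnc)
        de_m = truth_de_records(b.truth, "tolerant", mrna)
        sizes = [
            build_network(de_l, de_m, small_fpkm, b.design, "tolerant", r_min=r).n_edges
            for r in (0.90, 0.95, 0.99)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_sample_reordering_invariance(self, small_study, small_fpkm):
        b = small_study
        lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
        mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
        de_l = truth_de_records(b.truth, "tolerant", lnc)
        de_m = truth_de_records(b.truth, "tolerant", mrna)
        net1 = build_network(de_l, de_m, small_fpkm, b.design, "tolerant")
        design2 = b.design.sample(frac=1, random_state=7).reset_index(drop=True)
        net2 = build_network(de_l, de_m, small_fpkm, design2, "tolerant")
        pd.testing.assert_frame_equal(net1.edges, net2.edges)

    def test_module_recovery_single_module(self, small_study, small_fpkm):
        """Planted module pairs dominate the recovered edge set."""
        b = small_study
        lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
        mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
        pairs = planted_pairs(b.truth)
        for geno in ("tolerant", "sensitive"):
            net = build_network(
                truth_de_records(b.truth, geno, lnc),
                truth_de_records(b.truth, geno, mrna),
                small_fpkm, b.design, geno,
            )
            got = set(zip(net.edges["lncrna_id"], net.edges["mrna_id"]))
            assert len(pairs & got) / len(pairs) >= 0.90
            mod_edges = net.edges[
                [(l, m) in pairs for l, m in zip(net.edges["lncrna_id"], net.edges["mrna_id"])]
            ]
            assert (mod_edges["trend"] == "opposite").mean() < 0.05

    def test_recall_monotone_in_latent_strength(self):
        """Edge recall of planted pairs grows with the shared-factor SD."""
        recalls = []
        for sd in (0.25, 0.5, 1.0, 1.5, 2.5):
            cfg = SimulationConfig(
                n_mrna=150, n_lncrna=40, n_modules=1, module_size=(4, 10),
                module_latent_sd=sd, seed=5,
            )
            b = generate_study(cfg)
            fpkm = compute_fpkm(b.counts, b.feature_lengths,
                                b.design.set_index("sample_id")["library_size"])
            lnc = b.counts.index[b.counts.index.str.startswith("LNC_")]
            mrna = b.counts.index[b.counts.index.str.startswith("MRNA_")]
            net = build_network(
                truth_de_records(b.truth, "tolerant", lnc),
                truth_de_records(b.truth, "tolerant", mrna),
                fpkm, b.design, "tolerant",
            )
            pairs = planted_pairs(b.truth)
            got = set(zip(net.edges["lncrna_id"], net.edges["mrna_id"]))
            recalls.append(len(pairs & got) / len(pairs))
        assert recalls[-1] >= 0.9
        assert recalls == sorted(recalls) or recalls[-1] - recalls[0] > 0.3


class TestSubnetwork:
    def _toy(self):
        return _net([("l1", "m1"), ("l1", "m2"), ("l2", "m2"), ("l3", "m3")])

    def _term_map(self):
        return pd.DataFrame(
            {"feature_id": ["m1", "m2", "m3", "m4"],
             "term_id": ["T1", "T1", "T2", "T2"]}
        )

    def test_enumerated(self):
        sub = subnetwork_by_term(self._toy(), self._term_map(), "T1")
        assert set(zip(sub.edges["lncrna_id"], sub.edges["mrna_id"])) == {
            ("l1", "m1"), ("l1", "m2"), ("l2", "m2")}
        assert sub.lncrna_nodes == {"l1", "l2"}

    def test_full_and_empty_terms(self):
        net = self._toy()
        tm = pd.DataFrame({"feature_id": ["m1", "m2", "m3"], "term_id": ["ALL"] * 3})
        assert subnetwork_by_term(net, tm, "ALL").n_edges == net.n_edges
        tm2 = pd.DataFrame({"feature_id": ["m9"], "term_id": ["NONE"]})
        assert subnetwork_by_term(net, tm2, "NONE").n_edges == 0

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            subnetwork_by_term(self._toy(), self._term_map(), "T9")


class TestExport:
    def test_sif_single_edge(self):
        assert export_network(_net([("l1", "m1")]), "SIF") == "l1\tcoexp\tm1\n"

    def test_graphml_round_trip(self):
        net = _net([("l1", "m1"), ("l2", "m1")])
        text = export_network(net, "GraphML")
        ElementTree.fromstring(text)  # well-formed XML
        g = import_graphml(text)
        assert set(g.nodes) == {"l1", "l2", "m1"}
        assert set(map(frozenset, g.edges)) == {frozenset({"l1", "m1"}), frozenset({"l2", "m1"})}
        assert g.nodes["l1"]["node_type"] == "lncRNA"
        assert g.edges["l1", "m1"]["r"] == pytest.approx(0.99)

    def test_unknown_format(self):
        with pytest.raises(ValueError):
            export_network(_net([]), "DOT")
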