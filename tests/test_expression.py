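"""Unit and property tests for FPKM, the NB test, BH, and DE calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncnet.expression import (
    DETable,
    bh_adjust,
    call_de,
    compare_genotypes,
    compute_fpkm,
    condition_means,
    log2_ratio,
    nb_test,
)


def _counts_frame(arr, samples=None):
    arr = np.asarray(arr)
    features = [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=features, columns=samples)


class TestFPKM:
    def test_hand_example(self):
        """200 fragments on a 2 kb feature in a 2M-fragment library -> 50."""
        counts = _counts_frame([[200]])
        fpkm = compute_fpkm(
            counts, pd.Series([2000], index=["g0"]), pd.Series([2_000_000], index=["s0"])
        )
        assert fpkm.iloc[0, 0] == pytest.approx(50.0, rel=1e-12)

    def test_zero_count_gives_zero(self):
        counts = _counts_frame([[0, 5], [3, 0]])
        fpkm = compute_fpkm(
            counts,
            pd.Series([500, 1500], index=counts.index),
            pd.Series([1e6, 2e6], index=counts.columns),
        )
        assert (fpkm.to_numpy() == 0) ==  pytest.approx((counts.to_numpy() == 0))

    def test_library_size_scaling(self):
        counts = _counts_frame([[10, 10], [7, 7]])
        lens = pd.Series([1000, 4000], index=counts.index)
        one = compute_fpkm(counts, lens, pd.Series([1e6, 1e6], index=counts.columns))
        two = compute_fpkm(counts, lens, pd.Series([2e6, 1e6], index=counts.columns))
        assert np.allclose(two.iloc[:, 0], one.iloc[:, 0] / 2)
        assert np.allclose(two.iloc[:, 1], one.iloc[:, 1])

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(0)
        counts = _counts_frame(rng.integers(0, 500, size=(30, 8)))
        lens = pd.Series(rng.integers(200, 5000, size=30), index=counts.index)
        libs = pd.Series(rng.integers(10**6, 10**7, size=8), index=counts.columns)
        fpkm = compute_fpkm(counts, lens, libs)
        for i in range(30):
            for j in range(8):
                expect = counts.iloc[i, j] * 1e9 / (lens.iloc[i] * libs.iloc[j])
                assert fpkm.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_rejects_bad_lengths(self):
        counts = _counts_frame([[1]])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series([0], index=["g0"]), pd.Series([1e6], index=["s0"]))


class TestConditionMeans:
    def test_replicate_mean_and_permutation(self, toy_design):
        counts = _counts_frame(
            np.tile([[4, 6, 8, 1, 2, 3, 5, 5, 5, 7, 7, 7]], (1, 1)),
            samples=list(toy_design["sample_id"]),
        )
        lens = pd.Series([1000], index=counts.index)
        libs = toy_design.set_index("sample_id")["library_size"]
        fpkm = compute_fpkm(counts, lens, libs)
        means = condition_means(fpkm, toy_design)
        # FPKM scale: count * 1e9 / (1000 * 1e6) = count
        assert means[("tolerant", "DS")].iloc[0] == pytest.approx(6.0)
        assert means[("tolerant", "RW")].iloc[0] == pytest.approx(2.0)
        shuffled = toy_design.sample(frac=1, random_state=1)
        means2 = condition_means(fpkm, shuffled)
        pd.testing.assert_frame_equal(means, means2)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "rw, ds, eps, expect",
        [
            (8, 2, 0.0, 2.0),
            (0, 0, 0.1, 0.0),
            (8, 2, 0.1, np.log2(8.1 / 2.1)),
            (4, 4, 0.0, 0.0),
        ],
    )
    def test_values(self, rw, ds, eps, expect):
        assert log2_ratio(rw, ds, epsilon=eps) == pytest.approx(expect, abs=1e-12)

    def test_hand_value_with_pseudocount(self):
        assert log2_ratio(8, 2, epsilon=0.1) == pytest.approx(1.9475, abs=5e-5)

    def test_zero_denominator_without_epsilon_is_infinite(self):
        assert np.isposinf(log2_ratio(5, 0, epsilon=0.0))
        assert np.isneginf(log2_ratio(0, 5, epsilon=0.0))

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(1, 1, epsilon=-0.5)


class TestNBTest:
    def test_identical_groups_p_one(self):
        g = np.array([[10, 12, 11]], float)
        sizes = np.full(3, 1e6)
        assert nb_test(g, g, sizes, sizes)[0] == pytest.approx(1.0)

    def test_tenfold_shift_significant(self):
        p = nb_test(
            np.array([[10, 12, 11]]), np.array([[100, 110, 105]]),
            np.full(3, 1e6), np.full(3, 1e6),
        )[0]
        assert p < 0.01

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.integers(5, 200, size=(40, 3))
        b = rng.integers(5, 200, size=(40, 3))
        sizes = rng.uniform(5e5, 2e6, 3)
        p1 = nb_test(a, b, sizes, sizes)
        p2 = nb_test(b, a, sizes, sizes)
        assert np.allclose(p1, p2, rtol=1e-12)

    def test_all_zero_feature_degenerate(self):
        z = np.zeros((1, 3))
        p = nb_test(z, z, np.full(3, 1e6), np.full(3, 1e6))
        assert p[0] == 1.0

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            nb_test(np.array([[3]]), np.array([[4]]), np.array([1e6]), np.array([1e6]))

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 1000, size=(200, 3))
        b = rng.integers(0, 1000, size=(200, 3))
        sizes = rng.uniform(5e5, 2e6, 6)
        p = nb_test(a, b, sizes[:3], sizes[3:])
        assert ((p >= 0) & (p <= 1)).all()


def bh_oracle(pvals):
    """q_i = min over supersets definition: min_{j: p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        q[idx] = min(p[order[j]] * m / (j + 1) for j in range(pos, m))
    return np.minimum(q, 1.0)


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    @pytest.mark.parametrize("p", [[1.0, 1.0, 1.0], [0.2], []])
    def test_degenerate_inputs(self, p):
        q = bh_adjust(p)
        assert np.allclose(q, p)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=6)
    )
    def test_matches_exhaustive_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCallDE:
    def test_threshold_logic(self, small_study, small_fpkm):
        de = call_de(small_study.counts, small_fpkm, small_study.design, "tolerant")
        t = de.table
        up = t[t["call"] == "up"]
        down = t[t["call"] == "down"]
        assert (up["q"] <= 0.05).all() and (up["log2_ratio"] >= 1).all()
        assert (down["q"] <= 0.05).all() and (down["log2_ratio"] <= -1).all()
        not_de = t[t["call"] == "not_de"]
        fails = (not_de["q"] > 0.05) | (not_de["log2_ratio"].abs() < 1) | not_de["degenerate"]
        assert fails.all()

    def test_partition_identity(self, small_study, small_fpkm):
        de = call_de(small_study.counts, small_fpkm, small_study.design, "sensitive")
        counts = de.table["call"].value_counts()
        assert counts.sum() == len(small_study.counts)

    def test_unknown_genotype(self, small_study, small_fpkm):
        with pytest.raises(ValueError):
            call_de(small_study.counts, small_fpkm, small_study.design, "missing")


def _de_table(genotype, calls):
    tab = pd.DataFrame(
        {"call": pd.Series(calls), "log2_ratio": [2.0 if c == "up" else -2.0 for c in calls.values()]},
        index=pd.Index(calls.keys(), name="feature_id"),
    )
    return DETable(genotype=genotype, table=tab)


class TestCompareGenotypes:
    def test_enumerated_example(self):
        a = _de_table("A", {"f1": "up", "f2": "down"})
        b = _de_table("B", {"f1": "up", "f2": "up", "f3": "down"})
        part = compare_genotypes(a, b)
        assert part.shared_up == {"f1"}
        assert part.down_a_up_b == {"f2"}
        assert part.b_only == {"f3"}
        assert not part.a_only and not part.shared_down and not part.up_a_down_b

    def test_disjoint_and_identical(self):
        a = _de_table("A", {"f1": "up"})
        b = _de_table("B", {"f2": "down"})
        part = compare_genotypes(a, b)
        assert not part.shared and part.a_only == {"f1"} and part.b_only == {"f2"}
        same = compare_genotypes(a, a)
        assert same.shared == {"f1"} and not same.up_a_down_b and not same.down_a_up_b

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_partition_sums(self, data):
        """Class sizes always recompose |A| and |B| exactly."""
        feats = [f"f{i}" for i in range(12)]
        call = st.sampled_from(["up", "down", "not_de"])
        ca = {f: data.draw(call) for f in feats}
        cb = {f: data.draw(call) for f in feats}
        a = _de_table("A", {f: c for f, c in ca.items() if c != "not_de"} or {"fx": "up"})
        b = _de_table("B", {f: c for f, c in cb.items() if c != "not_de"} or {"fy": "up"})
        part = compare_genotypes(a, b)
        s = part.sizes()
        n_shared = s["shared_up"] + s["shared_down"] + s["up_a_down_b"] + s["down_a_up_b"]
        assert s["a_only"] + n_shared == len(a.de_features())
        assert s["b_only"] + n_shared == len(b.de_features())
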