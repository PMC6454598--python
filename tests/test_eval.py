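import math

import numpy as np
import pytest

from tsce.eval_intrinsic import (
    Grouping,
    cosine,
    evaluate,
    icd_prefix_group,
    icd_prefix_grouping,
    in_cluster_distance,
    knn_query,
    mcsm,
    out_cluster_distance,
)
from tsce.sgns import EmbeddingMatrix


def emb_of(vectors: dict[str, list[float]]) -> EmbeddingMatrix:
    tokens = sorted(vectors)
    return EmbeddingMatrix(tokens, np.array([vectors[t] for t in tokens], float))


class TestIcdPrefix:
    @pytest.mark.parametrize(
        "code,prefix",
        [("493.22", "493"), ("493.91", "493"), ("V10", "V10"), ("1.2.3", "1")],
    )
    def test_prefix(self, code, prefix):
        assert icd_prefix_group(code) == prefix

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            icd_prefix_group("")

    def test_grouping_over_tokens(self):
        g = icd_prefix_grouping(["D_493.22", "D_493.91", "D_12.0", "M_aspirin"])
        assert g.mapping == {
            "D_493.22": "493", "D_493.91": "493", "D_12.0": "12"
        }

    def test_grouping_with_procedures(self):
        g = icd_prefix_grouping(["D_1.2", "P_3.4"], code_types=("D", "P"))
        assert set(g.mapping) == {"D_1.2", "P_3.4"}


class TestCosine:
    def test_identical(self):
        v = np.array([1.0, 2.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_value(self):
        assert cosine(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == (
            pytest.approx(1 / math.sqrt(2))
        )

    def test_zero_vector_warns(self):
        with pytest.warns(UserWarning):
            assert cosine(np.zeros(2), np.array([1.0, 0.0])) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(2), np.zeros(3))


class TestInClusterDistance:
    def test_identical_within_groups_is_zero(self):
        emb = emb_of({"a": [1, 0], "b": [1, 0], "c": [0, 1], "d": [0, 1]})
        g = Grouping({"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert in_cluster_distance(emb, g) == pytest.approx(0.0)

    def test_single_pair_group(self):
        emb = emb_of({"a": [1, 0], "b": [1, 1]})
        g = Grouping({"a": "g", "b": "g"})
        assert in_cluster_distance(emb, g) == pytest.approx(
            1 - 1 / math.sqrt(2)
        )

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(50)
        tokens = [f"t{i}" for i in range(12)]
        emb = emb_of({t: list(rng.normal(size=5)) for t in tokens})
        g = Grouping({t: f"g{i % 3}" for i, t in enumerate(tokens)})
        got = in_cluster_distance(emb, g)
        # oracle: explicit double loop per group, mean of group means
        group_means = []
        for label in sorted(set(g.mapping.values())):
            members = sorted(t for t in tokens if g.mapping[t] == label)
            dists = [
                1 - cosine(emb.vector(u), emb.vector(w))
                for i, u in enumerate(members)
                for w in members[i + 1:]
            ]
            group_means.append(np.mean(dists))
        assert got == pytest.approx(np.mean(group_means))

    def test_singleton_groups_excluded(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1], "c": [1, 1]})
        g = Grouping({"a": "g1", "b": "g1", "c": "lonely"})
        expect = 1 - cosine(np.array([1.0, 0]), np.array([0, 1.0]))
        assert in_cluster_distance(emb, g) == pytest.approx(expect)

    def test_no_eligible_group_is_error(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1]})
        g = Grouping({"a": "g1", "b": "g2"})
        with pytest.raises(ValueError):
            in_cluster_distance(emb, g)


class TestOutClusterDistance:
    def test_two_singletons(self):
        emb = emb_of({"a": [1, 0], "b": [1, 1]})
        g = Grouping({"a": "g1", "b": "g2"})
        assert out_cluster_distance(emb, g) == pytest.approx(
            1 - 1 / math.sqrt(2)
        )

    def test_identical_vectors_zero(self):
        emb = emb_of({"a": [2, 1], "b": [2, 1], "c": [2, 1]})
        g = Grouping({"a": "g1", "b": "g2", "c": "g3"})
        assert out_cluster_distance(emb, g) == pytest.approx(0.0)

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(51)
        tokens = [f"t{i}" for i in range(10)]
        emb = emb_of({t: list(rng.normal(size=4)) for t in tokens})
        g = Grouping({t: f"g{i % 3}" for i, t in enumerate(tokens)})
        got = out_cluster_distance(emb, g)
        labels = sorted(set(g.mapping.values()))
        pair_means = []
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                ua = [t for t in tokens if g.mapping[t] == labels[a]]
                wb = [t for t in tokens if g.mapping[t] == labels[b]]
                dists = [
                    1 - cosine(emb.vector(u), emb.vector(w))
                    for u in ua
                    for w in wb
                ]
                pair_means.append(np.mean(dists))
        assert got == pytest.approx(np.mean(pair_means))

    def test_single_group_is_error(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1]})
        g = Grouping({"a": "g", "b": "g"})
        with pytest.raises(ValueError):
            out_cluster_distance(emb, g)

    def test_range_bounds(self):
        rng = np.random.default_rng(52)
        tokens = [f"t{i}" for i in range(20)]
        emb = emb_of({t: list(rng.normal(size=6)) for t in tokens})
        g = Grouping({t: f"g{i % 4}" for i, t in enumerate(tokens)})
        assert 0.0 <= in_cluster_distance(emb, g) <= 2.0
        assert 0.0 <= out_cluster_distance(emb, g) <= 2.0


class TestMCSM:
    def test_all_one_group_max_score(self):
        rng = np.random.default_rng(53)
        tokens = [f"t{i}" for i in range(8)]
        emb = emb_of({t: list(rng.normal(size=3)) for t in tokens})
        g = Grouping({t: "g" for t in tokens})
        k = 3
        expect = sum(1 / math.log2(i + 1) for i in range(1, k + 1))
        assert mcsm(emb, g, k=k) == pytest.approx(expect)

    def test_k1_all_one_group(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1], "c": [1, 1]})
        g = Grouping({t: "g" for t in "abc"})
        assert mcsm(emb, g, k=1) == pytest.approx(1.0)

    def test_no_shared_group_zero(self):
        rng = np.random.default_rng(54)
        tokens = [f"t{i}" for i in range(6)]
        emb = emb_of({t: list(rng.normal(size=3)) for t in tokens})
        g = Grouping({t: f"g{i}" for i, t in enumerate(tokens)})
        assert mcsm(emb, g, k=3) == 0.0

    def test_matches_brute_force_ranking_oracle(self):
        vectors = {
            "a1": [1.0, 0.1], "a2": [1.0, 0.0], "a3": [0.9, 0.2],
            "b1": [0.0, 1.0], "b2": [0.1, 1.0], "b3": [-0.1, 0.9],
        }
        emb = emb_of(vectors)
        g = Grouping({t: t[0] for t in vectors})
        k = 3
        got = mcsm(emb, g, k=k)
        # oracle: full similarity matrix + explicit sort per concept
        tokens = sorted(vectors)
        total = 0.0
        for v in tokens:
            sims = sorted(
                (
                    (-cosine(emb.vector(v), emb.vector(u)), u)
                    for u in tokens
                    if u != v
                ),
            )
            for i, (negsim, u) in enumerate(sims[:k], start=1):
                if g.mapping[u] == g.mapping[v]:
                    total += 1 / math.log2(i + 1)
        assert got == pytest.approx(total / len(tokens))

    def test_scale_invariance(self):
        rng = np.random.default_rng(55)
        tokens = [f"t{i}" for i in range(15)]
        X = rng.normal(size=(15, 6))
        g = Grouping({t: f"g{i % 3}" for i, t in enumerate(tokens)})
        m1 = mcsm(EmbeddingMatrix(tokens, X), g, k=5)
        m2 = mcsm(EmbeddingMatrix(tokens, 37.5 * X), g, k=5)
        assert m1 == pytest.approx(m2)

    def test_small_set_warns(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1], "c": [1, 1]})
        g = Grouping({t: "g" for t in "abc"})
        with pytest.warns(UserWarning, match="truncated"):
            mcsm(emb, g, k=40)

    def test_too_few_tokens_error(self):
        emb = emb_of({"a": [1, 0]})
        with pytest.raises(ValueError):
            mcsm(emb, Grouping({"a": "g"}), k=1)

    def test_upper_bound_invariant(self):
        rng = np.random.default_rng(56)
        tokens = [f"t{i}" for i in range(30)]
        emb = emb_of({t: list(rng.normal(size=8)) for t in tokens})
        g = Grouping({t: f"g{i % 5}" for i, t in enumerate(tokens)})
        k = 10
        bound = sum(1 / math.log2(i + 1) for i in range(1, k + 1))
        assert 0.0 <= mcsm(emb, g, k=k) <= bound


class TestKnnQuery:
    def test_duplicate_vector_first(self):
        emb = emb_of({"q": [1, 2], "dup": [2, 4], "other": [-1, 0]})
        top = knn_query(emb, "q", k=1)
        assert top[0][0] == "dup"
        assert top[0][1] == pytest.approx(1.0)

    def test_k_exceeding_vocab_returns_all(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1], "c": [1, 1]})
        assert len(knn_query(emb, "a", k=99)) == 2

    def test_matches_full_sort_oracle(self):
        vectors = {"a": [1.0, 0.0], "b": [0.5, 0.5], "c": [0.0, 1.0],
                   "d": [-1.0, 0.2]}
        emb = emb_of(vectors)
        got = knn_query(emb, "a", k=3)
        expect = sorted(
            (
                (t, cosine(emb.vector("a"), emb.vector(t)))
                for t in vectors
                if t != "a"
            ),
            key=lambda ts: (-ts[1], ts[0]),
        )
        assert [t for t, _ in got] == [t for t, _ in expect]
        for (_, s1), (_, s2) in zip(got, expect):
            assert s1 == pytest.approx(s2)

    def test_unknown_token(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(KeyError):
            knn_query(emb, "zzz", k=1)


class TestNullBehavior:
    def test_random_vectors_no_cohesion_gap(self):
        rng = np.random.default_rng(57)
        n_groups, per_group, dim = 50, 10, 20
        tokens = [f"t{i}" for i in range(n_groups * per_group)]
        emb = EmbeddingMatrix(tokens, rng.normal(size=(len(tokens), dim)))
        g = Grouping({t: f"g{i % n_groups}" for i, t in enumerate(tokens)})
        gap = abs(in_cluster_distance(emb, g) - out_cluster_distance(emb, g))
        assert gap < 0.05


class TestGroupingCSV:
    def test_roundtrip(self, tmp_path):
        g = Grouping({"D_1.2": "1", "D_3.4": "3"}, name="x")
        path = tmp_path / "g.csv"
        g.to_csv(path)
        back = Grouping.from_csv(path)
        assert back.mapping == g.mapping

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("")
        with pytest.raises(ValueError):
            Grouping.from_csv(path)


class TestEvaluate:
    def test_report_fields_and_ranges(self):
        rng = np.random.default_rng(58)
        tokens = [f"D_{i}.{j}" for i in range(4) for j in range(4)]
        emb = EmbeddingMatrix(tokens, rng.normal(size=(16, 6)))
        grouping = icd_prefix_grouping(tokens)
        report = evaluate(emb, grouping, k=5, embedding_name="test")
        assert 0 <= report.d_in <= 2 and 0 <= report.d_out <= 2
        bound = sum(1 / math.log2(i + 1) for i in range(1, 6))
        assert 0 <= report.mcsm <= bound
        payload = report.to_json()
        assert '"d_in"' in payload and '"mcsm"' in payload

    def test_no_overlap_is_error(self):
        emb = emb_of({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError):
            evaluate(emb, Grouping({"x": "g", "y": "g"}))
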