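import itertools

import numpy as np
import pytest

from knemap.comparison_benchmarks import (
    CompoundClustering,
    class_retrieval_curve,
    cluster_compounds,
    cluster_overlap,
    cosine_distance,
    cross_dataset_match,
    levenshtein,
    mean_retrieval_curve,
    method_pair_ranking,
    pairwise_similarity,
    rank_agreement,
    reference_pair_ranking,
)

from oracles import average_ranks, levenshtein_dp, retrieval_recount


class TestSimilarity:
    def test_cosine_identity_orthogonal_zero(self):
        u = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(u, u) == pytest.approx(0.0)
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(1.0)
        z = np.zeros(2)
        assert cosine_distance(z, z) == 0.0
        assert cosine_distance(z, np.array([1.0, 0.0])) == 1.0

    def test_pearson_of_proportional_vectors(self):
        sim = pairwise_similarity(
            ["a", "b"], np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]), metric="pearson"
        )
        assert sim.of("a", "b") == pytest.approx(1.0)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(0)
        vecs = rng.random((6, 8))
        sim = pairwise_similarity([f"e{i}" for i in range(6)], vecs)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 0.0)
        assert ((sim.values >= 0) & (sim.values <= 2)).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.ones(3), np.ones(4))


class TestCompoundClustering:
    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.05, (5, 4)) + np.array([1, 0, 0, 0.0])
        b = rng.normal(0, 0.05, (5, 4)) + np.array([0, 0, 1, 0.0])
        ids = [f"e{i}" for i in range(10)]
        sim = pairwise_similarity(ids, np.vstack([a, b]))
        cc = cluster_compounds(sim, 2)
        left = {cc.assignment[i] for i in ids[:5]}
        right = {cc.assignment[i] for i in ids[5:]}
        assert len(left) == len(right) == 1 and left != right

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(2)
        ids = [f"e{i}" for i in range(4)]
        sim = pairwise_similarity(ids, rng.random((4, 3)))
        assert cluster_compounds(sim, 4).k == 4

    def test_planted_groups_ari(self):
        from sklearn.metrics import adjusted_rand_score

        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = rng.normal(0, 1, (3, 12))
            labels = np.repeat([0, 1, 2], 10)
            vecs = centers[labels] + rng.normal(0, 0.15, (30, 12))
            ids = [f"e{i}" for i in range(30)]
            sim = pairwise_similarity(ids, vecs)
            cc = cluster_compounds(sim, 3)
            ari = adjusted_rand_score(labels, [cc.assignment[i] for i in ids])
            if ari >= 0.8:
                ok += 1
        assert ok >= 9


class TestClusterOverlap:
    def test_identical_clusterings(self):
        a = CompoundClustering("s1", {"x": 0, "y": 0, "z": 1}, 2)
        b = CompoundClustering("s2", {"x": 0, "y": 0, "z": 1}, 2)
        ov = cluster_overlap(a, b)
        assert all(j == 1.0 for _, j in ov.best_match.values())
        assert ov.consistent_exposures == {"x", "y", "z"}

    def test_all_in_one_vs_singletons(self):
        items = [f"e{i}" for i in range(4)]
        a = CompoundClustering("s1", {e: 0 for e in items}, 1)
        b = CompoundClustering("s2", {e: i for i, e in enumerate(items)}, 4)
        ov = cluster_overlap(a, b)
        assert np.allclose(ov.jaccard, 1 / 4)

    def test_random_partitions_match_set_arithmetic(self):
        rng = np.random.default_rng(5)
        items = [f"e{i}" for i in range(20)]
        a = CompoundClustering("s1", {e: int(rng.integers(3)) for e in items}, 3)
        b = CompoundClustering("s2", {e: int(rng.integers(4)) for e in items}, 4)
        ov = cluster_overlap(a, b)
        for i, ci in enumerate(ov.clusters_a):
            ma = {e for e in items if a.assignment[e] == ci}
            for j, cj in enumerate(ov.clusters_b):
                mb = {e for e in items if b.assignment[e] == cj}
                assert ov.jaccard[i, j] == pytest.approx(len(ma & mb) / len(ma | mb))

    def test_disjoint_exposures_rejected(self):
        a = CompoundClustering("s1", {"x": 0}, 1)
        b = CompoundClustering("s2", {"y": 0}, 1)
        with pytest.raises(ValueError):
            cluster_overlap(a, b)


class TestRetrieval:
    def test_perfect_grouping_reaches_maximum(self):
        vecs = np.array([[1, 0, 0], [1, 0.01, 0], [0, 1, 0], [0, 1, 0.01]], dtype=float)
        ids = ["a1", "a2", "b1", "b2"]
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        curve = class_retrieval_curve({"m": (ids, vecs)}, labels)
        # each compound retrieves its single classmate at x=1: score 4
        assert curve.scores["m"][0] == pytest.approx(4.0)
        assert curve.scores["m"][-1] == pytest.approx(4.0)

    def test_singleton_class_contributes_zero(self):
        vecs = np.array([[1, 0, 0.2], [0.9, 0.1, 0], [0.1, 1, 0.3]])
        ids = ["a1", "a2", "solo"]
        labels = {"a1": "A", "a2": "A", "solo": "S"}
        curve = class_retrieval_curve({"m": (ids, vecs)}, labels)
        # only the two A compounds contribute; maximum total is 2
        assert curve.scores["m"].max() <= 2.0 + 1e-12

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(9)
        ids = [f"e{i}" for i in range(12)]
        vecs = rng.random((12, 6))
        labels = {e: f"C{i % 3}" for i, e in enumerate(ids)}
        curve = class_retrieval_curve({"m": (ids, vecs)}, labels)
        sim = pairwise_similarity(ids, vecs, metric="pearson")
        expected = retrieval_recount(sim.of, ids, labels, len(ids) - 1)
        assert curve.scores["m"] == pytest.approx(expected)
        assert curve.auc["m"] == pytest.approx(np.trapezoid(expected, curve.x))

    def test_curves_non_decreasing(self):
        rng = np.random.default_rng(13)
        ids = [f"e{i}" for i in range(10)]
        vecs = rng.random((10, 5))
        labels = {e: f"C{i % 2}" for i, e in enumerate(ids)}
        curve = class_retrieval_curve({"m": (ids, vecs)}, labels)
        assert (np.diff(curve.scores["m"]) >= -1e-12).all()

    def test_mean_across_systems(self):
        rng = np.random.default_rng(3)
        ids = [f"e{i}" for i in range(8)]
        labels = {e: f"C{i % 2}" for i, e in enumerate(ids)}
        c1 = class_retrieval_curve({"m": (ids, rng.random((8, 4)))}, labels)
        c2 = class_retrieval_curve({"m": (ids, rng.random((8, 4)))}, labels)
        mean = mean_retrieval_curve([c1, c2])
        assert mean.scores["m"] == pytest.approx((c1.scores["m"] + c2.scores["m"]) / 2)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d", [("abc", "abc", 0), ("abc", "axc", 1), ("kitten", "sitting", 3), ("", "ab", 2)]
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_random_strings_match_dp_oracle(self):
        rng = np.random.default_rng(21)
        alphabet = list("ACGT")
        for _ in range(30):
            a = "".join(rng.choice(alphabet, rng.integers(0, 12)))
            b = "".join(rng.choice(alphabet, rng.integers(0, 12)))
            assert levenshtein(a, b) == levenshtein_dp(a, b)


class TestPairRanking:
    def test_forced_ordering(self):
        ranking = reference_pair_ranking({"a": "xxxx", "b": "xxxy", "c": "xyyy"})
        ranks = ranking.rank_of()
        assert ranks[("a", "b")] == 1.0  # distance 1
        assert ranks[("b", "c")] == 2.0  # distance 2
        assert ranks[("a", "c")] == 3.0  # distance 3

    def test_ties_get_average_rank(self):
        ranking = reference_pair_ranking({"a": "s", "b": "s", "c": "s"})
        assert set(ranking.ranks) == {2.0}  # three identical pairs tie at (1+2+3)/3

    def test_random_strings_match_oracle_sort(self):
        rng = np.random.default_rng(33)
        alphabet = list("ABCDEF")
        structures = {
            f"e{i}": "".join(rng.choice(alphabet, 8)) for i in range(10)
        }
        ranking = reference_pair_ranking(structures)
        dists = [levenshtein_dp(structures[a], structures[b]) for a, b in ranking.pairs]
        assert ranking.distances.tolist() == dists
        assert ranking.ranks.tolist() == average_ranks(dists)

    def test_descriptor_vectors_use_cosine(self):
        ranking = reference_pair_ranking(
            {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 0.1]), "c": np.array([0.0, 1.0])}
        )
        assert ranking.rank_of()[("a", "b")] == 1.0


class TestRankAgreement:
    def _vectors(self, seed, n=8, d=6):
        rng = np.random.default_rng(seed)
        ids = [f"e{i}" for i in range(n)]
        return ids, rng.random((n, d))

    def test_identity_gives_zero_and_one(self):
        ids, vecs = self._vectors(1)
        sim = pairwise_similarity(ids, vecs)
        mp = method_pair_ranking(sim)
        agr = rank_agreement(mp, mp)
        assert np.allclose(agr.mean_rank_difference, 0.0)
        assert np.allclose(agr.jaccard, 1.0)
        assert agr.auc_rank_difference == 0.0
        assert agr.auc_jaccard == pytest.approx(agr.x_jac[-1] - agr.x_jac[0])

    def test_full_set_jaccard_is_one_even_reversed(self):
        ids, vecs = self._vectors(2)
        sim = pairwise_similarity(ids, vecs)
        mp = method_pair_ranking(sim)
        rev = reference_pair_ranking({i: "".join(map(str, np.random.default_rng(int(i[1:])).integers(0, 9, 6))) for i in ids})
        agr = rank_agreement(mp, rev)
        assert agr.jaccard[-1] == pytest.approx(1.0)  # x = n_pairs covers all pairs

    def test_curves_match_nested_loop_oracle(self):
        ids, vecs = self._vectors(7)
        rng = np.random.default_rng(8)
        structures = {e: "".join(rng.choice(list("XYZW"), 7)) for e in ids}
        sim = pairwise_similarity(ids, vecs)
        mp = method_pair_ranking(sim)
        ref = reference_pair_ranking(structures)
        agr = rank_agreement(mp, ref)

        # oracle: explicit sorts and recounts
        m_rank = mp.rank_of()
        r_rank = ref.rank_of()
        m_sorted = sorted(mp.pairs, key=lambda p: (m_rank[p], p))
        r_sorted = sorted(ref.pairs, key=lambda p: (r_rank[p], p))
        n_pairs = len(mp.pairs)
        for xi, x in enumerate(agr.x_diff):
            top = m_sorted[:x]
            expected = np.mean([abs(m_rank[p] - r_rank[p]) for p in top])
            assert agr.mean_rank_difference[xi] == pytest.approx(expected)
        for xi, x in enumerate(agr.x_jac):
            a, b = set(m_sorted[:x]), set(r_sorted[:x])
            assert agr.jaccard[xi] == pytest.approx(len(a & b) / len(a | b))
        assert len(agr.top20_rank_differences) == min(20, n_pairs)

    def test_mismatched_pair_universe_rejected(self):
        ids, vecs = self._vectors(4)
        sim = pairwise_similarity(ids, vecs)
        mp = method_pair_ranking(sim)
        ref = reference_pair_ranking({"q1": "aa", "q2": "ab", "q3": "bb"})
        with pytest.raises(ValueError):
            rank_agreement(mp, ref)


class TestCrossDatasetMatch:
    def test_exact_match_ranks_first(self):
        q = {"sysA": {"q1": np.array([1.0, 0.0, 0.0])}, "sysB": {"q1": np.array([1.0, 0.0, 0.0])}}
        c = {
            "sysX": {"A": np.array([1.0, 0.0, 0.0]), "B": np.array([0.0, 0.0, 1.0])},
            "sysY": {"A": np.array([1.0, 0.0, 0.0]), "B": np.array([0.5, 0.0, 1.0])},
        }
        match = cross_dataset_match(q, c)
        assert match.best_match["q1"] == "A"
        assert match.mean_ranks.loc["q1", "A"] == pytest.approx(1.0)

    def test_mean_rank_arithmetic(self):
        # candidate ranked 1 in one system pair and 3 in another -> mean 2
        q = {"s1": {"q": np.array([1.0, 0.0, 0.0])}, "s2": {"q": np.array([0.0, 0.0, 1.0])}}
        c = {
            "t": {
                "A": np.array([1.0, 0.0, 0.0]),
                "B": np.array([0.9, 0.3, 0.1]),
                "C": np.array([0.0, 0.1, 1.0]),
            }
        }
        match = cross_dataset_match(q, c)
        # in (s1,t): order A,B,C -> A rank 1; in (s2,t): order C,B,A -> A rank 3
        assert match.mean_ranks.loc["q", "A"] == pytest.approx(2.0)

    def test_partition_mismatch_rejected(self):
        q = {"s": {"q": np.ones(3)}}
        c = {"t": {"A": np.ones(4)}}
        with pytest.raises(ValueError):
            cross_dataset_match(q, c)

    def test_planted_partner_recovered(self):
        rng_master = np.random.default_rng(100)
        hits = 0
        trials = 10
        for _ in range(trials):
            rng = np.random.default_rng(int(rng_master.integers(2**31)))
            base = {c: rng.dirichlet(np.ones(12)) for c in ["A", "B", "C", "D"]}
            q, c = {}, {}
            for sys_q, sys_c in (("s1", "t1"), ("s2", "t2")):
                c[sys_c] = {k: v + rng.normal(0, 0.01, 12) for k, v in base.items()}
                q[sys_q] = {"q": base["B"] + rng.normal(0, 0.02, 12)}
            match = cross_dataset_match(q, c)
            if match.best_match["q"] == "B":
                hits += 1
        assert hits >= 8
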