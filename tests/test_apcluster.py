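import numpy as np
import pytest

from flarediary import (
    APConfig,
    brute_force_exemplar_oracle,
    build_similarity,
    cluster_feature_matrix,
    preference_from_quantile,
    run_affinity_propagation,
)
from flarediary.apcluster import apply_preference, net_similarity


def _two_blobs(rng, n_per=4, dim=2, dist=10.0, radius=0.5):
    c0 = rng.normal(size=dim)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    c1 = c0 + dist * direction
    pts = np.vstack(
        [
            c0 + radius * rng.uniform(-1, 1, size=(n_per, dim)),
            c1 + radius * rng.uniform(-1, 1, size=(n_per, dim)),
        ]
    )
    return pts


class TestSimilarity:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        S = build_similarity(X)
        assert S[0, 1] == 0.0

    def test_one_dimensional_squared(self):
        S = build_similarity(np.array([[0.0], [3.0]]), r=2.0)
        assert S[0, 1] == pytest.approx(-9.0)
        assert S[1, 0] == pytest.approx(-9.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        S = build_similarity(X)
        Sp = build_similarity(X[perm])
        assert np.allclose(Sp, S[np.ix_(perm, perm)], equal_nan=True)

    def test_missing_values_rejected(self):
        X = np.array([[np.nan, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            build_similarity(X)


class TestPreference:
    @pytest.mark.parametrize("q, expected", [(0.0, -9.0), (1.0, -1.0), (0.5, -4.0)])
    def test_quantile_examples(self, q, expected):
        S = build_similarity(np.array([[0.0], [1.0], [3.0]]))
        # off-diagonal similarities are {-1, -4, -9}
        assert preference_from_quantile(S, q) == pytest.approx(expected)


class TestMessagePassing:
    def test_single_point(self):
        S = np.array([[-1.0]])
        res = run_affinity_propagation(S)
        assert res.exemplars == [0]
        assert list(res.labels) == [0]

    def test_identical_points_one_cluster(self):
        X = np.zeros((5, 2))
        res = cluster_feature_matrix(X, APConfig(q=0.0, seed=1))
        assert len(res.exemplars) == 1
        assert len(set(res.labels)) == 1

    def test_two_blobs_match_oracle(self):
        rng = np.random.default_rng(42)
        X = _two_blobs(rng)
        S = build_similarity(X)
        pref = preference_from_quantile(S, 0.0)
        Sp = apply_preference(S, pref)
        res = run_affinity_propagation(Sp, APConfig(q=0.0, tie_noise_scale=0.0))
        oracle_set, oracle_score = brute_force_exemplar_oracle(Sp)
        assert res.converged
        assert len(res.exemplars) == 2
        assert res.net_similarity == pytest.approx(oracle_score)
        assert sorted(res.exemplars) == sorted(oracle_set)

    def test_label_validity_and_determinism(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        cfg = APConfig(q=0.3, seed=9)
        a = cluster_feature_matrix(X, cfg)
        b = cluster_feature_matrix(X, cfg)
        assert set(a.labels) <= set(a.exemplars)
        for e in a.exemplars:
            assert a.labels[e] == e
        assert a.exemplars == b.exemplars
        assert np.array_equal(a.labels, b.labels)
        assert a.net_similarity == b.net_similarity

    def test_permutation_equivariance_of_labels(self):
        rng = np.random.default_rng(3)
        X = _two_blobs(rng, n_per=5)
        perm = rng.permutation(len(X))
        a = cluster_feature_matrix(X, APConfig(q=0.0, tie_noise_scale=0.0))
        b = cluster_feature_matrix(X[perm], APConfig(q=0.0, tie_noise_scale=0.0))
        # partitions agree up to exemplar renaming
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        for i in range(len(X)):
            for j in range(len(X)):
                same_a = a.labels[i] == a.labels[j]
                same_b = b.labels[inv[i]] == b.labels[inv[j]]
                assert same_a == same_b

    def test_monotone_cluster_count_in_preference(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 2))
        S = build_similarity(X)
        counts = []
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            pref = preference_from_quantile(S, q)
            res = run_affinity_propagation(
                apply_preference(S, pref), APConfig(seed=2)
            )
            counts.append(len(res.exemplars))
        assert counts == sorted(counts)

    def test_duplicate_rows_jitter_resolves(self):
        X = np.array([[-1.0, -1.0], [-1.0, -1.0], [1.0, 1.0], [1.0, 1.0]])
        res = cluster_feature_matrix(X, APConfig(q=0.0, seed=5))
        assert res.converged
        assert len(res.exemplars) == 2
        groups = {tuple(np.flatnonzero(res.labels == e)) for e in res.exemplars}
        assert groups == {(0, 1), (2, 3)}

    def test_agrees_with_sklearn_on_blobs(self):
        from sklearn.cluster import AffinityPropagation

        rng = np.random.default_rng(17)
        X = _two_blobs(rng, n_per=6, dist=8.0)
        S = build_similarity(X)
        pref = preference_from_quantile(S, 0.0)
        res = run_affinity_propagation(
            apply_preference(S, pref), APConfig(tie_noise_scale=0.0)
        )
        sk = AffinityPropagation(
            damping=0.9, preference=pref, affinity="euclidean", random_state=0
        ).fit(X)
        ours = [tuple(np.flatnonzero(res.labels == e)) for e in res.exemplars]
        theirs = [
            tuple(np.flatnonzero(sk.labels_ == k)) for k in range(sk.labels_.max() + 1)
        ]
        assert sorted(ours) == sorted(theirs)


class TestOracle:
    def test_identical_points_negative_preference(self):
        S = apply_preference(build_similarity(np.zeros((2, 1))), -1.0)
        exemplars, score = brute_force_exemplar_oracle(S)
        assert exemplars == [0]
        assert score == pytest.approx(-1.0)

    def test_distant_points_zero_preference(self):
        S = apply_preference(build_similarity(np.array([[0.0], [5.0]])), 0.0)
        exemplars, score = brute_force_exemplar_oracle(S)
        assert exemplars == [0, 1]
        assert score == pytest.approx(0.0)

    def test_oracle_upper_bounds_ap(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            X = rng.normal(size=(6, 2))
            S = build_similarity(X)
            Sp = apply_preference(S, preference_from_quantile(S, 0.0))
            res = run_affinity_propagation(Sp, APConfig(tie_noise_scale=0.0))
            _, best = brute_force_exemplar_oracle(Sp)
            assert best >= res.net_similarity - 1e-9

    def test_refuses_large_n(self):
        S = np.zeros((13, 13))
        with pytest.raises(ValueError, match="n <= 12"):
            brute_force_exemplar_oracle(S)
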