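import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import skew, special_ortho_group

from scpmp import (
    ClusterLabels,
    DataMatrix,
    ParameterError,
    adjusted_rand_index,
    elongation_score,
    entropy_metrics,
    geometric_perturbation,
)


def ari_contingency_oracle(truth, pred):
    """ARI from the pair-counting contingency-table formula."""
    t, p = np.asarray(truth), np.asarray(pred)
    tu, pu = np.unique(t), np.unique(p)
    nij = np.array([[np.sum((t == a) & (p == b)) for b in pu] for a in tu])
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = comb2(nij).sum()
    sum_a = comb2(nij.sum(axis=1)).sum()
    sum_b = comb2(nij.sum(axis=0)).sum()
    n = t.size
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    return (sum_ij - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_relabeling_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 4, size=30)
        p = rng.integers(1, 5, size=30)
        assert adjusted_rand_index(t, p) == pytest.approx(
            ari_contingency_oracle(t, p), abs=1e-12
        )

    def test_crossed_partition_hand_value(self):
        # truth (1,1,2,2) vs pred (1,2,1,2): all pair agreements are chance
        t, p = [1, 1, 2, 2], [1, 2, 1, 2]
        assert adjusted_rand_index(t, p) == pytest.approx(
            ari_contingency_oracle(t, p)
        )
        assert adjusted_rand_index(t, p) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_accepts_cluster_labels_objects(self):
        a = ClusterLabels(np.array([1, 1, 2, 2]), k=2, source="ground_truth")
        b = ClusterLabels(np.array([2, 2, 1, 1]), k=2)
        assert adjusted_rand_index(a, b) == 1.0


class TestEntropyMetrics:
    def test_perfect_partition_is_zero(self):
        ecp, eca = entropy_metrics([1, 1, 2, 2], [2, 2, 1, 1])
        assert ecp == 0.0 and eca == 0.0

    def test_mixed_cluster_contributes_ln2(self):
        # one predicted cluster holding two equal true classes: entropy ln 2
        ecp, eca = entropy_metrics([1, 1, 2, 2], [1, 1, 1, 1])
        assert ecp == pytest.approx(math.log(2))
        assert eca == 0.0  # each true class maps into one predicted cluster

    def test_singletons_are_pure_but_inaccurate(self):
        truth = [1, 1, 2, 2]
        pred = [1, 2, 3, 4]
        ecp, eca = entropy_metrics(truth, pred)
        assert ecp == 0.0
        assert eca == pytest.approx(math.log(2))

    def test_label_permutation_invariance(self, rng):
        t = rng.integers(1, 4, size=40)
        p = rng.integers(1, 4, size=40)
        perm = {1: 3, 2: 1, 3: 2}
        t2 = np.array([perm[v] for v in t])
        p2 = np.array([perm[v] for v in p])
        assert entropy_metrics(t, p) == pytest.approx(entropy_metrics(t2, p2))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 4), min_size=4, max_size=60), st.integers(0, 23))
    def test_permutation_invariance_property(self, labels, perm_idx):
        import itertools

        t = np.asarray(labels)
        rng = np.random.default_rng(0)
        p = rng.integers(1, 4, size=t.size)
        perm = list(itertools.permutations([1, 2, 3, 4]))[perm_idx]
        t2 = np.array([perm[v - 1] for v in t])
        assert entropy_metrics(t, p) == pytest.approx(entropy_metrics(t2, p))
        assert adjusted_rand_index(t, p) == pytest.approx(adjusted_rand_index(t2, p))

    def test_weighted_variant_differs_on_unbalanced_clusters(self):
        truth = [1, 2, 1, 2] + [1] * 16
        pred = [1] * 4 + [2] * 16  # mixed cluster is the small one
        unw, _ = entropy_metrics(truth, pred)
        w, _ = entropy_metrics(truth, pred, weighted=True)
        assert unw == pytest.approx(math.log(2) / 2)
        assert w == pytest.approx(math.log(2) * 4 / 20)


class TestGeometricPerturbation:
    def test_identity_embedding(self, blobs3):
        X, truth = blobs3
        gp = geometric_perturbation(X, X.values, truth)
        assert gp.pi == pytest.approx(0.0, abs=1e-12)
        assert gp.c_star == pytest.approx(1.0)

    def test_uniform_scaling_absorbed(self, blobs3):
        X, truth = blobs3
        gp = geometric_perturbation(X, 5.0 * X.values, truth)
        assert gp.pi == pytest.approx(0.0, abs=1e-12)
        assert gp.c_star == pytest.approx(0.2)

    def test_rigid_motion_invariance(self, blobs3):
        X, truth = blobs3
        rng = np.random.default_rng(4)
        R = special_ortho_group.rvs(2, random_state=rng)
        Y = 3.0 * X.values @ R + np.array([5.0, -2.0])
        assert geometric_perturbation(X, Y, truth).pi == pytest.approx(0.0, abs=1e-10)

    def test_collinear_means_against_grid_search_oracle(self):
        # X means at 0, 1, 2 and Y means at 0, 1, 3 on a line; the optimal
        # scale c is found by brute-force grid search as the oracle
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])[:, None]
        y = np.array([0.0, 0.0, 1.0, 1.0, 3.0, 3.0])[:, None]
        truth = [1, 1, 2, 2, 3, 3]
        gp = geometric_perturbation(x, y, truth)
        DX = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        DY = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
        # cluster sizes equal -> unweighted Frobenius suffices
        grid = np.linspace(0.0, 2.0, 200001)
        vals = [np.sum((DX - c * DY) ** 2) / np.sum(DX**2) for c in grid]
        assert gp.pi == pytest.approx(min(vals), abs=1e-8)

    def test_cluster_size_weighting_matches_pointwise_definition(self, rng):
        # the k x k weighted form must equal the n x n point-level matrix
        n = 30
        labels = rng.integers(1, 4, size=n)
        labels[:3] = [1, 2, 3]
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, 2))
        gp = geometric_perturbation(X, Y, labels)
        meansX = {j: X[labels == j].mean(axis=0) for j in (1, 2, 3)}
        meansY = {j: Y[labels == j].mean(axis=0) for j in (1, 2, 3)}
        DmuX = np.array(
            [[np.linalg.norm(meansX[labels[i]] - meansX[labels[j]]) for j in range(n)]
             for i in range(n)]
        )
        DmuY = np.array(
            [[np.linalg.norm(meansY[labels[i]] - meansY[labels[j]]) for j in range(n)]
             for i in range(n)]
        )
        c_star = (DmuX * DmuY).sum() / (DmuY**2).sum()
        pi = ((DmuX - c_star * DmuY) ** 2).sum() / (DmuX**2).sum()
        assert gp.c_star == pytest.approx(c_star, rel=1e-10)
        assert gp.pi == pytest.approx(pi, rel=1e-8, abs=1e-12)

    def test_single_cluster_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ParameterError):
            geometric_perturbation(X, X, np.ones(10, dtype=int))

    def test_coincident_embedding_means_rejected(self, blobs3):
        X, truth = blobs3
        with pytest.raises(ValueError, match="c\\*"):
            geometric_perturbation(X, np.zeros((X.n, 2)), truth)


class TestElongationScore:
    def test_hand_oracle_on_five_points(self):
        X = np.array([[0.0], [1.0], [2.0], [4.0], [8.0]])
        k = 2
        # 2nd-NN distances by hand: 2, 1, 2, 3, 6
        d = np.array([2.0, 1.0, 2.0, 3.0, 6.0])
        s = d.std(ddof=1)
        expected = 5 / (4 * 3) * np.sum(((d - d.mean()) / s) ** 3)
        got = elongation_score(X, k_nn=k)
        assert got.G1 == pytest.approx(expected, rel=1e-12)
        assert got.k_nn == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bias_corrected_skewness(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 3))
        got = elongation_score(DataMatrix(values=X))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d = np.sort(D, axis=1)[:, got.k_nn]
        assert got.G1 == pytest.approx(skew(d, bias=False), rel=1e-10)

    def test_default_k_is_ten_log_n(self, rng):
        X = rng.normal(size=(100, 2))
        assert elongation_score(X).k_nn == round(10 * math.log(100))

    def test_uniformly_spaced_ring_near_zero(self):
        # evenly spaced points with symmetric tiny jitter: k-NN distances
        # nearly constant, so skewness is near zero
        rng = np.random.default_rng(0)
        th = np.linspace(0, 2 * np.pi, 144, endpoint=False)
        radii = 1 + rng.normal(scale=0.001, size=144)
        X = np.c_[np.cos(th), np.sin(th)] * radii[:, None]
        assert abs(elongation_score(X, k_nn=4).G1) < 0.5

    def test_skewed_tail_positive(self):
        rng = np.random.default_rng(1)
        dense = rng.normal(scale=0.2, size=(80, 2))
        stragglers = rng.uniform(5, 50, size=(8, 2))
        score = elongation_score(np.vstack([dense, stragglers]), k_nn=5)
        assert score.G1 > 1.0

    def test_equal_distances_give_zero_with_warning(self):
        # equilateral triangle: all 1-NN distances equal
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        with pytest.warns(UserWarning):
            assert elongation_score(X, k_nn=1).G1 == 0.0

    def test_elongated_ewb_scores_higher_than_isotropic(self):
        from scpmp import synthetic

        # bridge-free so the comparison isolates cluster shape
        spec = synthetic.default_spec("ewb", seed=0, extra={"n_bridge": 0})
        X, _ = synthetic.generate(spec)
        iso = synthetic.default_spec(
            "ewb", seed=0, extra={"n_bridge": 0, "sd_long": 0.35}
        )  # isotropic override
        X_iso, _ = synthetic.generate(iso)
        assert elongation_score(X).G1 > elongation_score(X_iso).G1
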