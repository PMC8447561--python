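"""Spearman distance, Ward linkage (vs brute-force oracle), tree cuts,
Calinski–Harabasz, and semantic labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from conftest import planted_z_matrix
from lipophen.cluster import (
    HYPO, NORMO, ClusterAssignment, ClusteringError, DistanceMatrix,
    SpearmanWardClusterer, calinski_harabasz, cut_tree, elbow_curve,
    label_clusters, spearman_distance, ward_linkage,
)


def zframe(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids)


# ---------------------------------------------------------------------------
# independent O(n^3) re-scan oracle: Ward distances recomputed from the
# original dissimilarities at every step via the centroid identity
#   ||c_A - c_B||^2 = mean(d2[A,B]) - mean(d2[A,A])/2 - mean(d2[B,B])/2
#   height(A,B) = sqrt(2 * |A||B|/(|A|+|B|) * ||c_A - c_B||^2)
# ---------------------------------------------------------------------------

def ward_oracle(d):
    d2 = np.asarray(d, dtype=float) ** 2
    n = len(d2)

    def wdist(A, B):
        ab = d2[np.ix_(A, B)].mean()
        aa = d2[np.ix_(A, A)].mean() / 2.0
        bb = d2[np.ix_(B, B)].mean() / 2.0
        gap = ab - aa - bb
        return 2.0 * len(A) * len(B) / (len(A) + len(B)) * max(gap, 0.0)

    clusters = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                val = wdist(clusters[i], clusters[j])
                key = (val, min(clusters[i][0], clusters[j][0]),
                       max(clusters[i][0], clusters[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((frozenset(a + b), np.sqrt(best[0][0])))
        merged = sorted(a + b)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return merges


def member_sets(tree):
    n = tree.n_leaves
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (left, right, height, _) in enumerate(tree.merges):
        merged = sets[int(left)] | sets[int(right)]
        sets[n + step] = merged
        out.append((merged, height))
    return out


def random_distance(rng, n):
    """Random symmetric dissimilarity in [0, 2] with zero diagonal."""
    d = rng.uniform(0.05, 2.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


class TestSpearmanDistance:
    def test_self_distance_zero(self):
        d = spearman_distance(zframe([[1, 2, 3, 4], [1, 2, 3, 4]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_anti_monotone_profiles_at_two(self):
        d = spearman_distance(zframe([[1, 2, 3, 4], [8, 6, 4, 2]]))
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_partial_rank_agreement(self):
        # rho((1,2,3),(1,3,2)) = 0.5 by direct rank enumeration -> d = 0.5
        d = spearman_distance(zframe([[1, 2, 3], [1, 3, 2]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_all_tied_profile_is_error(self):
        with pytest.raises(ClusteringError, match="p1"):
            spearman_distance(zframe([[1, 2, 3], [5, 5, 5]], ids=["p0", "p1"]))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30)
    def test_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X = zframe(rng.normal(size=(6, 5)))
        d = spearman_distance(X).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_matches_scipy_spearman(self, rng):
        from scipy.stats import spearmanr
        X = zframe(rng.normal(size=(5, 8)))
        d = spearman_distance(X).values
        for i in range(5):
            for j in range(i + 1, 5):
                rho = spearmanr(X.iloc[i], X.iloc[j]).statistic
                assert d[i, j] == pytest.approx(1.0 - rho, abs=1e-12)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        d = DistanceMatrix(np.array([[0.0, 0.7], [0.7, 0.0]]), ["a", "b"])
        tree = ward_linkage(d)
        assert tree.merges[0, 2] == pytest.approx(0.7)
        assert tree.merges[0, 3] == 2

    def test_duplicates_merge_first_at_zero(self):
        X = zframe([[1, 2, 3], [9, 1, 4], [1, 2, 3]])
        tree = ward_linkage(spearman_distance(X))
        assert tree.merges[0, 2] == pytest.approx(0.0)
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 2}

    def test_singleton_matrix_is_error(self):
        with pytest.raises(ClusteringError):
            ward_linkage(DistanceMatrix(np.zeros((1, 1)), ["a"]))

    def test_heights_monotone_non_decreasing(self, rng):
        for _ in range(10):
            tree = ward_linkage(
                DistanceMatrix(random_distance(rng, 9),
                               [f"p{i}" for i in range(9)]))
            heights = tree.merges[:, 2]
            assert (np.diff(heights) >= -1e-10).all()

    @given(st.integers(0, 10_000), st.integers(3, 12))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_equals_rescan_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        d = random_distance(rng, n)
        tree = ward_linkage(DistanceMatrix(d, [f"p{i}" for i in range(n)]))
        got = member_sets(tree)
        expected = ward_oracle(d)
        for (ms, h), (oms, oh) in zip(got, expected):
            assert ms == oms
            assert h == pytest.approx(oh, abs=1e-8)

    def test_matches_scipy_ward(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        for _ in range(20):
            d = random_distance(rng, 10)
            tree = ward_linkage(DistanceMatrix(d, [f"p{i}" for i in range(10)]))
            Z = linkage(squareform(d, checks=False), method="ward")
            assert np.allclose(tree.merges[:, 2], Z[:, 2], atol=1e-8)
            assert np.allclose(tree.merges[:, 3], Z[:, 3])


class TestCutTree:
    def test_k1_and_kn(self, rng):
        d = DistanceMatrix(random_distance(rng, 6), [f"p{i}" for i in range(6)])
        tree = ward_linkage(d)
        assert len(set(cut_tree(tree, 1).index)) == 1
        assert len(set(cut_tree(tree, 6).index)) == 6

    def test_k_out_of_range(self, rng):
        d = DistanceMatrix(random_distance(rng, 4), [f"p{i}" for i in range(4)])
        tree = ward_linkage(d)
        with pytest.raises(ClusteringError):
            cut_tree(tree, 0)
        with pytest.raises(ClusteringError):
            cut_tree(tree, 5)

    def test_recovers_planted_blobs(self):
        X, truth = planted_z_matrix(n=100, sep=3.0, seed=1)
        assign = cut_tree(ward_linkage(spearman_distance(X)), 2)
        assert adjusted_rand_score(truth, assign.index) >= 0.9

    def test_leaf_order_is_permutation(self, rng):
        d = DistanceMatrix(random_distance(rng, 7), [f"p{i}" for i in range(7)])
        tree = ward_linkage(d)
        assert sorted(tree.leaf_order()) == list(range(7))


class TestCalinskiHarabasz:
    def test_hand_computed_fixture(self):
        # points 0,1,10,11 in 1-D, clusters {0,1} {10,11}: B=100, W=1 -> 200
        X = zframe([[0.0], [1.0], [10.0], [11.0]])
        assign = ClusterAssignment(index=np.array([0, 0, 1, 1]),
                                   ids=list(X.index), k=2)
        assert calinski_harabasz(X, assign) == pytest.approx(200.0)

    def test_zero_within_dispersion_returns_inf(self):
        X = zframe([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        assign = ClusterAssignment(index=np.array([0, 0, 1, 1]),
                                   ids=list(X.index), k=2)
        with pytest.warns(UserWarning):
            assert calinski_harabasz(X, assign) == np.inf

    def test_matches_sklearn(self, rng):
        X = zframe(rng.normal(size=(30, 4)))
        assign = cut_tree(ward_linkage(spearman_distance(X)), 3)
        ours = calinski_harabasz(X, assign)
        theirs = calinski_harabasz_score(X.to_numpy(), assign.index)
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_planted_beats_random_labels(self, rng):
        X, truth = planted_z_matrix(n=60, sep=3.0, seed=2)
        planted = cut_tree(ward_linkage(spearman_distance(X)), 2)
        random_labels = rng.integers(0, 2, size=60)
        while len(set(random_labels)) < 2:
            random_labels = rng.integers(0, 2, size=60)
        random_assign = ClusterAssignment(index=random_labels,
                                          ids=list(X.index), k=2)
        assert calinski_harabasz(X, planted) > calinski_harabasz(X, random_assign)


class TestElbow:
    def test_within_ss_zero_at_k_equals_n(self, rng):
        X = zframe(rng.normal(size=(8, 4)))
        tree = ward_linkage(spearman_distance(X))
        q = elbow_curve(X, tree, range(1, 9))
        assert q.within_ss[8] == pytest.approx(0.0)

    def test_within_ss_non_increasing(self, rng):
        X = zframe(rng.normal(size=(15, 5)))
        tree = ward_linkage(spearman_distance(X))
        q = elbow_curve(X, tree, range(1, 16))
        ws = [q.within_ss[k] for k in range(1, 16)]
        assert all(a >= b - 1e-10 for a, b in zip(ws, ws[1:]))

    def test_best_k_two_on_planted_blobs(self):
        X, _ = planted_z_matrix(n=80, sep=3.0, seed=3)
        tree = ward_linkage(spearman_distance(X))
        q = elbow_curve(X, tree, range(2, 9))
        assert q.best_k() == 2


class TestLabeling:
    def test_lower_anchor_median_is_hypo(self):
        # cluster medians 7.25 vs 26.5 mg/dL HDL-C
        X = zframe([[7, 1], [7.5, 2], [26, 1], [27, 2]])
        X.columns = ["hdl_c", "other"]
        assign = ClusterAssignment(index=np.array([0, 0, 1, 1]),
                                   ids=list(X.index), k=2)
        labelled = label_clusters(assign, X, anchor_feature="hdl_c")
        sem = labelled.semantic()
        assert sem.iloc[0] == HYPO and sem.iloc[2] == NORMO

    def test_k_not_two_is_error(self, rng):
        d = DistanceMatrix(random_distance(rng, 5), [f"p{i}" for i in range(5)])
        assign = cut_tree(ward_linkage(d), 3)
        with pytest.raises(ClusteringError):
            label_clusters(assign, zframe(rng.normal(size=(5, 2))), "0")


class TestEstimatorPipeline:
    def test_row_permutation_invariance(self):
        X, _ = planted_z_matrix(n=40, sep=2.5, seed=4)
        X.columns = [f"f{i}" for i in range(X.shape[1])]
        X = X.rename(columns={"f0": "hdl_c"})
        a = SpearmanWardClusterer(n_clusters=2).fit(X)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        b = SpearmanWardClusterer(n_clusters=2).fit(X.iloc[perm])
        sa, sb = a.assignment_.semantic(), b.assignment_.semantic()
        pd.testing.assert_series_equal(sa.sort_index(), sb.sort_index())

    def test_ari_monotone_in_separation(self):
        from lipophen.preprocess import fit_scaler, apply_scaler
        from lipophen.schema import CLUSTERING_FEATURES
        from lipophen.simulate import default_derivation_config, generate_cohort
        from lipophen.preprocess import impute_median

        aris = []
        for scale in (0.0, 0.5, 1.0):
            cfg = default_derivation_config(n=120, seed=5)
            base = default_derivation_config()
            for f in cfg.feature_means["hypo"]:
                mid = (base.feature_means["hypo"][f]
                       + base.feature_means["normo"][f]) / 2.0
                for ph in ("hypo", "normo"):
                    cfg.feature_means[ph][f] = \
                        mid + scale * (base.feature_means[ph][f] - mid)
            for ph in ("hypo", "normo"):
                for comp, v in base.sofa_shifts[ph].items():
                    mid = (base.sofa_shifts["hypo"][comp]
                           + base.sofa_shifts["normo"][comp]) / 2.0
                    cfg.sofa_shifts[ph][comp] = mid + scale * (v - mid)
            table, labels = generate_cohort(cfg)
            truth = [1 if l == "hypo" else 0 for l in labels]
            filled, _ = impute_median(table.to_frame(), CLUSTERING_FEATURES)
            z = apply_scaler(filled, fit_scaler(filled, CLUSTERING_FEATURES),
                             do_cap=False)
            assign = cut_tree(ward_linkage(spearman_distance(z)), 2)
            aris.append(adjusted_rand_score(truth, assign.index))
        assert aris[0] <= aris[1] + 0.05 <= aris[2] + 0.10
        assert abs(aris[0]) < 0.1          # no signal -> chance agreement
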