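"""Threshold calibration, flat BIRCH clustering, membership assignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist, pdist

from gcfkit.cluster import (
    assign_membership,
    build_gcf_models,
    calibrate_threshold,
    categorize,
)
from gcfkit.features import FeatureMatrix


def _matrix(X, ids=None):
    X = np.asarray(X, dtype=float)
    ids = ids or [f"b{i:04d}" for i in range(X.shape[0])]
    return FeatureMatrix(ids, [f"c{j}" for j in range(X.shape[1])], X)


def _blobs(rng, n_clusters=5, per_cluster=40, dim=12, spread=10.0, sep=600.0):
    centers = rng.uniform(0, sep, size=(n_clusters, dim))
    X = np.vstack([
        centers[k] + rng.normal(0, spread, size=(per_cluster, dim))
        for k in range(n_clusters)
    ])
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    return X, labels


# ---------------------------------------------------------------------------
# calibrate_threshold


def _calibration_oracle(X, percentile, n_batches, batch_size, seed):
    """Independent re-derivation: enumerate all within-batch pairs."""
    rng = np.random.default_rng(seed)
    n = len(X)
    take = min(batch_size, n)
    vals = []
    for _ in range(n_batches):
        idx = rng.choice(n, size=take, replace=False)
        d = [
            float(np.sqrt(((X[idx[i]] - X[idx[j]]) ** 2).sum()))
            for i in range(take)
            for j in range(i + 1, take)
        ]
        vals.append(np.percentile(d, percentile))
    return float(np.mean(vals))


def test_identical_rows_calibrate_to_zero():
    M = _matrix(np.tile([1.0, 2.0, 3.0], (10, 1)))
    assert calibrate_threshold(M, seed=1).T == 0.0


def test_calibration_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    X, _ = _blobs(rng, n_clusters=2, per_cluster=30)
    M = _matrix(X)
    cal = calibrate_threshold(M, X=1.0, n_batches=5, batch_size=20, seed=123)
    oracle = _calibration_oracle(X, 1.0, 5, 20, 123)
    assert cal.T == pytest.approx(oracle, rel=1e-12)


def test_small_matrix_uses_all_rows_every_batch():
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 255, size=(50, 6))
    M = _matrix(X)
    cal = calibrate_threshold(M, X=5.0, n_batches=7, batch_size=1000, seed=0)
    expected = float(np.percentile(pdist(X), 5.0))
    assert cal.T == pytest.approx(expected, rel=1e-12)


def test_single_row_cannot_calibrate():
    with pytest.raises(ValueError, match="single"):
        calibrate_threshold(_matrix([[1.0, 2.0]]))


def test_bad_percentile_rejected():
    M = _matrix(np.zeros((4, 2)))
    with pytest.raises(ValueError):
        calibrate_threshold(M, X=0.0)


# ---------------------------------------------------------------------------
# build_gcf_models vs oracles


def _leader_birch_oracle(X, T):
    """Brute-force incremental clusterer with the same admission rule:
    nearest subcluster by centroid distance, absorb iff RMS radius of
    the updated subcluster stays ≤ T."""
    clusters = []  # list of lists of row indices
    for i, x in enumerate(X):
        best, best_d = None, np.inf
        for c, rows in enumerate(clusters):
            centroid = X[rows].mean(axis=0)
            d = np.linalg.norm(centroid - x)
            if d < best_d:
                best, best_d = c, d
        if best is not None:
            rows = clusters[best] + [i]
            mean = X[rows].mean(axis=0)
            rms = np.sqrt(((X[rows] - mean) ** 2).sum(axis=1).mean())
            if rms <= T:
                clusters[best].append(i)
                continue
        clusters.append([i])
    return clusters


@pytest.mark.parametrize("seed", range(20))
def test_flat_birch_equals_bruteforce_oracle(seed):
    """On ≤200 random vectors the incremental clusterer must reproduce
    the brute-force implementation of the same rule, for 20 random
    seeds/orders."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    X = rng.choice([0.0, 85.0, 170.0, 255.0], size=(n, 8), p=[0.7, 0.1, 0.1, 0.1])
    T = float(rng.uniform(0, 500))
    models = build_gcf_models(_matrix(X), T)
    oracle = _leader_birch_oracle(X, T)
    got = [m.member_bgc_ids for m in models]
    expected = [[f"b{i:04d}" for i in rows] for rows in oracle]
    assert got == expected
    for m, rows in zip(models, oracle):
        np.testing.assert_allclose(m.centroid, X[rows].mean(axis=0), atol=1e-9)


def test_flat_birch_matches_sklearn_birch():
    """Cross-check against scikit-learn's BIRCH with a flat tree
    (branching factor ≥ n_samples), which implements the same
    clustering-feature admission rule."""
    from sklearn.cluster import Birch

    rng = np.random.default_rng(42)
    X, _ = _blobs(rng, n_clusters=4, per_cluster=30, spread=20.0)
    T = 150.0
    models = build_gcf_models(_matrix(X), T)
    sk = Birch(threshold=T, branching_factor=len(X) + 1, n_clusters=None).fit(X)
    mine = np.vstack([m.centroid for m in models])
    assert mine.shape == sk.subcluster_centers_.shape
    # identical subcluster centroids up to ordering
    np.testing.assert_allclose(
        mine[np.lexsort(mine.T[::-1])],
        sk.subcluster_centers_[np.lexsort(sk.subcluster_centers_.T[::-1])],
        atol=1e-8,
    )
    # sklearn's labels_ are a nearest-centroid pass over the final
    # subclusters; the same pass over my centroids must agree
    from sklearn.metrics import adjusted_rand_score

    relabel = cdist(X, mine).argmin(axis=1)
    assert adjusted_rand_score(relabel, sk.labels_) == 1.0


def test_huge_threshold_single_cluster():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 255, size=(30, 5))
    models = build_gcf_models(_matrix(X), T=1e6)
    assert len(models) == 1
    np.testing.assert_allclose(models[0].centroid, X.mean(axis=0))
    assert models[0].n_members == 30


def test_zero_threshold_distinct_rows_are_singletons():
    X = np.diag([255.0] * 6)
    models = build_gcf_models(_matrix(X), T=0.0)
    assert len(models) == 6
    for m in models:
        assert m.n_members == 1


def test_member_counts_partition_training_set():
    rng = np.random.default_rng(5)
    X, _ = _blobs(rng, n_clusters=3, per_cluster=25)
    M = _matrix(X)
    models = build_gcf_models(M, T=200.0)
    assert sum(m.n_members for m in models) == M.n
    all_members = [b for m in models for b in m.member_bgc_ids]
    assert sorted(all_members) == sorted(M.bgc_ids)


def test_empty_matrix_raises_no_training_bgcs():
    M = FeatureMatrix([], ["c0"], np.zeros((0, 1)))
    with pytest.raises(ValueError, match="no training BGCs"):
        build_gcf_models(M, T=100.0)


def test_gcf_count_non_increasing_in_threshold():
    rng = np.random.default_rng(17)
    X, _ = _blobs(rng, n_clusters=5, per_cluster=20, spread=30.0)
    M = _matrix(X)
    counts = [len(build_gcf_models(M, T)) for T in [0, 50, 150, 400, 800, 2000]]
    assert counts == sorted(counts, reverse=True)


def test_determinism_fixed_order_identical_models():
    rng = np.random.default_rng(9)
    X, _ = _blobs(rng, n_clusters=3, per_cluster=15)
    M = _matrix(X)
    a = build_gcf_models(M, 120.0)
    b = build_gcf_models(M, 120.0)
    assert [m.member_bgc_ids for m in a] == [m.member_bgc_ids for m in b]
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.centroid, mb.centroid)


# ---------------------------------------------------------------------------
# membership + categorize


def test_membership_matches_exhaustive_sort():
    rng = np.random.default_rng(31)
    C = rng.uniform(0, 255, size=(10, 6))
    Q = rng.uniform(0, 255, size=(20, 6))
    models = build_gcf_models(_matrix(C), T=0.0)  # 10 singleton models
    mem = assign_membership(_matrix(Q, ids=[f"q{i}" for i in range(20)]), models, N=4)
    D = cdist(Q, np.vstack([m.centroid for m in models]))
    for i, m in enumerate(mem):
        order = np.argsort(D[i], kind="stable")[:4]
        assert [g for g, _ in m.ranks] == [models[j].gcf_id for j in order]
        np.testing.assert_allclose([d for _, d in m.ranks], D[i, order])
        assert all(m.ranks[k][1] <= m.ranks[k + 1][1] for k in range(len(m.ranks) - 1))


def test_query_equal_to_centroid_has_zero_distance():
    X = np.array([[255.0, 0.0], [0.0, 255.0]])
    models = build_gcf_models(_matrix(X), T=0.0)
    mem = assign_membership(_matrix(X[:1], ids=["q"]), models, N=1)
    assert mem[0].best_distance == 0.0
    assert mem[0].category == "core"


def test_n_larger_than_model_count_truncates():
    X = np.diag([255.0] * 3)
    models = build_gcf_models(_matrix(X), T=0.0)
    mem = assign_membership(_matrix(X[:1], ids=["q"]), models, N=10)
    assert len(mem[0].ranks) == 3


def test_column_mismatch_rejected():
    models = build_gcf_models(_matrix(np.zeros((2, 3)) + 1.0), T=10.0)
    with pytest.raises(ValueError, match="columns"):
        assign_membership(_matrix(np.zeros((1, 5))), models)


def test_categorize_printed_rule_boundaries():
    T = 900.0
    assert categorize(T, T) == "core"            # d = T
    assert categorize(1.5 * T, T) == "putative"  # T < d ≤ 2T
    assert categorize(2 * T, T) == "putative"    # d = 2T inclusive
    assert categorize(2 * T + 1e-9, T) == "orphan"
    assert categorize(0.0, 0.0) == "core"


@given(st.floats(0, 1e6), st.floats(0, 1e6))
@settings(deadline=None)
def test_categorize_partitions_halfline(d, T):
    assert categorize(d, T) in {"core", "putative", "orphan"}
    if d <= T:
        assert categorize(d, T) == "core"
    elif d <= 2 * T:
        assert categorize(d, T) == "putative"
    else:
        assert categorize(d, T) == "orphan"


# ---------------------------------------------------------------------------
# planted recovery (parameter recovery on the pipeline fixture)


def test_planted_partition_recovered_at_calibrated_threshold(planted_set, planted_matrix):
    from gcfkit.evaluate import v_score

    T = calibrate_threshold(planted_matrix, seed=77).T
    models = build_gcf_models(planted_matrix, T)
    predicted = {b: m.gcf_id for m in models for b in m.member_bgc_ids}
    truth = planted_set.truth.set_index("bgc_id").gcf_truth
    reference = {b: int(truth[b]) for b in predicted}
    score = v_score(predicted, reference)
    assert score.v_score == pytest.approx(1.0)
    # planted geometry premise: between-centroid distances dominate
    labels = np.array([truth[b] for b in planted_matrix.bgc_ids])
    centroids = np.vstack(
        [planted_matrix.values[labels == g].mean(axis=0) for g in np.unique(labels)]
    )
    within = max(
        np.sqrt(((planted_matrix.values[labels == g] - centroids[i]) ** 2).sum(axis=1).mean())
        for i, g in enumerate(np.unique(labels))
    )
    between = pdist(centroids).min()
    assert within == 0.0 or between / within >= 4.0
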