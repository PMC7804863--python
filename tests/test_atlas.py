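"""GCF binning, phylogram export, novelty distance, per-species richness."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from gcfkit.atlas import (
    bin_gcfs,
    double_normalized_dataset_distribution,
    export_bin_phylogram,
    gcf_richness,
    nearest_reference_distance,
)
from gcfkit.cluster import GcfModel, Membership
from gcfkit.features import FeatureMatrix
from gcfkit.records import TAXONOMY_RANKS


def _models(X, T=100.0):
    return [GcfModel(i, np.asarray(x, dtype=float), 1, T) for i, x in enumerate(X)]


def _blob_models(rng, n_clusters=5, per_cluster=10, dim=8, sep=800.0, spread=10.0):
    centers = rng.uniform(0, sep, size=(n_clusters, dim))
    X = np.vstack([
        centers[k] + rng.normal(0, spread, size=(per_cluster, dim))
        for k in range(n_clusters)
    ])
    return _models(X), np.repeat(np.arange(n_clusters), per_cluster)


# ---------------------------------------------------------------------------
# bin_gcfs


def test_every_bin_a_singleton_when_bins_equal_models():
    models = _models(np.diag([255.0] * 4))
    bins, _ = bin_gcfs(models, n_bins=4, seed=0)
    assert sorted(len(b.member_gcf_ids) for b in bins) == [1, 1, 1, 1]
    assert sorted(g for b in bins for g in b.member_gcf_ids) == [0, 1, 2, 3]


def test_binning_is_seed_deterministic():
    rng = np.random.default_rng(2)
    models, _ = _blob_models(rng)
    a, _ = bin_gcfs(models, 5, seed=9)
    b, _ = bin_gcfs(models, 5, seed=9)
    assert [x.member_gcf_ids for x in a] == [x.member_gcf_ids for x in b]


def test_bins_recover_planted_geometry_and_match_nearest_oracle():
    rng = np.random.default_rng(3)
    models, labels = _blob_models(rng, n_clusters=5)
    bins, _ = bin_gcfs(models, 5, seed=1)
    # bins coincide with planted clusters
    for b in bins:
        assert len({labels[g] for g in b.member_gcf_ids}) == 1
    assert sum(len(b.member_gcf_ids) for b in bins) == len(models)
    # assignment equals the exhaustive nearest-centroid oracle
    X = np.vstack([m.centroid for m in models])
    C = np.vstack([b.centroid for b in bins])
    oracle = cdist(X, C).argmin(axis=1)
    for j, b in enumerate(bins):
        for g in b.member_gcf_ids:
            assert oracle[g] == j


def test_second_pass_maps_bgc_features_onto_bins():
    rng = np.random.default_rng(7)
    models, labels = _blob_models(rng, n_clusters=3)
    X = np.vstack([m.centroid for m in models])
    M = FeatureMatrix([f"b{i}" for i in range(len(X))],
                      [f"c{j}" for j in range(X.shape[1])], X)
    bins, assignment = bin_gcfs(models, 3, seed=0, bgc_matrix=M,
                                bgc_datasets={f"b{i}": f"ds{labels[i] % 2}" for i in range(len(X))})
    assert len(assignment) == len(X)
    C = np.vstack([b.centroid for b in bins])
    np.testing.assert_array_equal(assignment.bin_id.to_numpy(), cdist(X, C).argmin(axis=1))
    dist = double_normalized_dataset_distribution(bins)
    sums = dist.sum(axis=1)
    assert ((sums - 1.0).abs() < 1e-9).all()


def test_more_bins_than_models_rejected():
    with pytest.raises(ValueError):
        bin_gcfs(_models(np.zeros((3, 2))), 4)


# ---------------------------------------------------------------------------
# phylogram


def test_newick_roundtrip_and_leaf_set():
    rng = np.random.default_rng(5)
    models, _ = _blob_models(rng, n_clusters=3, per_cluster=2)
    bins, _ = bin_gcfs(models, 3, seed=0)
    nwk = export_bin_phylogram(bins)
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert labels == {f"bin{b.bin_id}" for b in bins}


def test_merge_heights_non_decreasing_rootward():
    """Average-linkage merge heights grow monotonically, so every
    child's distance-to-leaves never exceeds its parent's."""
    from scipy.cluster.hierarchy import linkage

    rng = np.random.default_rng(11)
    models, _ = _blob_models(rng, n_clusters=4, per_cluster=3)
    bins, _ = bin_gcfs(models, 4, seed=0)
    X = np.vstack([b.centroid for b in bins] + [np.zeros_like(bins[0].centroid)])
    Z = linkage(X, method="average")
    heights = Z[:, 2]
    assert (np.diff(heights) >= -1e-9).all()


def test_identical_centroids_merge_at_zero_height():
    c = np.array([100.0, 50.0, 0.0])
    bins_in = [
        type("B", (), {"bin_id": i, "centroid": c.copy()})() for i in range(2)
    ] + [type("B", (), {"bin_id": 2, "centroid": c + 500.0})()]
    nwk = export_bin_phylogram(bins_in)
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    t0 = tree.taxon_namespace.get_taxon("bin0")
    t1 = tree.taxon_namespace.get_taxon("bin1")
    assert pdm.distance(t0, t1) == pytest.approx(0.0, abs=1e-9)


def test_fewer_than_two_bins_rejected():
    with pytest.raises(ValueError):
        export_bin_phylogram([type("B", (), {"bin_id": 0, "centroid": np.zeros(3)})()])


# ---------------------------------------------------------------------------
# nearest reference distance


def test_centroid_equal_to_reference_is_related():
    ref = FeatureMatrix(["r0", "r1"], ["c0", "c1"], np.array([[255.0, 0.0], [0.0, 255.0]]))
    models = _models([[255.0, 0.0]])
    out = nearest_reference_distance(models, ref, T=100.0)
    assert out.min_distance[0] == 0.0
    assert out["class"][0] == "related"
    assert out.nearest_reference[0] == "r0"


def test_nearest_reference_matches_exhaustive_oracle():
    rng = np.random.default_rng(13)
    C = rng.uniform(0, 255, size=(50, 6))
    R = rng.uniform(0, 255, size=(30, 6))
    ref = FeatureMatrix([f"r{i}" for i in range(30)], [f"c{j}" for j in range(6)], R)
    out = nearest_reference_distance(_models(C), ref, T=300.0)
    D = cdist(C, R)
    np.testing.assert_allclose(out.min_distance.to_numpy(), D.min(axis=1))
    np.testing.assert_array_equal(
        out["class"].to_numpy(), np.where(D.min(axis=1) <= 300.0, "related", "distant")
    )


def test_related_set_monotone_in_threshold():
    rng = np.random.default_rng(14)
    C = rng.uniform(0, 255, size=(20, 4))
    R = rng.uniform(0, 255, size=(10, 4))
    ref = FeatureMatrix([f"r{i}" for i in range(10)], [f"c{j}" for j in range(4)], R)
    models = _models(C)
    r1 = set(nearest_reference_distance(models, ref, 100.0).query("`class`=='related'").gcf_id)
    r2 = set(nearest_reference_distance(models, ref, 400.0).query("`class`=='related'").gcf_id)
    assert r1 <= r2


def test_empty_reference_set_rejected():
    ref = FeatureMatrix([], ["c0"], np.zeros((0, 1)))
    with pytest.raises(ValueError):
        nearest_reference_distance(_models([[1.0]]), ref, 1.0)


# ---------------------------------------------------------------------------
# richness


def _taxonomy(species_of):
    rows = []
    for genome, sp in species_of.items():
        rows.append({"genome_id": genome,
                     **{r: "x" for r in TAXONOMY_RANKS[:-1]}, "species": sp})
    return pd.DataFrame(rows).set_index("genome_id")


def _mem(bgc, gcf, category="core"):
    return Membership(bgc, [(gcf, 0.0)], category)


def test_shared_single_gcf_across_four_genomes():
    mems = [_mem(f"b{i}", 7) for i in range(4)]
    tax = _taxonomy({f"g{i}": "SpA" for i in range(4)})
    out = gcf_richness(mems, {f"b{i}": f"g{i}" for i in range(4)}, tax, min_genomes=4)
    assert len(out) == 1
    row = out.iloc[0]
    assert row.n_gcfs == 1 and row.n_genomes == 4
    assert row.shared_80_100 == 1 and row.shared_0_20 == 0


def test_disjoint_gcfs_fall_in_second_bin():
    # 4 genomes with disjoint single GCFs: sharedness 1/4 → bin (0.2, 0.4]
    mems = [_mem(f"b{i}", i) for i in range(4)]
    tax = _taxonomy({f"g{i}": "SpA" for i in range(4)})
    out = gcf_richness(mems, {f"b{i}": f"g{i}" for i in range(4)}, tax, min_genomes=4)
    row = out.iloc[0]
    assert row.n_gcfs == 4
    assert row.shared_20_40 == 4


def test_species_below_min_genomes_excluded():
    mems = [_mem(f"b{i}", 1) for i in range(3)]
    tax = _taxonomy({f"g{i}": "SpB" for i in range(3)})
    out = gcf_richness(mems, {f"b{i}": f"g{i}" for i in range(3)}, tax, min_genomes=4)
    assert out.empty


def test_non_core_assignments_do_not_count():
    mems = [_mem(f"b{i}", 1) for i in range(4)] + [_mem("b9", 2, category="orphan")]
    genomes = {f"b{i}": f"g{i}" for i in range(4)}
    genomes["b9"] = "g0"
    tax = _taxonomy({f"g{i}": "SpA" for i in range(4)})
    out = gcf_richness(mems, genomes, tax, min_genomes=4)
    assert out.iloc[0].n_gcfs == 1


def test_missing_taxonomy_warns_and_excludes():
    mems = [_mem("b0", 1)]
    tax = _taxonomy({"gX": "SpA"})
    with pytest.warns(UserWarning, match="no taxonomy"):
        out = gcf_richness(mems, {"b0": "gOther"}, tax, min_genomes=1)
    assert out.empty
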