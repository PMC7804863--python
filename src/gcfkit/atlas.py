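"""Global-map analyses over a finished clustering run.

Four downstream views of a GCF collection:

* :func:`bin_gcfs` — compress many GCF centroids into a small number of
  K-means "bins" for visualization, then map all BGC features onto the
  bin centroids;
* :func:`export_bin_phylogram` — average-linkage dendrogram over bin
  centroids, rooted on an all-zero dummy vector and exported as Newick;
* :func:`nearest_reference_distance` — per-GCF distance to the closest
  reference BGC (e.g. a characterized-compound collection), classifying
  each GCF as *related* (d ≤ T) or *distant*;
* :func:`gcf_richness` — per-species GCF counts and sharedness
  histograms for species with enough strain-level genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .cluster import GcfModel, Membership
from .features import FeatureMatrix

_ROOT_LABEL = "__null_root__"


@dataclass
class GcfBin:
    bin_id: int
    centroid: np.ndarray
    member_gcf_ids: list[int]
    bgc_counts_per_dataset: dict[str, int] = field(default_factory=dict)


def bin_gcfs(
    models: Sequence[GcfModel],
    n_bins: int,
    seed: int = 0,
    bgc_matrix: FeatureMatrix | None = None,
    bgc_datasets: Mapping[str, str] | None = None,
) -> tuple[list[GcfBin], pd.DataFrame | None]:
    """Partition GCF centroids into K-means bins.

    K-means uses k-means++ initialization under ``seed`` with 10
    restarts, keeping the best inertia.  When ``bgc_matrix`` is given, a
    second membership pass maps every BGC feature row onto its nearest
    bin centroid and (with ``bgc_datasets``) tallies the per-dataset BGC
    distribution of each bin; the per-BGC assignment is returned as a
    DataFrame.
    """
    if n_bins > len(models):
        raise ValueError(f"n_bins ({n_bins}) exceeds number of GCF models ({len(models)})")
    X = np.vstack([m.centroid for m in models])
    km = KMeans(n_clusters=n_bins, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    bins = [
        GcfBin(
            bin_id=b,
            centroid=km.cluster_centers_[b],
            member_gcf_ids=[models[i].gcf_id for i in np.flatnonzero(labels == b)],
        )
        for b in range(n_bins)
    ]
    assignment = None
    if bgc_matrix is not None:
        D = cdist(bgc_matrix.values, km.cluster_centers_)
        nearest = D.argmin(axis=1)
        assignment = pd.DataFrame(
            {
                "bgc_id": bgc_matrix.bgc_ids,
                "bin_id": nearest,
                "distance": D[np.arange(len(nearest)), nearest],
            }
        )
        if bgc_datasets is not None:
            assignment["dataset"] = [bgc_datasets.get(b) for b in assignment["bgc_id"]]
            counts = assignment.groupby(["bin_id", "dataset"]).size()
            for (b, ds), n in counts.items():
                bins[b].bgc_counts_per_dataset[ds] = int(n)
    return bins, assignment


def _scipy_tree_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _scipy_tree_to_newick(node.left, labels)
    right = _scipy_tree_to_newick(node.right, labels)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.6f},{right}:{bl_right:.6f})"


def export_bin_phylogram(bins: Sequence[GcfBin]) -> str:
    """Average-linkage Euclidean dendrogram over bin centroids, Newick.

    An all-zero dummy vector is appended as an extra leaf before
    linkage; the tree is re-rooted on its attachment edge and the dummy
    leaf pruned, so the root sits where a feature-less BGC would attach.
    Leaf labels are ``bin<id>``.
    """
    if len(bins) < 2:
        raise ValueError("need at least 2 bins to build a phylogram")
    X = np.vstack([b.centroid for b in bins] + [np.zeros_like(bins[0].centroid)])
    labels = [f"bin{b.bin_id}" for b in bins] + [_ROOT_LABEL]
    Z = linkage(X, method="average", metric="euclidean")
    newick = _scipy_tree_to_newick(to_tree(Z), labels) + ";"

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    dummy = tree.find_node_with_taxon_label(_ROOT_LABEL)
    # Re-root on the dummy's attachment edge, then drop the dummy leaf.
    tree.reroot_at_edge(dummy.edge, update_bipartitions=False)
    tree.prune_taxa_with_labels([_ROOT_LABEL])
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def double_normalized_dataset_distribution(
    bins: Sequence[GcfBin],
) -> pd.DataFrame:
    """Per-bin dataset distributions, double-normalized.

    Raw per-bin BGC counts are first divided by each dataset's total BGC
    count (giving fractions comparable across datasets of different
    size), then re-normalized across datasets within each bin so rows
    sum to 1.  Suitable as a tree-annotation table.
    """
    totals: dict[str, int] = {}
    for b in bins:
        for ds, n in b.bgc_counts_per_dataset.items():
            totals[ds] = totals.get(ds, 0) + n
    datasets = sorted(totals)
    rows = []
    for b in bins:
        fracs = np.array(
            [b.bgc_counts_per_dataset.get(ds, 0) / totals[ds] for ds in datasets]
        )
        total = fracs.sum()
        rows.append(fracs / total if total > 0 else fracs)
    return pd.DataFrame(rows, index=[f"bin{b.bin_id}" for b in bins], columns=datasets)


def nearest_reference_distance(
    models: Sequence[GcfModel], references: FeatureMatrix, T: float
) -> pd.DataFrame:
    """Distance of every GCF centroid to its closest reference BGC.

    GCFs with d ≤ T are classified ``related`` (their chemistry is close
    to something already characterized), the rest ``distant`` — the
    "hidden iceberg" of potentially novel families.
    """
    if references.n == 0:
        raise ValueError("reference set is empty")
    C = np.vstack([m.centroid for m in models])
    if C.shape[1] != references.values.shape[1]:
        raise ValueError("GCF models and references have different column spaces")
    D = cdist(C, references.values)
    min_d = D.min(axis=1)
    nearest = D.argmin(axis=1)
    return pd.DataFrame(
        {
            "gcf_id": [m.gcf_id for m in models],
            "min_distance": min_d,
            "nearest_reference": [references.bgc_ids[j] for j in nearest],
            "class": np.where(min_d <= T, "related", "distant"),
        }
    )


SHAREDNESS_BINS = [(0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0)]


def gcf_richness(
    memberships: Sequence[Membership],
    bgc_genomes: Mapping[str, str],
    taxonomy: pd.DataFrame,
    min_genomes: int = 4,
) -> pd.DataFrame:
    """Per-species GCF richness and sharedness.

    Only species with ≥ ``min_genomes`` strain-level genomes are
    reported.  ``n_gcfs`` counts distinct GCFs with a rank-1 *core*
    assignment among the species' BGCs; the sharedness of a GCF is the
    fraction of the species' genomes carrying it, histogrammed in
    20%-wide bins (0,0.2] … (0.8,1.0].
    """
    if min_genomes < 1:
        raise ValueError("min_genomes must be >= 1")
    rows = []
    for mem in memberships:
        genome = bgc_genomes.get(mem.bgc_id)
        if genome is None:
            warnings.warn(f"{mem.bgc_id}: no genome mapping; excluded from richness")
            continue
        if genome not in taxonomy.index:
            warnings.warn(f"{genome}: no taxonomy; excluded from richness")
            continue
        rows.append(
            {
                "bgc_id": mem.bgc_id,
                "genome_id": genome,
                "species": taxonomy.loc[genome, "species"],
                "gcf_id": mem.best_gcf,
                "category": mem.category,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["species", "n_genomes", "n_gcfs"]
            + [f"shared_{int(lo*100)}_{int(hi*100)}" for lo, hi in SHAREDNESS_BINS]
        )

    out = []
    for species, sub in df.groupby("species"):
        genomes = set(sub["genome_id"])
        if len(genomes) < min_genomes:
            continue
        core = sub[sub["category"] == "core"]
        hist = {f"shared_{int(lo*100)}_{int(hi*100)}": 0 for lo, hi in SHAREDNESS_BINS}
        for gcf_id, gsub in core.groupby("gcf_id"):
            frac = len(set(gsub["genome_id"])) / len(genomes)
            for lo, hi in SHAREDNESS_BINS:
                if lo < frac <= hi:
                    hist[f"shared_{int(lo*100)}_{int(hi*100)}"] += 1
                    break
        out.append(
            {
                "species": species,
                "n_genomes": len(genomes),
                "n_gcfs": core["gcf_id"].nunique(),
                **hist,
            }
        )
    cols = ["species", "n_genomes", "n_gcfs"] + [
        f"shared_{int(lo*100)}_{int(hi*100)}" for lo, hi in SHAREDNESS_BINS
    ]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out)[cols].sort_values("species").reset_index(drop=True)
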