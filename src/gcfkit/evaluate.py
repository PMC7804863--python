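"""Score clustering results against reference groupings.

The V-score (V-measure) is the harmonic mean of *homogeneity* — do
members of one predicted cluster share the same reference group — and
*completeness* — does each reference group land in a single predicted
cluster.  Both are entropy ratios computed from the contingency table:

    h = 1 − H(ref | pred) / H(ref)      (1 when H(ref) = 0)
    c = 1 − H(pred | ref) / H(pred)     (1 when H(pred) = 0)
    v = 2hc / (h + c)                   (0 when h + c = 0)

Entropies are natural-log; any base cancels in the ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import build_gcf_models
from .features import FeatureMatrix


@dataclass(frozen=True)
class ClusteringScore:
    homogeneity: float
    completeness: float
    v_score: float
    delta_gcf: int  # predicted cluster count − reference group count


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_score(predicted: Mapping, reference: Mapping) -> ClusteringScore:
    """Entropy-based clustering agreement between two labelings.

    Both maps must share the same key set (item → label); labels are
    compared only through the partition they induce, so any relabeling
    of either side leaves the score unchanged.
    """
    if set(predicted) != set(reference):
        only_p = sorted(set(predicted) - set(reference))[:5]
        only_r = sorted(set(reference) - set(predicted))[:5]
        raise ValueError(
            f"predicted/reference key sets differ (only-predicted: {only_p}, "
            f"only-reference: {only_r})"
        )
    if not predicted:
        raise ValueError("cannot score an empty labeling")

    keys = sorted(predicted)
    _, pred = np.unique([str(predicted[k]) for k in keys], return_inverse=True)
    _, ref = np.unique([str(reference[k]) for k in keys], return_inverse=True)
    table = np.zeros((ref.max() + 1, pred.max() + 1))
    np.add.at(table, (ref, pred), 1.0)
    n = table.sum()

    h_ref = _entropy(table.sum(axis=1))
    h_pred = _entropy(table.sum(axis=0))
    # Conditional entropies from the joint table.
    h_ref_given_pred = 0.0
    for j in range(table.shape[1]):
        col = table[:, j]
        if col.sum() > 0:
            h_ref_given_pred += col.sum() / n * _entropy(col)
    h_pred_given_ref = 0.0
    for i in range(table.shape[0]):
        row = table[i]
        if row.sum() > 0:
            h_pred_given_ref += row.sum() / n * _entropy(row)

    h = 1.0 if h_ref == 0 else 1.0 - h_ref_given_pred / h_ref
    c = 1.0 if h_pred == 0 else 1.0 - h_pred_given_ref / h_pred
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return ClusteringScore(
        homogeneity=h,
        completeness=c,
        v_score=v,
        delta_gcf=len(set(predicted.values())) - len(set(reference.values())),
    )


def confusion_matrix(
    predicted: Mapping, reference: Mapping, collapse_singletons: bool = False
) -> pd.DataFrame:
    """Reference-group × predicted-cluster contingency table.

    With ``collapse_singletons`` every predicted cluster of size 1 is
    merged into a single ``singletons`` column — useful when many BGCs
    need a more lenient threshold to join their curated group.
    """
    if set(predicted) != set(reference):
        raise ValueError("predicted/reference key sets differ")
    keys = sorted(predicted)
    pred = [predicted[k] for k in keys]
    if collapse_singletons:
        sizes = pd.Series(pred).value_counts()
        singletons = set(sizes[sizes == 1].index)
        pred = ["singletons" if p in singletons else p for p in pred]
    ref = [reference[k] for k in keys]
    return pd.crosstab(
        pd.Series(ref, name="reference"), pd.Series(pred, name="predicted")
    )


def group_centroid_distances(
    matrix: FeatureMatrix, reference: Mapping
) -> pd.DataFrame:
    """BGC-to-group-centroid distance (radius) distributions.

    Each reference group's centroid is the mean feature vector of its
    members; every BGC is measured against every group centroid and the
    pair is tagged ``within`` or ``between``.  A bimodal separation of
    the two distributions indicates that the feature space carries the
    grouping signal.
    """
    groups = sorted(set(reference.values()))
    centroids = {}
    for g in groups:
        idx = [i for i, b in enumerate(matrix.bgc_ids) if reference[b] == g]
        centroids[g] = matrix.values[idx].mean(axis=0)
    rows = []
    for i, b in enumerate(matrix.bgc_ids):
        for g in groups:
            d = float(np.linalg.norm(matrix.values[i] - centroids[g]))
            rows.append(
                {
                    "bgc_id": b,
                    "group": g,
                    "distance": d,
                    "kind": "within" if reference[b] == g else "between",
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(
    matrix: FeatureMatrix, reference: Mapping, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Cluster at each threshold and score against the reference.

    Returns one row per threshold: T, number of GCFs, homogeneity,
    completeness, v_score and ΔGCF.  Thresholds must be ascending.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for T in thresholds:
        models = build_gcf_models(matrix, T)
        predicted = {
            b: m.gcf_id for m in models for b in m.member_bgc_ids
        }
        score = v_score(predicted, {b: reference[b] for b in predicted})
        rows.append(
            {
                "T": T,
                "n_gcf": len(models),
                "homogeneity": score.homogeneity,
                "completeness": score.completeness,
                "v_score": score.v_score,
                "delta_gcf": score.delta_gcf,
            }
        )
    return pd.DataFrame(rows)
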