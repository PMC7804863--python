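"""Gene-cluster-family construction: threshold calibration, flat-tree
BIRCH clustering, and fuzzy membership assignment.

The clustering threshold ``T`` is calibrated as the average Xth
percentile (default X = 1) of Euclidean pairwise distances within
randomly sampled batches of feature rows (default 100 batches of 1,000).
GCF models are then built by a single-level incremental (flat-tree
BIRCH) pass: each row joins the nearest existing subcluster provided the
subcluster's RMS radius after absorption stays within ``T``, otherwise
it seeds a new subcluster.  Centroids are member means; there is no
global refinement pass.  Finally every BGC is matched against all
centroids and its top-N nearest GCFs (default N = 3) are reported, with
the best-hit distance categorized as core (d ≤ T), putative
(T < d ≤ 2T) or orphan (d > 2T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .features import FeatureMatrix

DEFAULT_PERCENTILE = 1.0
DEFAULT_N_BATCHES = 100
DEFAULT_BATCH_SIZE = 1000
DEFAULT_N_RANKS = 3


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of the distance-sampling calibration."""

    T: float
    X: float = DEFAULT_PERCENTILE
    n_batches: int = DEFAULT_N_BATCHES
    batch_size: int = DEFAULT_BATCH_SIZE
    seed: int = 0


@dataclass
class GcfModel:
    """A GCF centroid model: mean feature vector of its members."""

    gcf_id: int
    centroid: np.ndarray
    n_members: int
    threshold_T: float
    member_bgc_ids: list[str] = field(default_factory=list)


@dataclass
class Membership:
    """Top-N GCF assignments of one BGC, ascending by distance."""

    bgc_id: str
    ranks: list[tuple[int, float]]  # (gcf_id, euclidean distance)
    category: str  # core | putative | orphan

    @property
    def best_gcf(self) -> int:
        return self.ranks[0][0]

    @property
    def best_distance(self) -> float:
        return self.ranks[0][1]


def calibrate_threshold(
    matrix: FeatureMatrix,
    X: float = DEFAULT_PERCENTILE,
    n_batches: int = DEFAULT_N_BATCHES,
    batch_size: int = DEFAULT_BATCH_SIZE,
    seed: int = 0,
) -> ThresholdCalibration:
    """Calibrate T from within-batch pairwise-distance percentiles.

    Each batch samples ``batch_size`` distinct rows (the whole matrix
    when it is smaller); the Xth percentile of all pairwise Euclidean
    distances in the batch is recorded and T is the mean over batches.
    Batches are drawn independently, so rows may recur across batches.
    """
    if not 0 < X <= 100:
        raise ValueError(f"percentile X must be in (0, 100], got {X}")
    n = matrix.n
    if n < 2:
        raise ValueError("cannot calibrate a distance threshold from a single feature")
    rng = np.random.default_rng(seed)
    take = min(batch_size, n)
    percentiles = np.empty(n_batches)
    for b in range(n_batches):
        idx = rng.choice(n, size=take, replace=False)
        d = pdist(matrix.values[idx])
        percentiles[b] = np.percentile(d, X)
    return ThresholdCalibration(
        T=float(percentiles.mean()), X=X, n_batches=n_batches,
        batch_size=batch_size, seed=seed,
    )


def build_gcf_models(matrix: FeatureMatrix, T: float) -> list[GcfModel]:
    """Single-level incremental clustering of feature rows at threshold T.

    Rows are scanned in matrix order (sorted by bgc_id upstream).  Each
    row is absorbed into the nearest subcluster by centroid distance if
    the subcluster's RMS radius after absorption — the root-mean-square
    distance of members to the updated mean — would not exceed T;
    otherwise it opens a new subcluster.  This is the admission rule of
    BIRCH clustering features (N, linear sum, squared sum) with a flat
    tree (branching factor ≥ n_samples), searched exhaustively.
    """
    if T < 0:
        raise ValueError(f"threshold T must be >= 0, got {T}")
    if matrix.n == 0:
        raise ValueError("no training BGCs (did completeness filtering remove everything?)")

    X = matrix.values
    zero_rows = [matrix.bgc_ids[i] for i in np.flatnonzero(~X.any(axis=1))]
    if zero_rows:
        warnings.warn(
            f"{len(zero_rows)} BGC(s) have all-zero feature vectors and will "
            f"co-locate in one low-information GCF: {zero_rows[:5]}..."
        )

    n_feat = X.shape[1]
    # Clustering features, preallocated and grown on demand.
    cap = 64
    counts = np.zeros(cap, dtype=np.int64)
    lsum = np.zeros((cap, n_feat))          # linear sums
    sqsum = np.zeros(cap)                   # total squared norms
    centroids = np.zeros((cap, n_feat))
    members: list[list[str]] = []
    k = 0

    for i in range(matrix.n):
        x = X[i]
        x_sq = float(x @ x)
        if k > 0:
            d = np.linalg.norm(centroids[:k] - x, axis=1)
            j = int(np.argmin(d))
            new_n = counts[j] + 1
            new_ls = lsum[j] + x
            new_ss = sqsum[j] + x_sq
            new_centroid = new_ls / new_n
            # RMS radius after absorption: sqrt(SS/n − ‖mean‖²).
            sq_radius = new_ss / new_n - float(new_centroid @ new_centroid)
            if np.sqrt(max(sq_radius, 0.0)) <= T:
                counts[j] = new_n
                lsum[j] = new_ls
                sqsum[j] = new_ss
                centroids[j] = new_centroid
                members[j].append(matrix.bgc_ids[i])
                continue
        if k == cap:
            cap *= 2
            counts = np.resize(counts, cap)
            counts[k:] = 0
            lsum = np.vstack([lsum, np.zeros((cap - k, n_feat))])
            sqsum = np.resize(sqsum, cap)
            sqsum[k:] = 0
            centroids = np.vstack([centroids, np.zeros((cap - k, n_feat))])
        counts[k] = 1
        lsum[k] = x
        sqsum[k] = x_sq
        centroids[k] = x
        members.append([matrix.bgc_ids[i]])
        k += 1

    return [
        GcfModel(
            gcf_id=j,
            centroid=centroids[j].copy(),
            n_members=int(counts[j]),
            threshold_T=T,
            member_bgc_ids=members[j],
        )
        for j in range(k)
    ]


def centroid_matrix(models: Sequence[GcfModel]) -> np.ndarray:
    return np.vstack([m.centroid for m in models])


def categorize(d1: float, T: float) -> str:
    """Best-hit membership category: core (d ≤ T), putative
    (T < d ≤ 2T), orphan (d > 2T); boundaries inclusive as written."""
    if d1 < 0 or T < 0:
        raise ValueError("distances must be non-negative")
    if d1 <= T:
        return "core"
    if d1 <= 2 * T:
        return "putative"
    return "orphan"


def assign_membership(
    matrix: FeatureMatrix,
    models: Sequence[GcfModel],
    N: int = DEFAULT_N_RANKS,
    T: float | None = None,
) -> list[Membership]:
    """Match every BGC with its top-N nearest GCF centroids.

    Distances are Euclidean on the raw feature values.  The membership
    category is derived from the rank-1 distance and the models' build
    threshold (or an explicit ``T``).
    """
    if not models:
        raise ValueError("no GCF models to assign against")
    if matrix.values.shape[1] != models[0].centroid.shape[0]:
        raise ValueError(
            f"feature columns ({matrix.values.shape[1]}) do not match model "
            f"columns ({models[0].centroid.shape[0]})"
        )
    if T is None:
        T = models[0].threshold_T
    C = centroid_matrix(models)
    gcf_ids = np.array([m.gcf_id for m in models])
    D = cdist(matrix.values, C)
    keep = min(N, len(models))
    out: list[Membership] = []
    for i, bgc_id in enumerate(matrix.bgc_ids):
        order = np.lexsort((gcf_ids, D[i]))[:keep]
        ranks = [(int(gcf_ids[j]), float(D[i, j])) for j in order]
        out.append(Membership(bgc_id, ranks, categorize(ranks[0][1], T)))
    return out
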