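"""Convert domain hits into the fixed-order BGC feature matrix.

Each BGC becomes one row over a fixed global column order (biosynthetic
models first, then sub-Pfam models, each block lexicographic):

* a biosynthetic/core column is 255 when the model hits anywhere in the
  BGC and 0 otherwise — Boolean presence, no copy-number effect;
* a sub-Pfam column carries a ranked fingerprint value: for every
  core-domain instance its sub-Pfam hits are sorted by descending
  bitscore, the top K (default 3) get ``round(255·(K−r+1)/K)`` for rank
  ``r``, and multiple instances in one BGC combine by column-wise max.
  With K=3 the attainable values are exactly {0, 85, 170, 255}.

The representation is order-free: permuting a BGC's genes leaves its
vector unchanged.  Values are raw integers in [0, 255]; no scaling is
applied before distance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DomainHit

DEFAULT_TOP_K = 3


@dataclass
class FeatureVector:
    """Sparse per-BGC feature map (column name → value in [0, 255])."""

    bgc_id: str
    values: dict[str, int] = field(default_factory=dict)

    def merge_max(self, other: Mapping[str, int]) -> None:
        for col, val in other.items():
            if val > self.values.get(col, 0):
                self.values[col] = val


@dataclass
class FeatureMatrix:
    """Dense matrix of BGC feature vectors with a fixed column order."""

    bgc_ids: list[str]
    columns: list[str]
    values: np.ndarray  # shape (n_bgcs, n_columns), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.bgc_ids), len(self.columns)):
            raise ValueError("matrix shape does not match ids/columns")

    @property
    def n(self) -> int:
        return len(self.bgc_ids)

    def row(self, bgc_id: str) -> np.ndarray:
        return self.values[self.bgc_ids.index(bgc_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bgc_ids, columns=self.columns)

    def subset(self, bgc_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.bgc_ids.index(b) for b in bgc_ids]
        return FeatureMatrix(list(bgc_ids), self.columns, self.values[idx])


def ranked_value(rank: int, top_k: int) -> int:
    """Feature value for a 1-based bitscore rank under a top-K scheme."""
    return round(255 * (top_k - rank + 1) / top_k)


def extract_biosynthetic_features(hits: Iterable[DomainHit]) -> dict[str, int]:
    """Boolean presence features: 255 iff ≥1 hit to the model."""
    return {h.model_name: 255 for h in hits if h.parent_hit is None}


def group_subpfam_hits(subpfam_hits: Iterable[DomainHit]) -> list[list[DomainHit]]:
    """Group sub-Pfam hits by their originating core-domain instance."""
    groups: dict[tuple, list[DomainHit]] = {}
    for h in subpfam_hits:
        if h.parent_hit is None:
            raise ValueError(f"sub-Pfam hit without parent core instance: {h.model_name}")
        p = h.parent_hit
        key = (p.cds_id, p.model_name, p.start_aa, p.end_aa)
        groups.setdefault(key, []).append(h)
    return [groups[k] for k in sorted(groups)]


def extract_subpfam_features(
    grouped_hits: Sequence[Sequence[DomainHit]], top_k: int = DEFAULT_TOP_K
) -> dict[str, int]:
    """Ranked fingerprint features from per-core-instance hit lists.

    Within each instance, hits are sorted by descending bitscore (ties
    broken by model name for determinism), the first ``top_k`` get
    descending values, and instances combine by column-wise maximum.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    out: dict[str, int] = {}
    for instance_hits in grouped_hits:
        ranked = sorted(instance_hits, key=lambda h: (-h.bitscore, h.model_name))
        for r, hit in enumerate(ranked[:top_k], start=1):
            val = ranked_value(r, top_k)
            if val > out.get(hit.model_name, 0):
                out[hit.model_name] = val
    return out


def featurize_bgc(
    bgc_id: str,
    biosyn_hits: Iterable[DomainHit],
    subpfam_hits: Iterable[DomainHit],
    top_k: int = DEFAULT_TOP_K,
) -> FeatureVector:
    """Combine both feature sets for one BGC."""
    vec = FeatureVector(bgc_id)
    vec.merge_max(extract_biosynthetic_features(biosyn_hits))
    vec.merge_max(extract_subpfam_features(group_subpfam_hits(subpfam_hits), top_k))
    return vec


def assemble_matrix(
    vectors: Sequence[FeatureVector], column_order: Sequence[str]
) -> FeatureMatrix:
    """Stack sparse vectors into a dense matrix with stable ordering.

    Rows are sorted by bgc_id; a vector column absent from
    ``column_order`` signals a library/model-store mismatch and raises.
    """
    columns = list(column_order)
    col_idx = {c: i for i, c in enumerate(columns)}
    vectors = sorted(vectors, key=lambda v: v.bgc_id)
    mat = np.zeros((len(vectors), len(columns)))
    for i, vec in enumerate(vectors):
        for col, val in vec.values.items():
            if col not in col_idx:
                raise KeyError(
                    f"{vec.bgc_id}: column {col!r} not in the model store's column order"
                )
            mat[i, col_idx[col]] = val
    return FeatureMatrix([v.bgc_id for v in vectors], columns, mat)


def project_onto(
    vectors: Sequence[FeatureVector], column_order: Sequence[str]
) -> FeatureMatrix:
    """Project query-time vectors onto a stored column order.

    Columns unseen by the store are dropped with a warning (the query
    library may be newer than the one the models were built with).
    """
    known = set(column_order)
    projected = []
    for vec in vectors:
        unknown = set(vec.values) - known
        if unknown:
            warnings.warn(
                f"{vec.bgc_id}: dropping {len(unknown)} feature column(s) unknown "
                f"to the model store: {sorted(unknown)[:5]}..."
            )
        projected.append(
            FeatureVector(vec.bgc_id, {c: v for c, v in vec.values.items() if c in known})
        )
    return assemble_matrix(projected, column_order)
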