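"""End-to-end orchestration: GenBank → scan → features → GCFs → store.

Two entry points mirror how the tool is used: :func:`run_clustering`
trains GCF models from a directory (or directories) of region GenBank
files and persists everything into one SQLite database, which then acts
as the model store; :func:`query_bgcs` featurizes new BGCs with the
same library, projects them onto the stored column order and matches
them against the stored centroids.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import store as db
from .cluster import (
    DEFAULT_N_RANKS,
    DEFAULT_PERCENTILE,
    GcfModel,
    Membership,
    assign_membership,
    build_gcf_models,
    calibrate_threshold,
)
from .features import (
    DEFAULT_TOP_K,
    FeatureMatrix,
    FeatureVector,
    assemble_matrix,
    featurize_bgc,
    project_onto,
)
from .genbank import attach_taxonomy, filter_complete, load_taxonomy, parse_dataset_dir
from .hmm import HmmLibrary, load_model_list, scan_biosynthetic, scan_subpfam
from .records import BgcRecord, DomainHit


@dataclass
class ClusteringResult:
    db_path: Path
    run_id: int
    T: float
    models: list[GcfModel]
    memberships: list[Membership]
    matrix: FeatureMatrix  # all input BGCs (training + fragments)


def extract_features(
    bgcs: Sequence[BgcRecord], library: HmmLibrary, top_k: int = DEFAULT_TOP_K
) -> tuple[list[FeatureVector], list[DomainHit], list[DomainHit]]:
    """Scan all CDSs of a BGC collection and build one vector per BGC."""
    all_cds = [c for b in bgcs for c in b.cds]
    biosyn_hits = scan_biosynthetic(all_cds, library)
    subpfam_hits = scan_subpfam(biosyn_hits, all_cds, library)
    by_bgc: dict[str, list[DomainHit]] = defaultdict(list)
    sub_by_bgc: dict[str, list[DomainHit]] = defaultdict(list)
    for h in biosyn_hits:
        by_bgc[h.bgc_id].append(h)
    for h in subpfam_hits:
        sub_by_bgc[h.bgc_id].append(h)
    vectors = [
        featurize_bgc(b.bgc_id, by_bgc[b.bgc_id], sub_by_bgc[b.bgc_id], top_k)
        for b in bgcs
    ]
    return vectors, biosyn_hits, subpfam_hits


def run_clustering(
    bgc_dirs: Sequence[str | Path],
    model_list: str | Path,
    hmm_dir: str | Path,
    db_path: str | Path,
    complete_only: bool = True,
    threshold: float | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    top_k: int = DEFAULT_TOP_K,
    n_ranks: int = DEFAULT_N_RANKS,
    taxonomy_path: str | Path | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """Full training run: parse, scan, featurize, calibrate, cluster.

    With ``complete_only`` (the default) GCF models are built from
    non-fragmented BGCs only, then *all* input BGCs — fragments
    included — are matched back against the models.  ``threshold``
    skips calibration when given.
    """
    library = load_model_list(model_list, hmm_dir)
    bgcs: list[BgcRecord] = []
    for d in bgc_dirs:
        bgcs.extend(parse_dataset_dir(d))
    bgcs.sort(key=lambda b: b.bgc_id)
    if not bgcs:
        raise ValueError("no BGCs parsed from input directories")
    if taxonomy_path is not None:
        attach_taxonomy(bgcs, load_taxonomy(taxonomy_path))

    vectors, biosyn_hits, subpfam_hits = extract_features(bgcs, library, top_k)
    columns = library.feature_columns()
    matrix = assemble_matrix(vectors, columns)

    training = filter_complete(bgcs) if complete_only else bgcs
    if not training:
        raise ValueError("no training BGCs left after completeness filtering")
    train_matrix = matrix.subset(sorted(b.bgc_id for b in training))

    if threshold is None:
        threshold = calibrate_threshold(
            train_matrix, X=percentile, seed=seed
        ).T
    models = build_gcf_models(train_matrix, threshold)
    memberships = assign_membership(matrix, models, N=n_ranks, T=threshold)

    conn = db.create_schema(db_path)
    try:
        db.store_library(conn, library)
        db.store_bgcs(conn, bgcs)
        if taxonomy_path is not None:
            db.store_taxonomy(conn, load_taxonomy(taxonomy_path))
        db.store_hits(conn, biosyn_hits, subpfam_hits)
        db.store_features(conn, vectors)
        run_id = db.store_run(
            conn,
            "cluster",
            {
                "threshold_T": threshold,
                "percentile_X": percentile,
                "top_k": top_k,
                "n_ranks": n_ranks,
                "complete_only": complete_only,
                "seed": seed,
            },
            library_checksum=library.checksum(),
            manifest={"bgc_dirs": [str(d) for d in bgc_dirs], "n_bgcs": len(bgcs)},
        )
        db.store_gcf_models(conn, run_id, models, columns)
        db.store_memberships(conn, run_id, memberships)
    finally:
        conn.close()

    return ClusteringResult(
        db_path=Path(db_path),
        run_id=run_id,
        T=threshold,
        models=models,
        memberships=memberships,
        matrix=matrix,
    )


@dataclass
class QueryResult:
    run_id: int
    memberships: list[Membership]
    table: pd.DataFrame


def query_bgcs(
    paths: Sequence[str | Path],
    db_path: str | Path,
    model_list: str | Path,
    hmm_dir: str | Path,
    n_ranks: int = DEFAULT_N_RANKS,
    run_id: int | None = None,
) -> QueryResult:
    """Match new BGCs against a stored model run.

    The supplied library must be the one the store was built with
    (checked by checksum); query vectors are projected onto the stored
    column order, assigned top-N memberships and persisted as a query
    run.  ``paths`` may mix GenBank files and directories.
    """
    from .genbank import parse_region_genbank

    library = load_model_list(model_list, hmm_dir)
    conn = db.create_schema(db_path)
    try:
        if run_id is None:
            run_id = db.latest_run(conn, "cluster")
        stored_checksum = conn.execute(
            "SELECT library_checksum FROM run WHERE run_id=?", (run_id,)
        ).fetchone()[0]
        if stored_checksum and stored_checksum != library.checksum():
            raise ValueError(
                "supplied HMM library does not match the one the model store "
                "was built with (checksum mismatch)"
            )
        models = db.load_gcf_models(conn, run_id)
        columns = db.load_column_order(conn)
        T = models[0].threshold_T

        bgcs: list[BgcRecord] = []
        for p in paths:
            p = Path(p)
            if p.is_dir():
                bgcs.extend(parse_dataset_dir(p, dataset="query"))
            else:
                bgcs.extend(parse_region_genbank(p, dataset="query"))
        bgcs.sort(key=lambda b: b.bgc_id)
        if not bgcs:
            raise ValueError("no BGCs parsed from query input")

        vectors, _, _ = extract_features(bgcs, library)
        matrix = project_onto(vectors, columns)
        memberships = assign_membership(matrix, models, N=n_ranks, T=T)

        query_run = db.store_run(
            conn,
            "query",
            {"threshold_T": T, "n_ranks": n_ranks},
            library_checksum=library.checksum(),
            manifest={"paths": [str(p) for p in paths], "model_run": run_id},
        )
        db.store_bgcs(conn, bgcs)
        db.store_features(conn, vectors)
        db.store_memberships(conn, query_run, memberships)
    finally:
        conn.close()

    table = pd.DataFrame(
        [
            {
                "bgc_id": m.bgc_id,
                "rank": r,
                "gcf_id": gcf_id,
                "distance": d,
                "category": m.category,
            }
            for m in memberships
            for r, (gcf_id, d) in enumerate(m.ranks, start=1)
        ]
    )
    return QueryResult(run_id=query_run, memberships=memberships, table=table)
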