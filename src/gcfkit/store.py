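"""Single-file SQLite persistence for the whole pipeline.

Everything a run produces — BGCs, CDSs, domain hits, sparse feature
vectors, GCF centroid models, memberships, taxonomy and run metadata —
lives in one SQLite database with foreign keys enforced.  Feature
vectors and centroids are stored sparsely (bgc/gcf, column, value) so
cross-cutting SQL analytics (e.g. "all CDSs with ≥1 hit to model X in
genus Y") work directly on the tables.  The database doubles as the
model store for query mode: column order, threshold and centroids are
all recoverable from it.
"""

from __future__ import annotations

import json
import sqlite3
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import GcfModel, Membership
from .features import FeatureVector
from .hmm import HmmLibrary
from .records import TAXONOMY_RANKS, BgcRecord, DomainHit

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS schema_meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS dataset (name TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS genome (
    genome_id TEXT PRIMARY KEY,
    dataset_name TEXT NOT NULL REFERENCES dataset(name)
);
CREATE TABLE IF NOT EXISTS taxonomy (
    genome_id TEXT PRIMARY KEY REFERENCES genome(genome_id),
    kingdom TEXT, phylum TEXT, class TEXT, "order" TEXT,
    family TEXT, genus TEXT, species TEXT
);
CREATE TABLE IF NOT EXISTS bgc (
    bgc_id TEXT PRIMARY KEY,
    dataset_name TEXT NOT NULL REFERENCES dataset(name),
    genome_id TEXT NOT NULL REFERENCES genome(genome_id),
    source_path TEXT NOT NULL,
    length_nt INTEGER NOT NULL CHECK (length_nt > 0),
    on_contig_edge INTEGER,            -- 1/0/NULL (unknown)
    class_labels TEXT NOT NULL         -- ';'-joined product strings
);
CREATE TABLE IF NOT EXISTS cds (
    cds_id TEXT PRIMARY KEY,
    bgc_id TEXT NOT NULL REFERENCES bgc(bgc_id),
    start_nt INTEGER NOT NULL,
    end_nt INTEGER NOT NULL,
    strand TEXT NOT NULL CHECK (strand IN ('+', '-')),
    aa_sequence TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS hmm_model (
    model_name TEXT PRIMARY KEY,
    category TEXT NOT NULL CHECK (category IN ('biosynthetic', 'core', 'subpfam')),
    parent_core TEXT REFERENCES hmm_model(model_name),
    gathering_cutoff REAL
);
CREATE TABLE IF NOT EXISTS domain_hit (
    hit_id INTEGER PRIMARY KEY,
    cds_id TEXT NOT NULL REFERENCES cds(cds_id),
    bgc_id TEXT NOT NULL REFERENCES bgc(bgc_id),
    model_name TEXT NOT NULL REFERENCES hmm_model(model_name),
    bitscore REAL NOT NULL,
    start_aa INTEGER NOT NULL,
    end_aa INTEGER NOT NULL,
    parent_hit_id INTEGER REFERENCES domain_hit(hit_id)
);
CREATE INDEX IF NOT EXISTS idx_hit_model ON domain_hit(model_name);
CREATE INDEX IF NOT EXISTS idx_hit_parent ON domain_hit(parent_hit_id);
CREATE TABLE IF NOT EXISTS feature (
    bgc_id TEXT NOT NULL REFERENCES bgc(bgc_id),
    column_name TEXT NOT NULL REFERENCES hmm_model(model_name),
    value INTEGER NOT NULL CHECK (value BETWEEN 0 AND 255),
    PRIMARY KEY (bgc_id, column_name)
);
CREATE TABLE IF NOT EXISTS column_order (
    position INTEGER PRIMARY KEY,
    column_name TEXT NOT NULL UNIQUE REFERENCES hmm_model(model_name)
);
CREATE TABLE IF NOT EXISTS run (
    run_id INTEGER PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('cluster', 'query')),
    created_at REAL NOT NULL,
    threshold_T REAL,
    percentile_X REAL,
    top_k INTEGER,
    n_ranks INTEGER,
    complete_only INTEGER,
    seed INTEGER,
    library_checksum TEXT,
    manifest TEXT
);
CREATE TABLE IF NOT EXISTS gcf (
    run_id INTEGER NOT NULL REFERENCES run(run_id),
    gcf_id INTEGER NOT NULL,
    n_members INTEGER NOT NULL CHECK (n_members >= 1),
    threshold_T REAL NOT NULL,
    PRIMARY KEY (run_id, gcf_id)
);
CREATE TABLE IF NOT EXISTS gcf_feature (
    run_id INTEGER NOT NULL,
    gcf_id INTEGER NOT NULL,
    column_name TEXT NOT NULL REFERENCES hmm_model(model_name),
    value REAL NOT NULL,
    PRIMARY KEY (run_id, gcf_id, column_name),
    FOREIGN KEY (run_id, gcf_id) REFERENCES gcf(run_id, gcf_id)
);
CREATE TABLE IF NOT EXISTS gcf_membership (
    run_id INTEGER NOT NULL REFERENCES run(run_id),
    bgc_id TEXT NOT NULL,
    rank INTEGER NOT NULL CHECK (rank >= 1),
    gcf_id INTEGER NOT NULL,
    distance REAL NOT NULL,
    category TEXT NOT NULL CHECK (category IN ('core', 'putative', 'orphan')),
    PRIMARY KEY (run_id, bgc_id, rank)
);
"""


class SchemaVersionError(RuntimeError):
    pass


def connect(db_path: str | Path) -> sqlite3.Connection:
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def create_schema(db_path: str | Path) -> sqlite3.Connection:
    """Initialize (or re-open) the database; idempotent.

    Raises :class:`SchemaVersionError` when the file already holds an
    incompatible schema version.
    """
    conn = connect(db_path)
    existing = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' AND name='schema_meta'"
    ).fetchone()
    if existing:
        row = conn.execute(
            "SELECT value FROM schema_meta WHERE key='version'"
        ).fetchone()
        if row is None or row[0] != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{db_path}: schema version {row[0] if row else None!r} != {SCHEMA_VERSION!r}"
            )
    conn.executescript(_SCHEMA)
    conn.execute(
        "INSERT OR IGNORE INTO schema_meta (key, value) VALUES ('version', ?)",
        (SCHEMA_VERSION,),
    )
    conn.commit()
    return conn


# ---------------------------------------------------------------------------
# Writers


def store_library(conn: sqlite3.Connection, library: HmmLibrary) -> None:
    rows = [
        (e.model_name, e.category, e.parent_core, e.gathering_cutoff)
        for e in sorted(library.entries, key=lambda e: (e.category != "core", e.model_name))
    ]
    conn.executemany(
        "INSERT OR REPLACE INTO hmm_model VALUES (?,?,?,?)", rows
    )
    conn.execute("DELETE FROM column_order")
    conn.executemany(
        "INSERT INTO column_order VALUES (?,?)",
        list(enumerate(library.feature_columns())),
    )
    conn.commit()


def store_bgcs(conn: sqlite3.Connection, records: Sequence[BgcRecord]) -> None:
    for r in records:
        conn.execute("INSERT OR IGNORE INTO dataset VALUES (?)", (r.dataset,))
        conn.execute(
            "INSERT OR IGNORE INTO genome VALUES (?,?)", (r.genome_id, r.dataset)
        )
        edge = None if r.on_contig_edge is None else int(r.on_contig_edge)
        conn.execute(
            "INSERT OR REPLACE INTO bgc VALUES (?,?,?,?,?,?,?)",
            (
                r.bgc_id,
                r.dataset,
                r.genome_id,
                r.source_path,
                r.length_nt,
                edge,
                ";".join(sorted(r.class_labels)),
            ),
        )
        conn.executemany(
            "INSERT OR REPLACE INTO cds VALUES (?,?,?,?,?,?)",
            [
                (c.cds_id, c.bgc_id, c.start_nt, c.end_nt, c.strand, c.aa_sequence)
                for c in r.cds
            ],
        )
        if r.taxonomy:
            conn.execute(
                "INSERT OR REPLACE INTO taxonomy VALUES (?,?,?,?,?,?,?,?)",
                (r.genome_id, *[r.taxonomy.get(k) for k in TAXONOMY_RANKS]),
            )
    conn.commit()


def store_taxonomy(conn: sqlite3.Connection, taxonomy: pd.DataFrame) -> None:
    """Store a genome→lineage table (index genome_id, 7 rank columns)."""
    for genome_id, row in taxonomy.iterrows():
        conn.execute(
            "INSERT OR REPLACE INTO taxonomy VALUES (?,?,?,?,?,?,?,?)",
            (genome_id, *[row[k] for k in TAXONOMY_RANKS]),
        )
    conn.commit()


def store_hits(
    conn: sqlite3.Connection,
    biosyn_hits: Sequence[DomainHit],
    subpfam_hits: Sequence[DomainHit] = (),
) -> None:
    """Persist domain hits; sub-Pfam hits keep their link to the core
    instance via ``parent_hit_id``."""
    hit_ids: dict[int, int] = {}
    for h in biosyn_hits:
        cur = conn.execute(
            "INSERT INTO domain_hit (cds_id, bgc_id, model_name, bitscore, start_aa, end_aa, parent_hit_id)"
            " VALUES (?,?,?,?,?,?,NULL)",
            (h.cds_id, h.bgc_id, h.model_name, h.bitscore, h.start_aa, h.end_aa),
        )
        hit_ids[id(h)] = cur.lastrowid
    for h in subpfam_hits:
        parent_id = hit_ids.get(id(h.parent_hit))
        conn.execute(
            "INSERT INTO domain_hit (cds_id, bgc_id, model_name, bitscore, start_aa, end_aa, parent_hit_id)"
            " VALUES (?,?,?,?,?,?,?)",
            (h.cds_id, h.bgc_id, h.model_name, h.bitscore, h.start_aa, h.end_aa, parent_id),
        )
    conn.commit()


def store_features(conn: sqlite3.Connection, vectors: Sequence[FeatureVector]) -> None:
    rows = [
        (v.bgc_id, col, int(val))
        for v in vectors
        for col, val in sorted(v.values.items())
        if val
    ]
    conn.executemany("INSERT OR REPLACE INTO feature VALUES (?,?,?)", rows)
    conn.commit()


def store_run(
    conn: sqlite3.Connection,
    kind: str,
    parameters: Mapping,
    library_checksum: str | None = None,
    manifest: Mapping | None = None,
) -> int:
    cur = conn.execute(
        "INSERT INTO run (kind, created_at, threshold_T, percentile_X, top_k,"
        " n_ranks, complete_only, seed, library_checksum, manifest)"
        " VALUES (?,?,?,?,?,?,?,?,?,?)",
        (
            kind,
            time.time(),
            parameters.get("threshold_T"),
            parameters.get("percentile_X"),
            parameters.get("top_k"),
            parameters.get("n_ranks"),
            int(bool(parameters.get("complete_only", False))),
            parameters.get("seed"),
            library_checksum,
            json.dumps(manifest or {}, sort_keys=True),
        ),
    )
    conn.commit()
    return cur.lastrowid


def store_gcf_models(
    conn: sqlite3.Connection, run_id: int, models: Sequence[GcfModel], columns: Sequence[str]
) -> None:
    for m in models:
        conn.execute(
            "INSERT INTO gcf VALUES (?,?,?,?)",
            (run_id, m.gcf_id, m.n_members, m.threshold_T),
        )
        nz = np.flatnonzero(m.centroid)
        conn.executemany(
            "INSERT INTO gcf_feature VALUES (?,?,?,?)",
            [(run_id, m.gcf_id, columns[j], float(m.centroid[j])) for j in nz],
        )
    conn.commit()


def store_memberships(
    conn: sqlite3.Connection, run_id: int, memberships: Sequence[Membership]
) -> None:
    rows = [
        (run_id, mem.bgc_id, rank, gcf_id, d, mem.category)
        for mem in memberships
        for rank, (gcf_id, d) in enumerate(mem.ranks, start=1)
    ]
    conn.executemany("INSERT INTO gcf_membership VALUES (?,?,?,?,?,?)", rows)
    conn.commit()


# ---------------------------------------------------------------------------
# Readers


def load_column_order(conn: sqlite3.Connection) -> list[str]:
    rows = conn.execute(
        "SELECT column_name FROM column_order ORDER BY position"
    ).fetchall()
    return [r[0] for r in rows]


def load_gcf_models(conn: sqlite3.Connection, run_id: int) -> list[GcfModel]:
    columns = load_column_order(conn)
    col_idx = {c: i for i, c in enumerate(columns)}
    gcfs = conn.execute(
        "SELECT gcf_id, n_members, threshold_T FROM gcf WHERE run_id=? ORDER BY gcf_id",
        (run_id,),
    ).fetchall()
    if not gcfs:
        raise ValueError(f"run {run_id}: no GCF models stored")
    models = []
    for gcf_id, n_members, T in gcfs:
        centroid = np.zeros(len(columns))
        for col, val in conn.execute(
            "SELECT column_name, value FROM gcf_feature WHERE run_id=? AND gcf_id=?",
            (run_id, gcf_id),
        ):
            centroid[col_idx[col]] = val
        models.append(GcfModel(gcf_id, centroid, n_members, T))
    return models


def load_memberships(conn: sqlite3.Connection, run_id: int) -> pd.DataFrame:
    return pd.read_sql_query(
        "SELECT bgc_id, rank, gcf_id, distance, category FROM gcf_membership"
        " WHERE run_id=? ORDER BY bgc_id, rank",
        conn,
        params=(run_id,),
    )


def latest_run(conn: sqlite3.Connection, kind: str = "cluster") -> int:
    row = conn.execute(
        "SELECT MAX(run_id) FROM run WHERE kind=?", (kind,)
    ).fetchone()
    if row[0] is None:
        raise ValueError(f"no run of kind {kind!r} in database")
    return int(row[0])


def load_feature_matrix(conn: sqlite3.Connection):
    """Rebuild the training FeatureMatrix from the sparse feature table."""
    from .features import FeatureMatrix

    columns = load_column_order(conn)
    col_idx = {c: i for i, c in enumerate(columns)}
    bgc_ids = [r[0] for r in conn.execute("SELECT bgc_id FROM bgc ORDER BY bgc_id")]
    row_idx = {b: i for i, b in enumerate(bgc_ids)}
    mat = np.zeros((len(bgc_ids), len(columns)))
    for bgc_id, col, val in conn.execute("SELECT bgc_id, column_name, value FROM feature"):
        mat[row_idx[bgc_id], col_idx[col]] = val
    return FeatureMatrix(bgc_ids, columns, mat)


# ---------------------------------------------------------------------------
# Cross-cutting analytics


def query_cds_by_domain_and_taxon(
    conn: sqlite3.Connection,
    domain_name: str,
    min_hits: int = 1,
    taxon: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Protein sequences with ≥ ``min_hits`` hits to a domain, optionally
    restricted to genomes of one taxon (``(rank, name)``).

    Mirrors the kind of SQL analytics the sparse schema is for, e.g.
    "all ketosynthase-carrying proteins from one genus".
    """
    sql = (
        "SELECT c.cds_id, c.bgc_id, b.genome_id, c.aa_sequence, COUNT(h.hit_id) AS n_hits"
        " FROM cds c JOIN bgc b ON b.bgc_id = c.bgc_id"
        " JOIN domain_hit h ON h.cds_id = c.cds_id AND h.model_name = ?"
    )
    params: list = [domain_name]
    if taxon is not None:
        rank, name = taxon
        if rank not in TAXONOMY_RANKS:
            raise ValueError(f"unknown taxonomic rank {rank!r}; expected one of {TAXONOMY_RANKS}")
        if conn.execute("SELECT COUNT(*) FROM taxonomy").fetchone()[0] == 0:
            warnings.warn("taxon filter requested but no taxonomy loaded; empty result")
            return pd.DataFrame(columns=["cds_id", "bgc_id", "genome_id", "aa_sequence", "n_hits"])
        col = '"order"' if rank == "order" else rank
        sql += f" JOIN taxonomy t ON t.genome_id = b.genome_id AND t.{col} = ?"
        params.append(name)
    sql += " GROUP BY c.cds_id HAVING COUNT(h.hit_id) >= ? ORDER BY c.cds_id"
    params.append(int(min_hits))
    return pd.read_sql_query(sql, conn, params=params)


def subpfam_diversity_report(
    conn: sqlite3.Connection, core_domain: str, group_by: str = "dataset"
) -> pd.DataFrame:
    """Distribution of rank-1 sub-Pfam clades of one core domain.

    For every core-domain hit instance, its best-bitscore sub-Pfam hit
    (ties broken by model name) counts one observation for that clade;
    proportions are reported per group (``dataset`` or ``phylum``) and
    sum to 1 within each group.  Groups with zero core hits are omitted.
    """
    row = conn.execute(
        "SELECT category FROM hmm_model WHERE model_name=?", (core_domain,)
    ).fetchone()
    if row is None or row[0] != "core":
        raise ValueError(f"{core_domain!r} is not a known core model")
    if group_by == "dataset":
        group_expr = "b.dataset_name"
        join = ""
    elif group_by == "phylum":
        group_expr = "t.phylum"
        join = " JOIN taxonomy t ON t.genome_id = b.genome_id"
    else:
        raise ValueError("group_by must be 'dataset' or 'phylum'")

    df = pd.read_sql_query(
        f"""
        SELECT p.hit_id AS core_instance, {group_expr} AS grp,
               s.model_name AS clade, s.bitscore
        FROM domain_hit p
        JOIN domain_hit s ON s.parent_hit_id = p.hit_id
        JOIN bgc b ON b.bgc_id = p.bgc_id{join}
        WHERE p.model_name = ?
        """,
        conn,
        params=(core_domain,),
    )
    if df.empty:
        return pd.DataFrame(columns=["group", "clade", "n", "proportion"])
    best = (
        df.sort_values(["core_instance", "bitscore", "clade"], ascending=[True, False, True])
        .groupby("core_instance", as_index=False)
        .first()
    )
    counts = best.groupby(["grp", "clade"]).size().rename("n").reset_index()
    counts["proportion"] = counts.groupby("grp")["n"].transform(lambda s: s / s.sum())
    return counts.rename(columns={"grp": "group"})


def export_tables(conn: sqlite3.Connection, out_dir: str | Path) -> list[Path]:
    """Dump every table to TSV (one file per table)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    tables = [
        r[0]
        for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
    ]
    for table in sorted(tables):
        df = pd.read_sql_query(f'SELECT * FROM "{table}"', conn)
        p = out_dir / f"{table}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
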