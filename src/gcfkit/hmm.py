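"""Profile-HMM library management and domain scanning.

Two tiers of models drive feature extraction:

* *biosynthetic* models (a curated subset of Pfam-like domain profiles,
  some of which are flagged *core* biosynthetic domains) are scanned
  against whole CDS translations at each model's gathering cutoff and
  yield Boolean presence features;
* *sub-Pfam* models are clade-level sub-profiles of one core domain,
  built by hierarchically clustering an alignment of that domain's
  sequences.  They are scanned only against the protein subsequence
  spanned by each core-domain hit and yield ranked fingerprint features.

All scanning goes through pyhmmer and is deterministic for a fixed
library and input.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence
from pyhmmer.plan7 import HMM, Background, Builder, HMMFile, Pipeline
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .records import CdsRecord, DomainHit

CATEGORIES = ("biosynthetic", "core", "subpfam")

_ALPHABET = Alphabet.amino()


def _as_str(name) -> str:
    return name.decode() if isinstance(name, bytes) else str(name)


# Fixed builder seed: profile construction must not vary between runs.
_BUILDER_SEED = 42


@dataclass(frozen=True)
class ModelListEntry:
    """One row of the curated model list."""

    model_name: str
    category: str  # biosynthetic | core | subpfam
    parent_core: str | None = None
    gathering_cutoff: float | None = None


class HmmLibrary:
    """Validated index of a curated model list plus its pHMM profiles."""

    def __init__(self, entries: Sequence[ModelListEntry], hmms: Mapping[str, HMM]):
        self.entries = list(entries)
        self.by_name = {e.model_name: e for e in self.entries}
        self.hmms = dict(hmms)
        self._validate()

    def _validate(self) -> None:
        names = [e.model_name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate model names in list: {sorted(dupes)}")
        missing = [n for n in names if n not in self.hmms]
        if missing:
            raise FileNotFoundError(f"models listed but no HMM profile found: {missing}")
        cores = {e.model_name for e in self.entries if e.category == "core"}
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"{e.model_name}: unknown category {e.category!r}")
            if e.category == "subpfam":
                if e.parent_core not in cores:
                    raise ValueError(
                        f"{e.model_name}: parent_core {e.parent_core!r} is not a core model"
                    )
            elif e.parent_core:
                raise ValueError(f"{e.model_name}: parent_core set on non-subpfam entry")

    # -- introspection -------------------------------------------------
    def names(self, category: str | None = None) -> list[str]:
        if category is None:
            return [e.model_name for e in self.entries]
        return [e.model_name for e in self.entries if e.category == category]

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(self.names(c)) for c in CATEGORIES}

    def subpfams_of(self, core_name: str) -> list[str]:
        return sorted(
            e.model_name
            for e in self.entries
            if e.category == "subpfam" and e.parent_core == core_name
        )

    def feature_columns(self) -> list[str]:
        """Global column order: biosynthetic+core models, then sub-Pfams,
        each block lexicographic."""
        biosyn = sorted(self.names("biosynthetic") + self.names("core"))
        sub = sorted(self.names("subpfam"))
        return biosyn + sub

    def checksum(self) -> str:
        """Digest over model names, categories and profile contents; used
        to detect library/model-store mismatches at query time."""
        h = hashlib.sha256()
        for e in sorted(self.entries, key=lambda e: e.model_name):
            h.update(f"{e.model_name}\t{e.category}\t{e.parent_core}".encode())
            hmm = self.hmms[e.model_name]
            h.update(np.asarray(hmm.match_emissions).tobytes())
        return h.hexdigest()


def load_model_list(path: str | Path, hmm_dir: str | Path) -> HmmLibrary:
    """Load a curated model-list TSV and its HMM profiles.

    The TSV has columns ``model_name``, ``category`` (biosynthetic, core
    or subpfam) and ``parent_core`` (set only for subpfam rows).  Every
    listed model must have a HMMER3 profile in ``hmm_dir`` — either a
    file named ``<model_name>.hmm`` or inside any multi-profile ``*.hmm``
    file in the directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"model_name", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"model list must have columns {sorted(required)}")
    entries = [
        ModelListEntry(
            model_name=row.model_name,
            category=row.category,
            parent_core=(row.parent_core or None) if "parent_core" in df.columns else None,
            gathering_cutoff=float(row.gathering_cutoff)
            if "gathering_cutoff" in df.columns and row.gathering_cutoff
            else None,
        )
        for row in df.itertuples()
    ]
    hmms: dict[str, HMM] = {}
    for hmm_path in sorted(Path(hmm_dir).glob("*.hmm")):
        with HMMFile(str(hmm_path)) as fh:
            for hmm in fh:
                hmms[_as_str(hmm.name)] = hmm
    return HmmLibrary(entries, hmms)


# ---------------------------------------------------------------------------
# Building profiles


def build_hmm_from_alignment(name: str, aligned: Sequence[tuple[str, str]],
                             gathering_cutoff: float | None = None) -> HMM:
    """Build a profile from an aligned set of (seq_name, aligned_seq).

    Gap characters ``-``/``.`` are honoured as alignment gaps.  When a
    gathering cutoff is given it is written into the profile so scans can
    filter at it.
    """
    if len(aligned) < 1:
        raise ValueError("alignment must contain at least one sequence")
    seqs = [
        TextSequence(name=sname.encode(), sequence=s.replace(".", "-"))
        for sname, s in aligned
    ]
    msa = TextMSA(name=name.encode(), sequences=seqs)
    builder = Builder(_ALPHABET, seed=_BUILDER_SEED)
    hmm, _, _ = builder.build_msa(msa.digitize(_ALPHABET), Background(_ALPHABET))
    if gathering_cutoff is not None:
        hmm.cutoffs.gathering = (gathering_cutoff, gathering_cutoff)
    return hmm


def write_hmm(hmm: HMM, path: str | Path) -> None:
    with open(path, "wb") as fh:
        hmm.write(fh, binary=False)


def _pairwise_identity_distance(seqs: Sequence[str]) -> np.ndarray:
    """Distance = 1 − fraction of identical residues over mutually
    non-gap alignment columns; 1.0 when two sequences share no columns."""
    arr = np.array([list(s.replace(".", "-").upper()) for s in seqs])
    n = len(seqs)
    nongap = arr != "-"
    dist = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap
        shared = both.sum(axis=1)
        ident = ((arr[i] == arr) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.where(shared > 0, ident / np.maximum(shared, 1), 0.0)
        dist[i] = d
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def build_subpfam_models(
    alignment: Sequence[tuple[str, str]] | str | Path,
    core_name: str,
    n_clades: int,
    linkage_method: str = "average",
) -> tuple[dict[str, HMM], pd.DataFrame]:
    """Split an aligned core-domain family into clade sub-profiles.

    The aligned sequences are hierarchically clustered (identity-based
    distance, average linkage by default), the tree is cut to exactly
    ``n_clades`` clades and one profile is built per clade from its
    sub-alignment.  Returns the clade profiles (named
    ``<core_name>-c<k>``) and the sequence→clade assignment table.
    """
    if isinstance(alignment, (str, Path)):
        from Bio import AlignIO

        path = Path(alignment)
        fmt = "stockholm" if path.suffix in (".sto", ".stk") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        alignment = [(rec.id, str(rec.seq)) for rec in aln]
    names = [n for n, _ in alignment]
    seqs = [s for _, s in alignment]
    if len(seqs) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    if not 2 <= n_clades <= len(seqs):
        raise ValueError(f"n_clades must be in [2, {len(seqs)}], got {n_clades}")

    dist = _pairwise_identity_distance(seqs)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = cut_tree(Z, n_clusters=n_clades).ravel()

    # Stable clade numbering: order of first appearance in the alignment.
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    clade_ids = [remap[lab] for lab in labels]

    assignment = pd.DataFrame({"sequence": names, "clade": clade_ids})
    models: dict[str, HMM] = {}
    for k in sorted(set(clade_ids)):
        members = [(names[i], seqs[i]) for i in range(len(seqs)) if clade_ids[i] == k]
        model_name = f"{core_name}-c{k}"
        models[model_name] = build_hmm_from_alignment(model_name, members)
    return models, assignment


# ---------------------------------------------------------------------------
# Scanning


class ScanError(RuntimeError):
    pass


def _sequence_block(cds: Sequence[CdsRecord]) -> DigitalSequenceBlock:
    seqs = [
        TextSequence(name=str(i).encode(), sequence=c.aa_sequence).digitize(_ALPHABET)
        for i, c in enumerate(cds)
    ]
    return DigitalSequenceBlock(_ALPHABET, seqs)


def scan_biosynthetic(cds: Sequence[CdsRecord], library: HmmLibrary) -> list[DomainHit]:
    """Scan CDS translations against biosynthetic+core models.

    Hits are filtered at each model's gathering cutoff (sequence and
    domain level, as HMMER applies it).  Returned hits carry bitscore and
    1-based envelope coordinates on the protein.
    """
    cds = list(cds)
    if not cds:
        return []
    block = _sequence_block(cds)
    hits: list[DomainHit] = []
    for name in sorted(set(library.names("biosynthetic") + library.names("core"))):
        hmm = library.hmms[name]
        try:
            pipeline = Pipeline(_ALPHABET, bit_cutoffs="gathering" if hmm.cutoffs.gathering_available() else None)
            top = pipeline.search_hmm(hmm, block)
        except Exception as exc:
            raise ScanError(f"scanning model {name} failed: {exc}") from exc
        for hit in top:
            if not hit.included:
                continue
            record = cds[int(_as_str(hit.name))]
            for dom in hit.domains:
                if not dom.included:
                    continue
                hits.append(
                    DomainHit(
                        cds_id=record.cds_id,
                        bgc_id=record.bgc_id,
                        model_name=name,
                        bitscore=float(dom.score),
                        start_aa=int(dom.env_from),
                        end_aa=int(dom.env_to),
                    )
                )
    hits.sort(key=lambda h: (h.bgc_id, h.cds_id, h.model_name, h.start_aa))
    return hits


def scan_subpfam(
    core_hits: Sequence[DomainHit],
    cds: Sequence[CdsRecord],
    library: HmmLibrary,
) -> list[DomainHit]:
    """Scan each core-domain hit's spanned subsequence against that
    core's sub-Pfam models.

    All hits with positive bitscore are kept; ranking and top-K selection
    happen during feature extraction.  Each returned hit's ``parent_hit``
    is the originating core-domain instance.
    """
    import warnings

    cds_by_id = {c.cds_id: c for c in cds}
    core_instances = [h for h in core_hits if library.by_name.get(h.model_name, None)
                      and library.by_name[h.model_name].category == "core"]
    results: list[DomainHit] = []
    # Group instances per core model so each sub-model scans one block.
    by_core: dict[str, list[DomainHit]] = {}
    for h in core_instances:
        by_core.setdefault(h.model_name, []).append(h)
    for core_name, instances in sorted(by_core.items()):
        sub_names = library.subpfams_of(core_name)
        if not sub_names:
            continue
        subseqs = []
        kept_instances = []
        for inst in instances:
            parent = cds_by_id[inst.cds_id]
            fragment = parent.aa_sequence[inst.start_aa - 1 : inst.end_aa]
            if not fragment:
                warnings.warn(f"{inst.cds_id}: core hit with empty spanned subsequence; skipped")
                continue
            kept_instances.append(inst)
            subseqs.append(
                TextSequence(
                    name=str(len(kept_instances) - 1).encode(), sequence=fragment
                ).digitize(_ALPHABET)
            )
        if not subseqs:
            continue
        block = DigitalSequenceBlock(_ALPHABET, subseqs)
        for sub_name in sub_names:
            pipeline = Pipeline(_ALPHABET)
            try:
                top = pipeline.search_hmm(library.hmms[sub_name], block)
            except Exception as exc:
                raise ScanError(f"scanning sub-model {sub_name} failed: {exc}") from exc
            for hit in top:
                if hit.score <= 0:
                    continue
                inst = kept_instances[int(_as_str(hit.name))]
                best = max(hit.domains, key=lambda d: d.score)
                results.append(
                    DomainHit(
                        cds_id=inst.cds_id,
                        bgc_id=inst.bgc_id,
                        model_name=sub_name,
                        bitscore=float(hit.score),
                        start_aa=inst.start_aa + int(best.env_from) - 1,
                        end_aa=inst.start_aa + int(best.env_to) - 1,
                        parent_hit=inst,
                    )
                )
    results.sort(key=lambda h: (h.bgc_id, h.cds_id, h.model_name, h.start_aa))
    return results
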