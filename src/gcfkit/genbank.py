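"""Parse antiSMASH/MIBiG-style region GenBank files into BGC records.

antiSMASH v5 marks each predicted locus with a ``region`` feature; v4 used
``cluster``.  Both dialects are accepted (``region`` preferred when a file
carries both).  The contig-edge qualifier is spelled ``contig_edge`` in
antiSMASH output and ``on_contig_edge`` in some derived files; both are
read.  MIBiG entries have neither feature qualifier set and are treated as
complete reference clusters.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .records import TAXONOMY_RANKS, BgcRecord, CdsRecord

_EDGE_QUALIFIERS = ("contig_edge", "on_contig_edge")


class GenbankFormatError(ValueError):
    """Raised when a file cannot be interpreted as a region GenBank file."""


def _read_edge_flag(qualifiers: dict) -> bool | None:
    for key in _EDGE_QUALIFIERS:
        if key in qualifiers:
            return str(qualifiers[key][0]).strip().lower() == "true"
    return None


def _cds_translation(feature, record) -> str:
    if "translation" in feature.qualifiers:
        return str(feature.qualifiers["translation"][0]).strip().rstrip("*")
    # Conceptual translation from the nucleotide sequence.
    seq = feature.extract(record.seq)
    return str(Seq(seq).translate(to_stop=False)).rstrip("*")


def parse_region_genbank(
    path: str | Path, dataset: str = "default", genome_id: str | None = None
) -> list[BgcRecord]:
    """Parse one GenBank flat file into one ``BgcRecord`` per region.

    Multi-record files are scanned record by record; every ``region`` (or
    ``cluster``) feature yields a BGC whose id is the file stem plus a
    region index.  A file with no region feature at all is treated as a
    MIBiG-style entry: the whole record is one BGC.

    Parameters
    ----------
    path:
        GenBank flat file (``.gbk``/``.gbff``).
    dataset:
        Dataset label recorded on every BGC (provenance grouping).
    genome_id:
        Genome label; defaults to the file stem.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenbankFormatError(f"{path}: not a parseable GenBank file: {exc}") from exc
    if not seq_records:
        raise GenbankFormatError(f"{path}: no GenBank records found")

    if genome_id is None:
        genome_id = path.stem

    bgcs: list[BgcRecord] = []
    region_idx = 0
    for record in seq_records:
        regions = [f for f in record.features if f.type == "region"]
        if not regions:
            regions = [f for f in record.features if f.type == "cluster"]
        mibig_style = not regions
        if mibig_style:
            # MIBiG-style: the whole record is the cluster.
            region_spans = [(0, len(record.seq), None, set())]
        else:
            region_spans = []
            for f in regions:
                labels = {str(p) for p in f.qualifiers.get("product", [])}
                region_spans.append(
                    (
                        int(f.location.start),
                        int(f.location.end),
                        _read_edge_flag(f.qualifiers),
                        labels,
                    )
                )

        cds_features = [f for f in record.features if f.type == "CDS"]
        for start0, end0, edge, labels in region_spans:
            region_idx += 1
            bgc_id = f"{path.stem}.region{region_idx:03d}" if not mibig_style else path.stem
            length = end0 - start0
            if length <= 0:
                raise GenbankFormatError(f"{path}: region with non-positive length")
            cds_list: list[CdsRecord] = []
            for i, f in enumerate(cds_features):
                fs, fe = int(f.location.start), int(f.location.end)
                if fs < start0 or fe > end0:
                    continue
                aa = _cds_translation(f, record)
                if not aa:
                    continue
                locus = f.qualifiers.get("locus_tag", [f"cds{i + 1}"])[0]
                cds_list.append(
                    CdsRecord(
                        cds_id=f"{bgc_id}|{locus}",
                        bgc_id=bgc_id,
                        start_nt=fs - start0 + 1,
                        end_nt=fe - start0,
                        strand="-" if f.location.strand == -1 else "+",
                        aa_sequence=aa,
                    )
                )
            if not cds_list:
                warnings.warn(f"{bgc_id}: region without CDS features; kept with empty CDS list")
            bgcs.append(
                BgcRecord(
                    bgc_id=bgc_id,
                    dataset=dataset,
                    genome_id=genome_id,
                    source_path=str(path),
                    length_nt=length,
                    on_contig_edge=edge,
                    class_labels=frozenset(labels),
                    cds=cds_list,
                )
            )
    return bgcs


def parse_dataset_dir(directory: str | Path, dataset: str | None = None) -> list[BgcRecord]:
    """Parse every ``*.gbk``/``*.gbff`` file under a dataset directory.

    The genome id of each BGC is the file stem; the dataset label defaults
    to the directory name.
    """
    directory = Path(directory)
    if dataset is None:
        dataset = directory.name
    bgcs: list[BgcRecord] = []
    for path in sorted(directory.glob("*.gb*")):
        bgcs.extend(parse_region_genbank(path, dataset=dataset))
    return bgcs


def filter_complete(records: Iterable[BgcRecord]) -> list[BgcRecord]:
    """Keep only non-fragmented BGCs.

    A record is kept when its contig-edge flag is false or unknown; files
    lacking the qualifier (MIBiG references) count as complete.
    """
    return [r for r in records if r.is_complete]


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a genome→lineage TSV (columns: genome_id + 7 ranks)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["genome_id", *TAXONOMY_RANKS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    return df.set_index("genome_id")


def attach_taxonomy(records: Sequence[BgcRecord], taxonomy: pd.DataFrame) -> None:
    """Join a lineage onto each BGC in place; unknown genomes stay None."""
    for r in records:
        if r.genome_id in taxonomy.index:
            row = taxonomy.loc[r.genome_id]
            r.taxonomy = {rank: row[rank] for rank in TAXONOMY_RANKS}
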