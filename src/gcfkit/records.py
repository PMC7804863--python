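"""Core record types shared across the pipeline.

A *BGC* (biosynthetic gene cluster) is one predicted secondary-metabolite
locus; a *CDS* is one protein-coding gene inside it; a *DomainHit* is one
profile-HMM match on a CDS translation.  These three records are the raw
material of feature extraction and everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: 7-rank lineage column names, kingdom first.
TAXONOMY_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass
class CdsRecord:
    """One protein-coding gene of a BGC.

    Coordinates are 1-based inclusive GenBank coordinates on the region
    sequence; ``aa_sequence`` is the protein translation.
    """

    cds_id: str
    bgc_id: str
    start_nt: int
    end_nt: int
    strand: str  # "+" or "-"
    aa_sequence: str

    def __post_init__(self) -> None:
        if self.start_nt > self.end_nt:
            raise ValueError(
                f"{self.cds_id}: start_nt {self.start_nt} > end_nt {self.end_nt}"
            )
        if not self.aa_sequence:
            raise ValueError(f"{self.cds_id}: empty amino-acid sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.cds_id}: strand must be '+' or '-'")


@dataclass
class BgcRecord:
    """One BGC region with provenance and completeness metadata.

    ``on_contig_edge`` is tri-state: ``True`` (fragmented), ``False``
    (complete), or ``None`` when the source file carries no contig-edge
    qualifier (e.g. MIBiG entries), which downstream treats as complete.
    """

    bgc_id: str
    dataset: str
    genome_id: str
    source_path: str
    length_nt: int
    on_contig_edge: Optional[bool]
    class_labels: frozenset[str]
    cds: list[CdsRecord] = field(default_factory=list)
    taxonomy: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"{self.bgc_id}: length_nt must be positive")
        for c in self.cds:
            if c.end_nt > self.length_nt:
                raise ValueError(
                    f"{c.cds_id}: end_nt {c.end_nt} beyond BGC length {self.length_nt}"
                )

    @property
    def is_complete(self) -> bool:
        """Complete unless the contig-edge flag is explicitly true."""
        return self.on_contig_edge is not True


@dataclass(frozen=True)
class DomainHit:
    """One pHMM hit on one CDS translation.

    ``start_aa``/``end_aa`` are 1-based inclusive envelope coordinates on
    the protein.  For sub-Pfam hits, ``parent_hit`` points back to the
    core-domain hit instance whose spanned subsequence was scanned.
    """

    cds_id: str
    bgc_id: str
    model_name: str
    bitscore: float
    start_aa: int
    end_aa: int
    parent_hit: Optional["DomainHit"] = None
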