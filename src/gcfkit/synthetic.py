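"""Synthetic pHMM libraries and BGC sets with planted GCF structure.

These generators make the whole pipeline testable without any external
download: a toy profile library stands in for the curated
biosynthetic-Pfam / sub-Pfam collections, and simulated region GenBank
files stand in for antiSMASH output.  Each planted GCF is defined by a
characteristic subset of biosynthetic motifs plus one clade of one core
motif; member BGCs carry point-mutated copies of those motifs as CDSs,
mixed with random filler genes.  The planted group label of every BGC is
recorded in a truth table so clustering results can be scored against
ground truth.

Everything is seeded and byte-reproducible.  The generator emulates
domain-content structure only: it does not model realistic Pfam
architecture statistics, gene synteny signal, or taxon abundances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .hmm import HmmLibrary, build_hmm_from_alignment, load_model_list
from .records import TAXONOMY_RANKS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed back-translation codon table (one codon per amino acid).
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Gathering cutoff written into every toy biosynthetic model (bits).
TOY_GATHERING_CUTOFF = 20.0
_SEQS_PER_MODEL = 10
_ALIGNMENT_NOISE = 0.05   # per-residue substitution rate within a model's alignment
_CLADE_DIVERGENCE = 0.35  # per-residue divergence between clades of one core motif
_FIXED_HMM_DATE = "Thu Jan  1 00:00:00 1970"


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    out = list(motif)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(out)


def _random_motif(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _write_hmm_deterministic(hmm, path: Path) -> None:
    """Write a HMMER3 text profile with a pinned DATE line so repeated
    generator runs produce byte-identical files."""
    buf = io.BytesIO()
    hmm.write(buf, binary=False)
    lines = buf.getvalue().decode().splitlines(keepends=True)
    lines = [
        f"DATE  {_FIXED_HMM_DATE}\n" if line.startswith("DATE ") else line
        for line in lines
    ]
    path.write_text("".join(lines))


@dataclass
class ToyLibrary:
    """A generated pHMM library bundle: files on disk plus the motif
    truth needed to plant BGC structure."""

    hmm_dir: Path
    model_list_path: Path
    motifs: dict[str, str]          # model name → consensus motif (biosyn + core)
    clade_motifs: dict[str, str]    # sub-Pfam model name → clade consensus
    core_names: list[str]
    biosyn_names: list[str]         # non-core biosynthetic models

    def load(self) -> HmmLibrary:
        return load_model_list(self.model_list_path, self.hmm_dir)


def make_toy_hmm_library(
    out_dir: str | Path,
    n_biosyn: int = 6,
    n_core: int = 2,
    clades_per_core: int = 3,
    motif_length: int = 40,
    seed: int = 0,
) -> ToyLibrary:
    """Generate a toy pHMM library.

    ``n_biosyn`` biosynthetic models are built from distinct random
    consensus motifs; the first ``n_core`` of them are flagged *core*
    and each gets ``clades_per_core`` sub-Pfam models built from
    diverged copies of the core motif.  Every model's profile is built
    from a 10-sequence ungapped synthetic alignment, so it is scannable
    and self-consistent; biosynthetic/core models carry a gathering
    cutoff of 20 bits.
    """
    if n_biosyn < 1 or n_core < 0 or n_core > n_biosyn:
        raise ValueError("need n_biosyn >= 1 and 0 <= n_core <= n_biosyn")
    if n_core > 0 and clades_per_core < 2:
        raise ValueError("clades_per_core must be >= 2")
    if motif_length < 10:
        raise ValueError("motif_length must be >= 10 residues")

    out_dir = Path(out_dir)
    hmm_dir = out_dir / "hmm"
    hmm_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    motifs: dict[str, str] = {}
    clade_motifs: dict[str, str] = {}
    core_names: list[str] = []
    biosyn_names: list[str] = []

    for m in range(n_biosyn):
        name = f"toyD{m + 1:03d}"
        category = "core" if m < n_core else "biosynthetic"
        motif = _random_motif(motif_length, rng)
        motifs[name] = motif
        aligned = [
            (f"{name}_s{i}", _mutate(motif, _ALIGNMENT_NOISE, rng))
            for i in range(_SEQS_PER_MODEL)
        ]
        hmm = build_hmm_from_alignment(name, aligned, gathering_cutoff=TOY_GATHERING_CUTOFF)
        _write_hmm_deterministic(hmm, hmm_dir / f"{name}.hmm")
        rows.append((name, category, "", TOY_GATHERING_CUTOFF))
        (core_names if category == "core" else biosyn_names).append(name)

        if category == "core":
            for c in range(clades_per_core):
                sub_name = f"{name}-c{c + 1}"
                clade_motif = _mutate(motif, _CLADE_DIVERGENCE, rng)
                clade_motifs[sub_name] = clade_motif
                sub_aligned = [
                    (f"{sub_name}_s{i}", _mutate(clade_motif, _ALIGNMENT_NOISE, rng))
                    for i in range(_SEQS_PER_MODEL)
                ]
                sub_hmm = build_hmm_from_alignment(sub_name, sub_aligned)
                _write_hmm_deterministic(sub_hmm, hmm_dir / f"{sub_name}.hmm")
                rows.append((sub_name, "subpfam", name, ""))

    model_list_path = out_dir / "model_list.tsv"
    pd.DataFrame(
        rows, columns=["model_name", "category", "parent_core", "gathering_cutoff"]
    ).to_csv(model_list_path, sep="\t", index=False)

    return ToyLibrary(
        hmm_dir=hmm_dir,
        model_list_path=model_list_path,
        motifs=motifs,
        clade_motifs=clade_motifs,
        core_names=core_names,
        biosyn_names=biosyn_names,
    )


# ---------------------------------------------------------------------------
# BGC simulation


@dataclass
class PlantedGcf:
    """Ground-truth definition of one planted family."""

    gcf_id: int
    biosyn_subset: list[str]   # characteristic biosynthetic motifs
    core_model: str
    clade_model: str           # the sub-Pfam clade carried by members
    species: str


@dataclass
class SimulatedBgcSet:
    """A generated BGC collection with its ground truth."""

    bgc_dir: Path
    truth_path: Path
    taxonomy_path: Path
    truth: pd.DataFrame = field(repr=False)
    planted: list[PlantedGcf] = field(default_factory=list, repr=False)


def _backtranslate(aa: str) -> str:
    return "".join(CODON_TABLE[res] for res in aa) + "TAA"


def _gene_records(genes: list[tuple[str, str, int]], spacer: int = 30):
    """Lay out (locus_tag, protein, strand) genes on a contig; returns
    (sequence string, CDS feature list)."""
    seq_parts: list[str] = []
    features: list[SeqFeature] = []
    pos = spacer
    seq_parts.append("A" * spacer)
    for locus, aa, strand in genes:
        nt = _backtranslate(aa)
        if strand == -1:
            nt = str(Seq(nt).reverse_complement())
        start = pos
        end = pos + len(nt)
        features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=strand),
                type="CDS",
                qualifiers={"locus_tag": [locus], "translation": [aa]},
            )
        )
        seq_parts.append(nt)
        seq_parts.append("A" * spacer)
        pos = end + spacer
    return "".join(seq_parts), features


def _write_region_genbank(
    path: Path,
    bgc_name: str,
    genes: list[tuple[str, str, int]],
    contig_edge: bool,
    product: str,
) -> None:
    seq, cds_features = _gene_records(genes)
    region = SeqFeature(
        FeatureLocation(0, len(seq)),
        type="region",
        qualifiers={
            "region_number": ["1"],
            "product": [product],
            "contig_edge": ["True" if contig_edge else "False"],
        },
    )
    record = SeqRecord(
        Seq(seq),
        id=bgc_name,
        name=bgc_name[:16],
        description=f"synthetic BGC region {bgc_name}",
        features=[region, *cds_features],
        annotations={"molecule_type": "DNA", "date": "01-JAN-2000", "topology": "linear"},
    )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def simulate_bgc_set(
    out_dir: str | Path,
    library: ToyLibrary,
    n_gcfs: int = 5,
    bgcs_per_gcf: int = 8,
    within_mutation_rate: float = 0.02,
    fragment_fraction: float = 0.0,
    n_filler_genes: int = 2,
    seed: int = 0,
) -> SimulatedBgcSet:
    """Simulate a BGC collection with planted GCF structure.

    Each planted GCF carries a characteristic subset of the library's
    biosynthetic motifs plus one clade of one core motif; members encode
    point-mutated copies (``within_mutation_rate`` per residue) of those
    motifs plus random filler genes.  ``fragment_fraction`` of the BGCs
    (rounded, chosen deterministically under the seed) are emitted as
    fragments: contig-edge flag set and a random suffix of genes
    deleted.  One GenBank file is written per BGC (file stem doubles as
    its genome id), together with a truth table and a 7-rank taxonomy
    table keyed on species labels that follow the planted families.
    """
    if not 0 <= within_mutation_rate <= 1:
        raise ValueError("within_mutation_rate must be in [0, 1]")
    if not 0 <= fragment_fraction <= 1:
        raise ValueError("fragment_fraction must be in [0, 1]")
    if n_gcfs < 1 or bgcs_per_gcf < 1:
        raise ValueError("n_gcfs and bgcs_per_gcf must be >= 1")
    if not library.core_names:
        raise ValueError("library has no core models; cannot plant clade structure")

    out_dir = Path(out_dir)
    bgc_dir = out_dir / "bgc"
    bgc_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pool = library.biosyn_names
    subset_size = max(1, len(pool) // 2)

    planted: list[PlantedGcf] = []
    seen_signatures: set[tuple] = set()
    for g in range(n_gcfs):
        # Distinct characteristic signatures keep planted families separable.
        for _ in range(1000):
            subset = sorted(rng.choice(pool, size=min(subset_size, len(pool)), replace=False))
            core = library.core_names[int(rng.integers(len(library.core_names)))]
            clades = sorted(k for k in library.clade_motifs if k.startswith(core + "-"))
            clade = clades[int(rng.integers(len(clades)))]
            signature = (tuple(subset), clade)
            if signature not in seen_signatures:
                seen_signatures.add(signature)
                break
        planted.append(
            PlantedGcf(
                gcf_id=g + 1,
                biosyn_subset=list(subset),
                core_model=core,
                clade_model=clade,
                species=f"Species{g + 1:02d}",
            )
        )

    n_total = n_gcfs * bgcs_per_gcf
    n_fragments = int(round(fragment_fraction * n_total))
    fragment_idx = set(rng.choice(n_total, size=n_fragments, replace=False).tolist())

    truth_rows = []
    idx = 0
    for gcf in planted:
        for m in range(bgcs_per_gcf):
            stem = f"G{gcf.gcf_id:02d}B{m + 1:02d}"
            genes: list[tuple[str, str, int]] = []
            for t, model in enumerate(gcf.biosyn_subset):
                aa = _mutate(library.motifs[model], within_mutation_rate, rng)
                genes.append((f"b{t + 1}", aa, 1 if t % 2 == 0 else -1))
            core_aa = _mutate(library.clade_motifs[gcf.clade_model], within_mutation_rate, rng)
            genes.append(("core1", core_aa, 1))
            for f in range(n_filler_genes):
                genes.append((f"fill{f + 1}", _random_motif(60, rng), 1))
            rng.shuffle(genes)

            is_fragment = idx in fragment_idx
            if is_fragment and len(genes) > 1:
                n_drop = int(rng.integers(1, len(genes)))
                genes = genes[: len(genes) - n_drop]

            _write_region_genbank(
                bgc_dir / f"{stem}.gbk",
                stem,
                genes,
                contig_edge=is_fragment,
                product=f"toy_class_{gcf.core_model}",
            )
            truth_rows.append(
                {
                    "bgc_id": f"{stem}.region001",
                    "genome_id": stem,
                    "gcf_truth": gcf.gcf_id,
                    "is_fragment": is_fragment,
                    "species": gcf.species,
                }
            )
            idx += 1

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    taxonomy_path = out_dir / "taxonomy.tsv"
    tax_rows = []
    for row in truth.itertuples():
        g = int(row.gcf_truth)
        lineage = {
            "kingdom": "Bacteria",
            "phylum": f"Phylum{(g - 1) % 2 + 1}",
            "class": f"Class{(g - 1) % 2 + 1}",
            "order": f"Order{g}",
            "family": f"Family{g}",
            "genus": f"Genus{chr(ord('A') + (g - 1) % 4)}",
            "species": row.species,
        }
        tax_rows.append({"genome_id": row.genome_id, **lineage})
    pd.DataFrame(tax_rows, columns=["genome_id", *TAXONOMY_RANKS]).to_csv(
        taxonomy_path, sep="\t", index=False
    )

    return SimulatedBgcSet(
        bgc_dir=bgc_dir,
        truth_path=truth_path,
        taxonomy_path=taxonomy_path,
        truth=truth,
        planted=planted,
    )


def truncate_region_genbank(
    path: str | Path, out_path: str | Path, max_fraction: float = 0.25, seed: int = 0
) -> int:
    """Emit a mildly truncated fragment variant of a generated region.

    Removes a random suffix of at most ``max_fraction`` of the CDS
    features (at least one), trims the sequence accordingly, and sets
    the contig-edge flag.  Returns the number of genes removed.
    """
    path, out_path = Path(path), Path(out_path)
    record = next(SeqIO.parse(str(path), "genbank"))
    cds = [f for f in record.features if f.type == "CDS"]
    if len(cds) < 2:
        raise ValueError(f"{path}: need >= 2 CDS features to truncate")
    rng = np.random.default_rng(seed)
    max_drop = max(1, int(max_fraction * len(cds)))
    n_drop = int(rng.integers(1, max_drop + 1))
    kept = cds[: len(cds) - n_drop]
    genes = [
        (
            f.qualifiers["locus_tag"][0],
            f.qualifiers["translation"][0],
            f.location.strand,
        )
        for f in kept
    ]
    _write_region_genbank(
        out_path,
        out_path.stem,
        genes,
        contig_edge=True,
        product="toy_fragment",
    )
    return n_drop
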