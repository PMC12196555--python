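"""Sequence and annotation I/O plus coordinate arithmetic.

Conventions
-----------
CDS positions are 1-based inclusive, with the A of the start codon at
position 1.  Genomic intervals are stored 0-based half-open internally;
GFF3 input (1-based inclusive) and BED output (0-based half-open) are
converted at the I/O boundary.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = set("ACGTN")

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "CdsWindow",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "cds_position_to_codon",
    "distance_to_window",
    "find_shared_exons",
    "read_gene_models",
    "write_bed6",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the record invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; nucleotide records are restricted to A,C,G,T,N."""

    identifier: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsWindow:
    """An inclusive 1-based window on a coding sequence (e.g. a ZFN target site)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid CDS window [{self.start}, {self.end}]")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GeneModel:
    """A gene with per-isoform exon structure and its coding sequence.

    ``isoforms`` maps isoform id to ordered exon intervals in genomic
    coordinates (0-based half-open).  ``cds_sequence`` is the authoritative
    coding sequence used for all codon arithmetic; it must begin with ATG.
    """

    gene_id: str
    strand: Literal["+", "-"]
    isoforms: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.cds_sequence:
            if len(self.cds_sequence) < 3:
                raise ValueError("cds_sequence must be at least one codon long")
            if not self.cds_sequence.upper().startswith("ATG"):
                raise ValueError("cds_sequence must begin with ATG")
            self.cds_sequence = self.cds_sequence.upper()
        for iso_id, exons in self.isoforms.items():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"isoform {iso_id}: exons [{s1},{e1}) and [{s2},{e2}) "
                        "overlap or are unordered"
                    )


def _validate_nucleotide(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"{context} contains non-nucleotide characters: {sorted(bad)}")


def read_fasta(path: str | os.PathLike, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and record order is preserved.  Duplicate
    identifiers, empty sequences and malformed headers raise
    :class:`FastaParseError` naming the offending line.

    ``alphabet`` may be ``"nucleotide"``, ``"protein"`` or ``"auto"``
    (validate as nucleotide only when the content looks like DNA).
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    # Track header line numbers for error messages.
    header_lines: list[int] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                if line[1:].strip() == "":
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                header_lines.append(lineno)
            elif line.strip() and not header_lines:
                raise FastaParseError(
                    f"{path}: sequence data before any header at line {lineno}"
                )
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line = header_lines[i] if i < len(header_lines) else "?"
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(
                f"{path}: record '{rec.id}' (line {line}) has an empty sequence"
            )
        if rec.id in seen:
            raise FastaParseError(
                f"{path}: duplicate identifier '{rec.id}' at line {line} "
                f"(first seen at line {seen[rec.id]})"
            )
        seen[rec.id] = line if isinstance(line, int) else -1
        if alphabet == "nucleotide" or (
            alphabet == "auto" and set(seq) <= NUCLEOTIDES
        ):
            if alphabet == "nucleotide":
                _validate_nucleotide(seq, f"record '{rec.id}'")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70
) -> None:
    """Write records as wrapped multi-FASTA."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    seq = seq.upper()
    _validate_nucleotide(seq)
    return str(Seq(seq).reverse_complement())


def cds_position_to_codon(pos: int) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon index.

    With ATG at positions 1-3, position ``pos`` lies in codon
    ``ceil(pos / 3)``; e.g. CDS position 692 falls in codon 231.
    """
    if pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {pos}")
    return ceil(pos / 3)


def distance_to_window(pos: int, window: CdsWindow) -> tuple[str, int]:
    """Relate a CDS position to a window: (relation, distance in nt).

    A position upstream of the window is ``window.start - pos`` nucleotides
    away; downstream is ``pos - window.end``; inside is distance 0.
    """
    if pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {pos}")
    if pos < window.start:
        return ("upstream", window.start - pos)
    if pos > window.end:
        return ("downstream", pos - window.end)
    return ("inside", 0)


def find_shared_exons(model: GeneModel) -> list[tuple[int, int]]:
    """Exon intervals present, with identical coordinates, in every isoform.

    Identity of genomic intervals (not mere overlap) is required: an exon
    shared by all predicted isoforms is a safe region to target for
    disruption of every transcript.  Returned in genomic order.
    """
    if not model.isoforms:
        raise ValueError(f"gene {model.gene_id} has no isoforms")
    iso_sets = [set(exons) for exons in model.isoforms.values()]
    shared = set.intersection(*iso_sets)
    return sorted(shared)


def read_gene_models(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3: exon features grouped by transcript Parent.

    Strand is taken from the gene (or first transcript) record.  CDS
    sequences are not reconstructed here (no genome is attached); callers
    supply ``cds_sequence`` separately when codon arithmetic is needed.
    """
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbpath,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        models: list[GeneModel] = []
        for gene in db.features_of_type("gene"):
            isoforms: dict[str, list[tuple[int, int]]] = {}
            for tx in db.children(gene, level=1):
                if tx.featuretype not in ("mRNA", "transcript"):
                    continue
                exons = sorted(
                    # GFF3 is 1-based inclusive; convert to 0-based half-open.
                    (feat.start - 1, feat.end)
                    for feat in db.children(tx, featuretype="exon")
                )
                if exons:
                    isoforms[tx.id] = exons
            models.append(
                GeneModel(gene_id=gene.id, strand=gene.strand or "+", isoforms=isoforms)
            )
        return models
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)


def write_bed6(
    intervals: Sequence[tuple[str, int, int, str, int | float, str]],
    path: str | os.PathLike,
) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6.

    Intervals must already be 0-based half-open.
    """
    with open(path, "w") as out:
        for chrom, start, end, name, score, strand in intervals:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
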