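"""Sequence record types and FASTA input/output.

Protein and coding-sequence records are thin identified-string containers;
all file IO goes through Biopython so headers and line wrapping follow
community conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
DNA_ALPHABET = frozenset("ACGTN")


class SequenceError(ValueError):
    """Raised for malformed or out-of-alphabet sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence over the 20 canonical residues plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"protein record {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise SequenceError(
                    f"protein record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingRecord:
    """An identified nucleotide coding sequence (ACGT plus N).

    ``frame_offset`` declares where codon 1 starts (0-based shift into the
    sequence); the default 0 treats the record as a spliced CDS beginning at
    the start codon.
    """

    id: str
    nucleotides: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise SequenceError(f"coding record {self.id!r} is empty")
        for pos, ch in enumerate(self.nucleotides, start=1):
            if ch not in DNA_ALPHABET:
                raise SequenceError(
                    f"coding record {self.id!r}: invalid base {ch!r} at position {pos}"
                )
        if not 0 <= self.frame_offset <= 2:
            raise SequenceError(f"frame offset must be 0, 1 or 2, got {self.frame_offset}")

    def __len__(self) -> int:
        return len(self.nucleotides)


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read all protein records from a FASTA file (uppercased)."""
    records = [
        ProteinRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def read_coding_fasta(path: str | Path) -> list[CodingRecord]:
    """Read all nucleotide coding records from a FASTA file (uppercased)."""
    records = [
        CodingRecord(id=rec.id, nucleotides=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord | CodingRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA."""
    seqs = []
    for rec in records:
        body = rec.residues if isinstance(rec, ProteinRecord) else rec.nucleotides
        seqs.append(SeqRecord(Seq(body), id=rec.id, description=""))
    SeqIO.write(seqs, str(path), "fasta")
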