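"""CRISPR knockout-allele consequence prediction.

Models the sequence consequence of a Cas9-induced deletion in a spliced
coding sequence: apply the deletion, translate in the edited frame with the
standard genetic code, and classify the outcome (frameshift, premature stop
codon, predicted loss of function). Also locates sgRNA and primer binding
sites by exact match on either strand.

Exon structure and splice effects are deliberately not modeled: the pipeline
operates on the spliced CDS, and exon numbers are metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .records import CodingRecord, SequenceError


class CoordinateError(ValueError):
    """Raised for deletion intervals outside the sequence."""


@dataclass(frozen=True)
class EditOutcome:
    """Predicted consequence of a deletion allele.

    ``premature_stop_codon_index`` is the 1-based codon position of the first
    stop in the edited frame, when that stop falls strictly before the codon
    position equivalent to the wild-type stop; ``predicted_lof`` is set when
    the edit causes a frameshift or introduces a premature stop.
    """

    deletion_start: int
    deletion_length: int
    frameshift: bool
    premature_stop_codon_index: int | None
    predicted_lof: bool

    def __post_init__(self) -> None:
        if self.frameshift != (self.deletion_length % 3 != 0):
            raise ValueError("frameshift flag inconsistent with deletion length")
        if self.predicted_lof and not (
            self.frameshift or self.premature_stop_codon_index is not None
        ):
            raise ValueError("loss of function requires frameshift or premature stop")


def apply_deletion(cds: CodingRecord, start: int, length: int) -> CodingRecord:
    """Remove the closed 1-based interval [start, start+length-1]; returns a new record."""
    if length < 0:
        raise CoordinateError(f"deletion length must be non-negative, got {length}")
    if start < 1 or start + length - 1 > len(cds):
        raise CoordinateError(
            f"deletion [{start}, {start + length - 1}] outside sequence "
            f"of length {len(cds)}"
        )
    edited = cds.nucleotides[: start - 1] + cds.nucleotides[start - 1 + length :]
    if not edited:
        raise SequenceError(f"deletion removes the entire sequence {cds.id!r}")
    return CodingRecord(
        id=f"{cds.id}_del{start}_{length}" if length else cds.id,
        nucleotides=edited,
        frame_offset=cds.frame_offset,
    )


def translate_cds(cds: CodingRecord) -> tuple[str, int | None]:
    """Translate with the standard genetic code until the first stop.

    Returns the translated protein (stop excluded; codons containing N become
    X) and the 1-based codon index of the stop, or None if no stop occurs.
    A trailing partial codon is ignored.
    """
    body = cds.nucleotides[cds.frame_offset :]
    if len(body) < 3:
        raise SequenceError(
            f"coding record {cds.id!r}: fewer than 3 nucleotides in frame"
        )
    usable = body[: len(body) - len(body) % 3]
    full = str(Seq(usable).translate())  # standard table; ambiguous codons -> X
    stop = full.find("*")
    if stop == -1:
        return full, None
    return full[:stop], stop + 1


def classify_edit(cds: CodingRecord, start: int, length: int) -> EditOutcome:
    """Classify the consequence of deleting ``length`` bp at ``start``.

    The premature-stop rule compares codon indices in the edited frame: the
    wild-type stop at codon ``s`` corresponds, after an in-frame or shifted
    deletion of L bp, to edited codon ``s - L/3`` (rounded down); any stop
    strictly before that position is premature. Frameshift is purely
    ``length mod 3 != 0``.
    """
    frameshift = length % 3 != 0
    _, wt_stop = translate_cds(cds)
    edited = apply_deletion(cds, start, length)
    _, ed_stop = translate_cds(edited)

    premature: int | None = None
    if ed_stop is not None:
        if wt_stop is None:
            # wild type ran to the end without a stop: any stop is early
            premature = ed_stop
        else:
            wt_equiv = wt_stop - length // 3
            if ed_stop < wt_equiv:
                premature = ed_stop
    predicted_lof = frameshift or premature is not None
    return EditOutcome(
        deletion_start=start,
        deletion_length=length,
        frameshift=frameshift,
        premature_stop_codon_index=premature,
        predicted_lof=predicted_lof,
    )


def reverse_complement(oligo: str) -> str:
    return str(Seq(oligo).reverse_complement())


def find_oligo_sites(seq: CodingRecord, oligo: str) -> list[tuple[int, str]]:
    """Exact-match positions of an oligo on both strands, 1-based.

    Returns (position, strand) pairs where position is the 1-based start of
    the match on the forward sequence; strand "-" means the reverse complement
    of the oligo matches there (i.e. the oligo binds the reverse strand).
    """
    if not oligo:
        raise SequenceError("empty oligo")
    oligo = oligo.upper()
    if set(oligo) - set("ACGT"):
        bad = sorted(set(oligo) - set("ACGT"))
        raise SequenceError(f"oligo contains non-ACGT characters: {bad}")
    hits: list[tuple[int, str]] = []
    for strand, probe in (("+", oligo), ("-", reverse_complement(oligo))):
        pos = seq.nucleotides.find(probe)
        while pos != -1:
            hits.append((pos + 1, strand))
            pos = seq.nucleotides.find(probe, pos + 1)
    return sorted(hits)
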