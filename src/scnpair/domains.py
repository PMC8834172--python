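"""Domain-resolved conservation scoring of two paralogs against a reference.

The analysis: take a table of reference-coordinate domain features (UniProt
topological domains and transmembrane segments of the sodium channel), project
each span through the reference-anchored pairwise alignments, compute percent
identity of each paralog over the reference residues of that span, and flag
domains whose conservation differs between the paralogs by more than a
threshold (default 20 percentage points, strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import PairwiseAlignment, map_ref_position_to_column, percent_identity

DOMAIN_CLASSES = {
    "TM_segment",
    "extracellular_loop",
    "cytoplasmic_linker",
    "pore_loop",
    "N_terminus",
    "C_terminus",
    "other",
}

#: spans shorter than this many residues are annotated as short peptides
SHORT_PEPTIDE_LENGTH = 5

#: differential-conservation flag threshold, percentage points (strict >)
FLAG_THRESHOLD = 20.0


class DomainTableError(ValueError):
    """Raised for malformed domain annotation tables."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A named reference-coordinate feature, 1-based inclusive span."""

    label: str
    klass: str
    start: int
    end: int
    channel_domain: str | None = None  # I..IV for the four homologous domains
    short_peptide: bool = False

    def __post_init__(self) -> None:
        if self.klass not in DOMAIN_CLASSES:
            raise DomainTableError(
                f"domain {self.label!r}: unknown class {self.klass!r}"
            )
        if not 1 <= self.start <= self.end:
            raise DomainTableError(
                f"domain {self.label!r}: invalid span {self.start}..{self.end}"
            )
        if self.channel_domain is not None and self.channel_domain not in {
            "I",
            "II",
            "III",
            "IV",
        }:
            raise DomainTableError(
                f"domain {self.label!r}: channel domain must be I-IV, "
                f"got {self.channel_domain!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainConservationRecord:
    """Per-domain identity of paralogs A and B vs the reference (one table row).

    ``delta`` is identity_b - identity_a in percentage points (positive means
    paralog B better conserved); ``flagged`` is |delta| > threshold, strictly.
    Identities are None when the reference span aligned entirely to gaps.
    """

    annotation: DomainAnnotation
    identity_a: float | None
    identity_b: float | None
    delta: float | None
    flagged: bool


def _validate_table(domains: list[DomainAnnotation], ref_length: int | None) -> None:
    labels = [d.label for d in domains]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise DomainTableError(f"duplicate domain labels: {sorted(dupes)}")
    offenders = []
    ordered = sorted(domains, key=lambda d: d.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start <= prev.end:
            offenders.append(f"{prev.label} overlaps {cur.label}")
    if ref_length is not None:
        for d in domains:
            if d.end > ref_length:
                offenders.append(f"{d.label} extends past reference length {ref_length}")
    if offenders:
        raise DomainTableError("invalid domain spans: " + "; ".join(offenders))


def read_domain_table(
    path: str | Path, ref_length: int | None = None
) -> list[DomainAnnotation]:
    """Read a TSV of domain features (label/class/channel_domain/start/end).

    Rows are validated (bounds, overlap, duplicate labels) and returned sorted
    by start coordinate; the short-peptide mark is derived from span length.
    """
    df = pd.read_csv(path, sep="\t", dtype={"channel_domain": "string"})
    required = {"label", "class", "channel_domain", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DomainTableError(f"domain table missing columns: {sorted(missing)}")
    domains = []
    for row in df.to_dict("records"):
        cd = row["channel_domain"]
        cd = None if pd.isna(cd) or cd == "" else str(cd)
        start, end = int(row["start"]), int(row["end"])
        if end < start:
            raise DomainTableError(f"domain {row['label']!r}: end {end} < start {start}")
        domains.append(
            DomainAnnotation(
                label=str(row["label"]),
                klass=str(row["class"]),
                start=start,
                end=end,
                channel_domain=cd,
                short_peptide=(end - start + 1) < SHORT_PEPTIDE_LENGTH,
            )
        )
    _validate_table(domains, ref_length)
    return sorted(domains, key=lambda d: d.start)


def write_domain_table(domains: list[DomainAnnotation], path: str | Path) -> None:
    """Write annotations in the TSV dialect that :func:`read_domain_table` reads."""
    pd.DataFrame(
        [
            {
                "label": d.label,
                "class": d.klass,
                "channel_domain": d.channel_domain or "",
                "start": d.start,
                "end": d.end,
            }
            for d in domains
        ]
    ).to_csv(path, sep="\t", index=False)


def read_uniprot_feature_gff(
    path: str | Path, ref_length: int | None = None
) -> list[DomainAnnotation]:
    """Import UniProt feature GFF rows (Topological domain / Transmembrane).

    A coordinate passthrough: start/end are taken as 1-based inclusive, the
    class is inferred from the feature type and the Note attribute, and labels
    are synthesised as ``<type>_<start>`` when no Note is present.
    """
    wanted = {"Topological domain", "Transmembrane", "Domain", "Region"}
    domains: list[DomainAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] not in wanted:
                continue
            start, end = int(parts[3]), int(parts[4])
            attrs = parts[8] if len(parts) > 8 else ""
            note = ""
            for item in attrs.split(";"):
                if item.startswith("Note="):
                    note = item[5:].strip()
            if parts[2] == "Transmembrane":
                klass = "TM_segment"
            elif "Cytoplasmic" in note:
                klass = "cytoplasmic_linker"
            elif "Extracellular" in note:
                klass = "extracellular_loop"
            else:
                klass = "other"
            label = note.replace(" ", "_") if note else f"{parts[2].replace(' ', '_')}_{start}"
            domains.append(
                DomainAnnotation(
                    label=label,
                    klass=klass,
                    start=start,
                    end=end,
                    short_peptide=(end - start + 1) < SHORT_PEPTIDE_LENGTH,
                )
            )
    # UniProt labels repeat ("Helical"); make them unique by coordinate
    seen: dict[str, int] = {}
    unique: list[DomainAnnotation] = []
    for d in domains:
        if d.label in seen:
            d = DomainAnnotation(
                label=f"{d.label}_{d.start}",
                klass=d.klass,
                start=d.start,
                end=d.end,
                channel_domain=d.channel_domain,
                short_peptide=d.short_peptide,
            )
        seen[d.label] = 1
        unique.append(d)
    _validate_table(unique, ref_length)
    return sorted(unique, key=lambda d: d.start)


def score_domains(
    aln_a: PairwiseAlignment,
    aln_b: PairwiseAlignment,
    domains: list[DomainAnnotation],
    flag_threshold: float = FLAG_THRESHOLD,
) -> list[DomainConservationRecord]:
    """Score per-domain identity of paralogs A and B against the shared reference.

    Both alignments must be anchored on the same reference sequence. For each
    domain the reference span is projected to alignment columns independently
    in each alignment; identity is computed over reference residues (paralog
    gaps count as mismatches). Domains whose reference span aligned entirely
    to gaps get identity None and are excluded from flagging.
    """
    if aln_a.ref_sequence != aln_b.ref_sequence:
        raise DomainTableError(
            "the two alignments are anchored on different reference sequences"
        )
    ref_len = len(aln_a.ref_sequence)
    records = []
    for dom in domains:
        if dom.end > ref_len:
            raise DomainTableError(
                f"domain {dom.label!r} span {dom.start}..{dom.end} exceeds "
                f"reference length {ref_len}"
            )
        ids = []
        for aln in (aln_a, aln_b):
            c0 = map_ref_position_to_column(aln, dom.start)
            c1 = map_ref_position_to_column(aln, dom.end)
            ids.append(percent_identity(aln, columns=range(c0, c1 + 1)))
        identity_a, identity_b = ids
        if identity_a is None or identity_b is None:
            delta, flagged = None, False
        else:
            delta = identity_b - identity_a
            flagged = abs(delta) > flag_threshold
        records.append(
            DomainConservationRecord(
                annotation=dom,
                identity_a=identity_a,
                identity_b=identity_b,
                delta=delta,
                flagged=flagged,
            )
        )
    return records


def proteinwide_identity(aln: PairwiseAlignment) -> float | None:
    """Percent identity over the full alignment (all reference residues)."""
    return percent_identity(aln)


def records_to_frame(records: list[DomainConservationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        a = r.annotation
        rows.append(
            {
                "label": a.label,
                "class": a.klass,
                "channel_domain": a.channel_domain or "",
                "start": a.start,
                "end": a.end,
                "identity_a": math.nan if r.identity_a is None else r.identity_a,
                "identity_b": math.nan if r.identity_b is None else r.identity_b,
                "delta": math.nan if r.delta is None else r.delta,
                "flagged": r.flagged,
                "short_peptide": a.short_peptide,
            }
        )
    return pd.DataFrame(rows)


def write_conservation_report(
    records: list[DomainConservationRecord], path: str | Path
) -> str:
    """Write the per-domain TSV and return a one-line text summary."""
    if not records:
        raise DomainTableError("no conservation records to write")
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)
    n_flagged = int(df["flagged"].sum())
    summary = (
        f"{len(df)} domains scored, {n_flagged} flagged "
        f"(>|{FLAG_THRESHOLD:.0f}| percentage-point conservation difference)"
    )
    return summary


def read_conservation_report(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the report TSV."""
    return pd.read_csv(path, sep="\t", dtype={"channel_domain": "string"}).fillna(
        {"channel_domain": ""}
    )
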