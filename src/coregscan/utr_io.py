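"""Reading, normalizing and annotating 3'UTR sequence records.

Sequences are handled as uppercase RNA over ``{A, C, G, U, N}``.  Coordinates
are 1-based inclusive with position 1 being the first nucleotide after the
stop codon; BED export converts to the 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from Bio import SeqIO

_RNA_ALPHABET = frozenset("ACGUN")
_TO_RNA = str.maketrans("Tt", "UU")


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to uppercase RNA (T -> U).

    Idempotent; any character outside ``{A,C,G,T,U,N}`` (case-insensitive)
    raises ``ValueError``.
    """
    if not seq:
        raise ValueError("empty sequence")
    out = seq.translate(_TO_RNA).upper()
    bad = set(out) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return out


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence with gene/transcript identity.

    ``sequence`` is normalized RNA; position 1 is the first nt after the
    stop codon.
    """

    gene_id: str
    transcript_accession: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """Read UTR records from FASTA.

    Headers are parsed as ``gene|accession`` (pipe-delimited) or a bare
    identifier (accession then empty).  Sequences are normalized to RNA.
    """
    records: list[UTRRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = entry.id.split("|")
        gene_id = fields[0]
        accession = fields[1] if len(fields) > 1 else ""
        try:
            seq = to_rna(str(entry.seq))
        except ValueError as exc:
            raise ValueError(f"record {entry.id!r}: {exc}") from exc
        records.append(UTRRecord(gene_id, accession, seq))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_utr_fasta(records: Iterable[UTRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.gene_id
            if rec.transcript_accession:
                header += f"|{rec.transcript_accession}"
            fh.write(f">{header}\n{rec.sequence}\n")


def mutate_site(record: UTRRecord, start: int, replacement: str) -> UTRRecord:
    """Replace positions ``[start, start+len-1]`` (1-based) with ``replacement``.

    Returns a new record of unchanged length; used e.g. to destroy a PRE core
    (UGUA -> ACAC) as in reporter mutagenesis.
    """
    repl = to_rna(replacement)
    if start < 1 or start + len(repl) - 1 > record.length:
        raise ValueError(
            f"replacement [{start}, {start + len(repl) - 1}] out of range "
            f"for record of length {record.length}"
        )
    seq = record.sequence
    new_seq = seq[: start - 1] + repl + seq[start - 1 + len(repl) :]
    return replace(record, sequence=new_seq)


def truncate_utr(record: UTRRecord, length: int) -> UTRRecord:
    """Restrict a record to positions ``[1, length]``."""
    if length < 1 or length > record.length:
        raise ValueError(f"length {length} outside [1, {record.length}]")
    return replace(record, sequence=record.sequence[:length])


class LocatedMotif(Protocol):
    """Anything placeable on a UTR: 1-based inclusive span plus a class label."""

    record_id: str
    start: int
    end: int

    @property
    def bed_name(self) -> str: ...


def write_annotations(
    records: Sequence[UTRRecord],
    hits: Sequence[LocatedMotif],
    path: str | Path,
) -> None:
    """Write motif hits as BED6 (0-based half-open; start-1, end unchanged).

    The name column is the motif class; rows sort by (record, start) with
    ties broken by class name.
    """
    known = {r.gene_id for r in records}
    for hit in hits:
        if hit.record_id not in known:
            raise ValueError(f"hit references unknown record {hit.record_id!r}")
    rows = sorted(hits, key=lambda h: (h.record_id, h.start, h.bed_name))
    with open(path, "w") as fh:
        for h in rows:
            fh.write(f"{h.record_id}\t{h.start - 1}\t{h.end}\t{h.bed_name}\t0\t+\n")


def bed_interval_to_internal(bed_start: int, bed_end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    return bed_start + 1, bed_end


def internal_interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open BED."""
    return start - 1, end
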