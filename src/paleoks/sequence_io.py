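"""Reading, validating and translating coding sequences.

A :class:`CodingSequence` is a frame-0 CDS whose length is a multiple of 3,
made only of unambiguous bases, with no internal stop codon; a single terminal
stop is stripped on ingest so that downstream codon alignments contain sense
codons only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import STOP_CODONS

_VALID_BASES = frozenset("ACGT")


class CDSValidationError(ValueError):
    """A record violating the CodingSequence invariants; ``reason`` is short
    and machine-readable (it ends up in the validation TSV)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string under the standard genetic
    code; stop codons render as ``*``.

    Raises ``ValueError`` naming the first offending position for characters
    outside {A, C, G, T} and for lengths not divisible by 3.
    """
    nt = nt.upper()
    for pos, base in enumerate(nt):
        if base not in _VALID_BASES:
            raise ValueError(f"invalid character {base!r} at position {pos}")
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise ValueError("length not multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS with its conceptual translation."""

    id: str
    nt: str
    aa: str

    def __len__(self) -> int:
        return len(self.nt)


def validate_cds(seq_id: str, nt: str, mask_ambiguous: bool = False) -> CodingSequence:
    """Validate a raw nucleotide string into a :class:`CodingSequence`.

    ``mask_ambiguous=True`` excises codons containing ambiguity codes instead
    of rejecting the record (the stored sequence then skips those codons).
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise CDSValidationError("length not multiple of 3")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if any(set(c) - _VALID_BASES for c in codons):
        if not mask_ambiguous:
            raise CDSValidationError("ambiguous bases")
        codons = [c for c in codons if not set(c) - _VALID_BASES]
        if not codons:
            raise CDSValidationError("no unambiguous codons")
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
        if not codons:
            raise CDSValidationError("only a stop codon")
    if any(c in STOP_CODONS for c in codons):
        raise CDSValidationError("internal stop")
    clean = "".join(codons)
    return CodingSequence(id=seq_id, nt=clean, aa=translate(clean))


class SequenceSet:
    """Ordered collection of :class:`CodingSequence` with unique ids.

    ``rejected`` keeps (id, reason) tuples for records that failed validation
    during :func:`read_cds_fasta`.
    """

    def __init__(self, records, source_label: str = "", rejected=None):
        self.records: list[CodingSequence] = list(records)
        self.source_label = source_label
        self.rejected: list[tuple[str, str]] = list(rejected or [])
        self._by_id = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> CodingSequence:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_cds_fasta(path, source_label: str | None = None, mask_ambiguous: bool = False) -> SequenceSet:
    """Read a nucleotide FASTA of coding sequences, validating every record.

    Records failing validation are excluded and reported in ``.rejected``
    with a reason; ids take the description up to the first whitespace.
    Raises on an unreadable file or when no record validates.
    """
    path = Path(path)
    records, rejected, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            rejected.append((rec.id, "duplicate id"))
            continue
        seen.add(rec.id)
        try:
            records.append(validate_cds(rec.id, str(rec.seq), mask_ambiguous=mask_ambiguous))
        except CDSValidationError as exc:
            rejected.append((rec.id, exc.reason))
    if not records:
        raise ValueError(f"no valid coding sequences in {path}")
    return SequenceSet(records, source_label=source_label or path.stem, rejected=rejected)


def write_fasta(seqs: SequenceSet, path, protein: bool = False, width: int = 60) -> None:
    """Write the set as FASTA (nucleotide by default, protein on request)."""
    recs = [
        SeqRecord(Seq(r.aa if protein else r.nt), id=r.id, description="")
        for r in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_validation_report(seqs: SequenceSet, path) -> None:
    """TSV of rejected records: id <tab> reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "reason"])
        for seq_id, reason in seqs.rejected:
            w.writerow([seq_id, reason])
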