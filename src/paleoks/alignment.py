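"""Pairwise protein alignment and codon back-translation.

Local (Smith-Waterman) alignment with Karlin-Altschul E-value statistics
screens for homologs; global (Needleman-Wunsch) alignment of family members
feeds codon back-translation for Ks estimation.  Both aligners run with
BLOSUM62 and BLAST-style affine gap costs (open 11, extend 1: a gap of
length g costs 11 + g) so decisions mirror default BLASTP behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import CodingSequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: published gapped Karlin-Altschul constants for BLOSUM62 11/1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class LocalHit:
    """A significant local alignment between two proteins."""

    query_id: str
    subject_id: str
    score: float
    aligned_length: int  # aligned residue pairs, gap columns excluded
    identity: float
    evalue: float | None = None

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.query_id, self.subject_id)))


def make_aligner(mode: str, matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0):
    """A configured ``PairwiseAligner``; gap costs follow the BLAST convention
    (first gapped residue costs open+extend)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else BLOSUM62
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _aligned_stats(alignment, a: str, b: str) -> tuple[int, int]:
    """(aligned residue pairs, identical pairs) over gap-free columns."""
    length = matches = 0
    for (astart, aend), (bstart, bend) in zip(*alignment.aligned):
        length += aend - astart
        matches = matches + sum(
            a[astart + k] == b[bstart + k] for k in range(aend - astart)
        )
    return length, matches


def smith_waterman(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalHit | None:
    """Optimal local alignment under affine gaps; ``None`` when no positive-
    scoring local alignment exists."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = make_aligner("local", matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    alignment = aligner.align(a, b)[0]
    length, matches = _aligned_stats(alignment, a, b)
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        aligned_length=length,
        identity=matches / length if length else 0.0,
    )


def evalue(score: float, m: int, n: int, lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score).

    ``n`` is the subject length, or the searched set's total residue count in
    a database-style search.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if lam <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return K * m * n * math.exp(-lam * score)


def needleman_wunsch(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Optimal global alignment; returns the two gapped rows (equal length)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = make_aligner("global", matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free codon columns of a pair of CDS, via their protein alignment."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def columns(self):
        return zip(self.codons_a, self.codons_b)


def backtranslate(
    protein_alignment: tuple[str, str],
    cds_a: CodingSequence,
    cds_b: CodingSequence,
) -> CodonAlignment:
    """Map a gapped protein alignment back onto the two CDS.

    Columns where either row is a gap are dropped; the ungapped rows must
    equal the CDS translations exactly.
    """
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    for row, cds, name in ((row_a, cds_a, "first"), (row_b, cds_b, "second")):
        ungapped = row.replace("-", "")
        if ungapped != cds.aa:
            for k, (x, y) in enumerate(zip(ungapped, cds.aa)):
                if x != y:
                    raise ValueError(
                        f"{name} row mismatches translation at residue {k}: {x!r} != {y!r}"
                    )
            raise ValueError(f"{name} row length mismatches translation")
    codons_a, codons_b = [], []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            codons_a.append(cds_a.nt[3 * ia : 3 * ia + 3])
            codons_b.append(cds_b.nt[3 * ib : 3 * ib + 3])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if not codons_a:
        raise ValueError("no gap-free columns")
    return CodonAlignment(
        gene_a=cds_a.id,
        gene_b=cds_b.id,
        codons_a=tuple(codons_a),
        codons_b=tuple(codons_b),
    )


def align_codon_pair(cds_a: CodingSequence, cds_b: CodingSequence, **kwargs) -> CodonAlignment:
    """Convenience: global protein alignment + back-translation."""
    return backtranslate(needleman_wunsch(cds_a.aa, cds_b.aa, **kwargs), cds_a, cds_b)
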