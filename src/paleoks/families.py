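"""Gene-family construction from all-vs-all protein similarity.

Two-tier thresholds: hits at E <= 1e-5 define family membership (single
linkage over the hit graph); the stricter gate (aligned length > 100 residues
and E < 1e-15) selects which pairs are retained for the Ks age distribution.
"""

from __future__ import annotations

import csv
import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .alignment import (
    DEFAULT_K,
    DEFAULT_LAMBDA,
    LocalHit,
    _aligned_stats,
    evalue,
    make_aligner,
)
from .sequence_io import SequenceSet

FAMILY_EVALUE = 1e-5
PAIR_EVALUE = 1e-15
PAIR_MIN_LENGTH = 100


@dataclass
class GeneFamily:
    """A connected set of paralogous genes.

    A family of n members descends from n-1 retained single-gene
    duplications, while it offers n(n-1)/2 pairwise comparisons; the
    redundancy between the two is what node weighting later corrects.
    """

    family_id: str
    member_ids: tuple[str, ...]
    hits: list[LocalHit] = field(default_factory=list)
    retained_pairs: list[LocalHit] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def all_pairs(self):
        return itertools.combinations(self.member_ids, 2)


def _kmer_candidates(seqs: SequenceSet, k: int = 5, min_shared: int = 2, bucket_cap: int = 500):
    """Deterministic candidate pairs: protein pairs sharing >= ``min_shared``
    distinct k-mers.  A cheap screen so the exact aligner only runs on pairs
    that could plausibly score; k-mer buckets larger than ``bucket_cap`` are
    skipped (low-complexity words)."""
    index = defaultdict(list)
    for idx, rec in enumerate(seqs):
        for kmer in {rec.aa[i : i + k] for i in range(len(rec.aa) - k + 1)}:
            index[kmer].append(idx)
    counts: Counter = Counter()
    for members in index.values():
        if 1 < len(members) <= bucket_cap:
            for pair in itertools.combinations(members, 2):
                counts[pair] += 1
    return sorted(p for p, c in counts.items() if c >= min_shared)


def all_vs_all(
    seqs: SequenceSet,
    family_evalue: float = FAMILY_EVALUE,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    prefilter: str | None = "kmer",
    kmer_size: int = 5,
    min_shared_kmers: int = 2,
) -> list[LocalHit]:
    """Score every unordered pair once and keep hits with E <= threshold.

    E-values are database-style: n is the total residue count of the set.
    ``prefilter="kmer"`` (default) restricts exact alignment to pairs sharing
    k-mers; ``prefilter=None`` scores all pairs exactly.
    """
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    n_db = sum(len(r.aa) for r in records)
    if prefilter == "kmer":
        candidates = _kmer_candidates(seqs, k=kmer_size, min_shared=min_shared_kmers)
    elif prefilter is None:
        candidates = itertools.combinations(range(len(records)), 2)
    else:
        raise ValueError(f"unknown prefilter {prefilter!r}")

    aligner = make_aligner("local", matrix, gap_open, gap_extend)
    hits = []
    for i, j in candidates:
        a, b = records[i], records[j]
        score = aligner.score(a.aa, b.aa)
        if score <= 0:
            continue
        e = evalue(score, len(a.aa), n_db, lam=lam, K=K)
        if e > family_evalue:
            continue
        alignment = aligner.align(a.aa, b.aa)[0]
        length, matches = _aligned_stats(alignment, a.aa, b.aa)
        hits.append(
            LocalHit(
                query_id=a.id,
                subject_id=b.id,
                score=float(score),
                aligned_length=length,
                identity=matches / length if length else 0.0,
                evalue=e,
            )
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def build_families(
    hits: list[LocalHit],
    pair_min_length: int = PAIR_MIN_LENGTH,
    pair_evalue: float = PAIR_EVALUE,
) -> list[GeneFamily]:
    """Families = connected components of the significant-hit graph;
    ``retained_pairs`` additionally require aligned_length > pair_min_length
    (strict) and E < pair_evalue (strict).  Singletons never appear (a hit
    always involves two genes)."""
    graph = nx.Graph()
    for h in hits:
        graph.add_edge(*h.pair())
    by_pair = {h.pair(): h for h in hits}
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    families = []
    for idx, members in enumerate(components):
        fam_hits = [
            by_pair[pair]
            for pair in itertools.combinations(members, 2)
            if pair in by_pair
        ]
        retained = [
            h
            for h in fam_hits
            if h.aligned_length > pair_min_length and h.evalue < pair_evalue
        ]
        families.append(
            GeneFamily(
                family_id=f"F{idx:05d}",
                member_ids=members,
                hits=fam_hits,
                retained_pairs=retained,
            )
        )
    return families


def write_hits_tsv(hits, path) -> None:
    """Tabular hits, outfmt-6-like column order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query", "subject", "score", "aligned_length", "identity", "evalue"])
        for h in hits:
            w.writerow(
                [h.query_id, h.subject_id, f"{h.score:g}", h.aligned_length,
                 f"{h.identity:.4f}", f"{h.evalue:.3e}"]
            )


def write_families_tsv(families, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "member_id"])
        for fam in families:
            for m in fam.member_ids:
                w.writerow([fam.family_id, m])
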