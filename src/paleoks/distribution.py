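"""Redundancy-corrected Ks age distributions.

An n-member family offers n(n-1)/2 pairwise Ks values but represents only
n-1 duplication events; left uncorrected, large families dominate the age
distribution.  Node weighting fixes this: family members are clustered by
average linkage on their pairwise Ks, each internal node of the resulting
tree is one duplication event, every pair is assigned to the node that joins
its two members, and the pairs of a node share a total weight of one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

MIN_KS = 0.1
MAX_KS = 5.0
BIN_WIDTH = 0.1
PEAK_WINDOW = (0.9, 1.5)


@dataclass(frozen=True)
class WeightedKs:
    """One paralog pair's Ks with its duplication-node assignment."""

    family_id: str
    id_a: str
    id_b: str
    ks: float
    weight: float
    node_id: str


def node_weight(family_id: str, member_ids, ks_by_pair: dict) -> list[WeightedKs]:
    """Assign duplication-node weights to a family's pairwise Ks values.

    ``ks_by_pair`` maps unordered id pairs to Ks; pairs with missing or
    non-finite Ks take no part (a saturated-only family yields nothing).
    Weights of the pairs assigned to one node sum to exactly 1.
    """
    members = sorted(member_ids)
    n = len(members)

    def get_ks(a, b):
        v = ks_by_pair.get((a, b), ks_by_pair.get((b, a), np.nan))
        return v if v is not None else np.nan

    finite = {
        (a, b): get_ks(a, b)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if np.isfinite(get_ks(a, b))
    }
    if not finite:
        return []
    if n == 2:
        (a, b), ks = next(iter(finite.items()))
        return [WeightedKs(family_id, a, b, float(ks), 1.0, f"{family_id}.n0")]

    fill = 2.0 * max(finite.values()) + 1.0
    dist = np.full((n, n), fill)
    np.fill_diagonal(dist, 0.0)
    idx = {m: i for i, m in enumerate(members)}
    for (a, b), ks in finite.items():
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = ks
    merge = linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, list[str]] = {i: [m] for i, m in enumerate(members)}
    out = []
    for node, row in enumerate(merge):
        left, right = clusters.pop(int(row[0])), clusters.pop(int(row[1]))
        pairs = [
            tuple(sorted((a, b)))
            for a in left
            for b in right
            if tuple(sorted((a, b))) in finite
        ]
        if pairs:
            w = 1.0 / len(pairs)
            node_id = f"{family_id}.n{node}"
            for a, b in sorted(pairs):
                out.append(WeightedKs(family_id, a, b, float(finite[(a, b)]), w, node_id))
        clusters[n + node] = left + right
    return out


def filter_ks(pairs, min_ks: float = MIN_KS, max_ks: float = MAX_KS):
    """Keep pairs with min_ks <= ks <= max_ks (both endpoints inclusive);
    weights are left untouched."""
    return [p for p in pairs if min_ks <= p.ks <= max_ks]


@dataclass(frozen=True)
class KsHistogram:
    """Weighted Ks histogram on a fixed 0.1-wide grid over [0, max]."""

    bin_edges: np.ndarray
    bin_weights: np.ndarray

    @property
    def total_weight(self) -> float:
        return float(self.bin_weights.sum())

    def relative_frequencies(self) -> np.ndarray:
        total = self.total_weight
        return self.bin_weights / total if total > 0 else self.bin_weights


def histogram(pairs, bin_width: float = BIN_WIDTH, max_ks: float = MAX_KS) -> KsHistogram:
    """Half-open bins [x, x+w) over [0, max_ks], last bin closed; bar height
    is summed pair weight."""
    edges = np.round(np.arange(0.0, max_ks + bin_width / 2, bin_width), 10)
    ks = np.array([p.ks for p in pairs], dtype=float)
    w = np.array([p.weight for p in pairs], dtype=float)
    if ks.size:
        counts, _ = np.histogram(ks, bins=edges, weights=w)
    else:
        counts = np.zeros(len(edges) - 1)
    return KsHistogram(bin_edges=edges, bin_weights=counts)


def select_peak_duplicates(
    pairs,
    peak_mean: float,
    window_lo: float = PEAK_WINDOW[0],
    window_hi: float = PEAK_WINDOW[1],
    rule: str = "nearest-peak",
) -> dict[str, WeightedKs]:
    """One representative duplicate pair per family from the WGD peak window.

    Among each family's pairs with Ks in [window_lo, window_hi], keep the
    pair closest to the fitted peak mean (ties to the smaller Ks);
    ``rule="nearest-boundary"`` instead minimises distance to the nearer
    window edge.  Families with no in-window pair are absent.
    """
    if rule not in ("nearest-peak", "nearest-boundary"):
        raise ValueError(f"unknown rule {rule!r}")
    chosen: dict[str, WeightedKs] = {}
    for p in pairs:
        if not (window_lo <= p.ks <= window_hi):
            continue
        if rule == "nearest-peak":
            key = (abs(p.ks - peak_mean), p.ks)
        else:
            key = (min(abs(p.ks - window_lo), abs(p.ks - window_hi)), p.ks)
        cur = chosen.get(p.family_id)
        if cur is None or key < cur[0]:
            chosen[p.family_id] = (key, p)
    return {fid: p for fid, (_, p) in chosen.items()}


def write_weighted_tsv(pairs, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "id_a", "id_b", "ks", "weight", "node_id"])
        for p in pairs:
            w.writerow([p.family_id, p.id_a, p.id_b, f"{p.ks:.6f}", f"{p.weight:.6g}", p.node_id])


def write_histogram_tsv(hist: KsHistogram, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bin_lo", "bin_hi", "weight"])
        for lo, hi, wt in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.bin_weights):
            w.writerow([f"{lo:.1f}", f"{hi:.1f}", f"{wt:.6g}"])
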