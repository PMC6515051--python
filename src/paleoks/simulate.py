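"""Synthetic transcriptome-like paralog populations with known ground truth.

The generator emulates the statistical structure a paranome's Ks age
distribution is expected to show: an exponentially decaying background of
small-scale duplications (SSD) — many young pairs, ever fewer old ones, the
"L shape" — plus one or more WGD bursts, log-normal on the Ks scale.  Each
family's duplication history is realised as an ultrametric tree in Ks units
and actual codon sequences are evolved along it under the same GY94 model
the ML estimator fits, so simulated truth and estimated Ks share one
definition of a synonymous site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .codon import SENSE_CODONS, CodonModel, frequencies_from_nucleotide_weights
from .sequence_io import CodingSequence, SequenceSet, translate

#: slightly AT-rich base composition, transcriptome-like
DEFAULT_NUCLEOTIDE_FREQS = {"A": 0.28, "C": 0.22, "G": 0.22, "T": 0.28}


@dataclass(frozen=True)
class WgdBurst:
    """One WGD event cohort: log-normal Ks burst."""

    mean_ks: float
    sd_log: float
    fraction: float  # fraction of duplication events drawn from this burst


@dataclass
class SimulationConfig:
    """Generator settings; the defaults describe a 2000-family paranome with
    a steep SSD background (mean Ks 0.4) and one WGD burst at Ks 1.2."""

    n_families: int = 2000
    family_size_distribution: dict = field(default_factory=lambda: {2: 0.7, 3: 0.2, 4: 0.1})
    ssd_rate: float = 2.5  # exponential decay rate of background Ks
    wgd_components: tuple = (WgdBurst(1.2, 0.15, 0.4),)
    kappa: float = 2.0
    omega: float = 0.2
    nucleotide_freqs: dict = field(default_factory=lambda: dict(DEFAULT_NUCLEOTIDE_FREQS))
    gene_length_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        self.wgd_components = tuple(
            c if isinstance(c, WgdBurst) else WgdBurst(*c) for c in self.wgd_components
        )
        if sum(c.fraction for c in self.wgd_components) > 1.0 + 1e-12:
            raise ValueError("WGD fractions exceed 1")
        if self.ssd_rate <= 0:
            raise ValueError("ssd_rate must be positive")

    def codon_model(self) -> CodonModel:
        return CodonModel(
            kappa=self.kappa,
            omega=self.omega,
            codon_freqs=frequencies_from_nucleotide_weights(self.nucleotide_freqs),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _sample_codons(rng, p, size) -> np.ndarray:
    cum = np.cumsum(p)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right")


def _evolve(rng, model: CodonModel, states: np.ndarray, t: float) -> np.ndarray:
    """One branch of length t (substitutions/codon), site-independent."""
    if t <= 0:
        return states.copy()
    cum = np.cumsum(model.transition_matrix(t), axis=1)
    cum[:, -1] = 1.0
    u = rng.random(states.size)
    rows = cum[states]
    return (u[:, None] < rows).argmax(axis=1)


def _states_to_cds(seq_id: str, states: np.ndarray) -> CodingSequence:
    nt = "".join(SENSE_CODONS[s] for s in states)
    return CodingSequence(id=seq_id, nt=nt, aa=translate(nt))


def simulate_codon_pair(
    true_ks: float,
    model: CodonModel,
    length: int,
    seed=0,
    ids: tuple[str, str] = ("pair_a", "pair_b"),
) -> tuple[CodingSequence, CodingSequence]:
    """Two descendants of a common ancestor at expected synonymous divergence
    ``true_ks`` between them (each branch carries half).  The ancestor is
    drawn from the model's equilibrium; no stop codons can arise (the chain
    lives on the 61 sense codons)."""
    if true_ks < 0:
        raise ValueError("true_ks must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _sample_codons(rng, model.pi, length)
    branch = model.t_for_ks(true_ks) / 2.0
    a = _evolve(rng, model, anc, branch)
    b = _evolve(rng, model, anc, branch)
    return _states_to_cds(ids[0], a), _states_to_cds(ids[1], b)


def _draw_event(rng, config: SimulationConfig) -> tuple[float, str]:
    """(Ks age, origin label) of one duplication event."""
    u = rng.random()
    acc = 0.0
    for i, comp in enumerate(config.wgd_components):
        acc += comp.fraction
        if u < acc:
            ks = float(np.exp(rng.normal(np.log(comp.mean_ks), comp.sd_log)))
            return ks, f"WGD_{i}"
    return float(rng.exponential(1.0 / config.ssd_rate)), "SSD"


def _simulate_family(rng, config, model, family_id: str, size: int, sequences: bool):
    """Sample a duplication history (random ultrametric tree whose node
    heights are event ages in Ks/2 units), evolve sequences along it, and
    report every leaf pair with the Ks and origin of its joining event."""
    events = sorted(
        (_draw_event(rng, config) for _ in range(size - 1)),
        key=lambda e: -e[0],
    )
    # build top-down: each event splits one uniformly chosen live lineage
    class _Node:
        __slots__ = ("height", "event", "left", "right", "leaf")

        def __init__(self, height=0.0, event=None, leaf=None):
            self.height = height
            self.event = event
            self.left = self.right = None
            self.leaf = leaf

    root = _Node(leaf=0)
    live = [root]
    for ev in events:
        node = live[int(rng.integers(len(live)))]
        node.height = ev[0] / 2.0
        node.event = ev
        node.left = _Node(leaf=node.leaf)
        node.right = _Node(leaf=None)
        node.leaf = None
        live.remove(node)
        live.extend([node.left, node.right])

    # assign leaf ids in deterministic (left-to-right) order
    leaves = []

    def _collect(node):
        if node.left is None:
            node.leaf = len(leaves)
            leaves.append(node)
        else:
            _collect(node.left)
            _collect(node.right)

    _collect(root)
    ids = [f"{family_id}_g{i + 1}" for i in range(len(leaves))]

    seqs = []
    if sequences:
        anc = _sample_codons(rng, model.pi, config.gene_length_codons)
        out_states = {}

        def _down(node, states, height_from):
            # heights are in Ks/2 units: a branch spanning h accumulates an
            # expected synonymous divergence of h, so two sister paths from a
            # node at height v/2 are ks = v apart, matching the event's age
            span = height_from - node.height
            states = _evolve(rng, model, states, model.t_for_ks(2.0 * span) / 2.0)
            if node.left is None:
                out_states[node.leaf] = states
            else:
                _down(node.left, states, node.height)
                _down(node.right, states, node.height)

        root_height = root.height if root.left is not None else 0.0
        # the root sequence sits at the deepest event; no stem branch above it
        if root.left is None:
            out_states[root.leaf] = anc
        else:
            _down(root.left, anc, root_height)
            _down(root.right, anc, root_height)
        seqs = [_states_to_cds(ids[i], out_states[i]) for i in range(len(leaves))]

    # pairwise truth: MRCA height -> event
    rows = []

    def _pairs(node):
        if node.left is None:
            return [node.leaf]
        left = _pairs(node.left)
        right = _pairs(node.right)
        for i in left:
            for j in right:
                a, b = sorted((i, j))
                rows.append(
                    {
                        "family_id": family_id,
                        "id_a": ids[a],
                        "id_b": ids[b],
                        "true_ks": node.event[0],
                        "origin": node.event[1],
                    }
                )
        return left + right

    _pairs(root)
    rows.sort(key=lambda r: (r["id_a"], r["id_b"]))
    return seqs, rows


def simulate_population(
    config: SimulationConfig, sequences: bool = True
) -> tuple[SequenceSet | None, pd.DataFrame]:
    """Generate a whole paralog population.

    Returns the realised sequences (None when ``sequences=False``; the truth
    table alone is much cheaper when only Ks values are needed) and a truth
    table with one row per within-family pair: family_id, id_a, id_b,
    true_ks, origin in {SSD, WGD_i}.  Fully deterministic under a fixed
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    model = config.codon_model()
    sizes = sorted(config.family_size_distribution)
    size_p = np.array([config.family_size_distribution[s] for s in sizes], dtype=float)
    size_p /= size_p.sum()

    all_seqs, all_rows = [], []
    for f in range(config.n_families):
        size = int(rng.choice(sizes, p=size_p))
        fam_id = f"SF{f:05d}"
        seqs, rows = _simulate_family(rng, config, model, fam_id, size, sequences)
        all_seqs.extend(seqs)
        all_rows.extend(rows)
    truth = pd.DataFrame(all_rows, columns=["family_id", "id_a", "id_b", "true_ks", "origin"])
    seq_set = SequenceSet(all_seqs, source_label="synthetic") if sequences else None
    return seq_set, truth
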