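"""Goldman-Yang (GY94) codon substitution machinery.

Shared by the maximum-likelihood Ks estimator and the sequence simulator so
that both sides use the same definition of a synonymous site: the rate matrix
is normalised to one expected substitution per codon per unit branch length,
and synonymous sites are counted from the synonymous flux of the mutation-only
(omega = 1) model, Yang's convention.  This keeps ``Ks`` as estimated from an
alignment and ``Ks`` as targeted by the simulator on the same scale.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)
AA_OF: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def is_transition(x: str, y: str) -> bool:
    """True when two (differing) bases are both purines or both pyrimidines."""
    return (x in _PURINES) == (y in _PURINES)


def _single_difference_pairs():
    src, dst, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            src.append(i)
            dst.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(AA_OF[ci] == AA_OF[cj])
    return (
        np.asarray(src, dtype=np.intp),
        np.asarray(dst, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


_SRC, _DST, _TS, _SYN = _single_difference_pairs()


def f3x4_frequencies(nt_seqs, pseudocount: float = 0.5) -> np.ndarray:
    """Codon equilibrium frequencies from per-position nucleotide frequencies.

    Counts each codon position's nucleotide composition over all supplied
    in-frame nucleotide strings jointly, then sets pi(codon) proportional to
    the product of its three positional frequencies, renormalised over the 61
    sense codons.  A half-count pseudo-observation per base keeps every
    frequency positive (the chain must stay irreducible even when a base is
    absent at some position).
    """
    counts = np.zeros((3, 4))
    for seq in nt_seqs:
        if len(seq) % 3 != 0:
            raise ValueError("sequence length must be a multiple of 3")
        for pos in range(3):
            for base in seq[pos::3]:
                counts[pos, _BASE_INDEX[base]] += 1
    freqs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    )
    pi = np.array(
        [
            freqs[0, _BASE_INDEX[c[0]]]
            * freqs[1, _BASE_INDEX[c[1]]]
            * freqs[2, _BASE_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def frequencies_from_nucleotide_weights(weights: dict[str, float]) -> np.ndarray:
    """F3x4-style codon frequencies with the same base composition at all
    three codon positions (used to parameterise the simulator)."""
    w = np.array([weights[b] for b in "ACGT"], dtype=float)
    if np.any(w <= 0):
        raise ValueError("nucleotide weights must be positive")
    w = w / w.sum()
    pi = np.array(
        [w[_BASE_INDEX[c[0]]] * w[_BASE_INDEX[c[1]]] * w[_BASE_INDEX[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


class CodonModel:
    """GY94 codon substitution model over the 61 sense codons.

    Parameters
    ----------
    kappa : transition/transversion rate ratio.
    omega : nonsynonymous/synonymous rate ratio (dN/dS).
    codon_freqs : equilibrium frequencies over ``SENSE_CODONS`` (default
        uniform); typically F3x4 estimates.

    The generator matrix is scaled so that the expected number of
    substitutions per codon per unit time is 1 at stationarity.
    """

    def __init__(self, kappa: float = 2.0, omega: float = 0.2, codon_freqs=None):
        if kappa <= 0 or omega <= 0:
            raise ValueError("kappa and omega must be positive")
        if codon_freqs is None:
            pi = np.full(N_SENSE, 1.0 / N_SENSE)
        else:
            pi = np.asarray(codon_freqs, dtype=float)
            if pi.shape != (N_SENSE,) or np.any(pi <= 0):
                raise ValueError("codon_freqs must be %d positive values" % N_SENSE)
            pi = pi / pi.sum()
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.pi = pi

        rates = pi[_DST] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
        Q = np.zeros((N_SENSE, N_SENSE))
        Q[_SRC, _DST] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.Q = Q
        # proportion of the unit substitution flux that is synonymous
        self.rho_s = float((pi[_SRC] * Q[_SRC, _DST])[_SYN].sum())

        self._eig = None
        self._mutation_rho_s = None

    # -- spectral decomposition ------------------------------------------
    def _decompose(self):
        if self._eig is None:
            d = np.sqrt(self.pi)
            B = self.Q * d[:, None] / d[None, :]
            B = (B + B.T) / 2.0  # reversible => symmetric up to round-off
            w, U = np.linalg.eigh(B)
            self._eig = (w, U, d)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows renormalised to remove round-off."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, U, d = self._decompose()
        P = (U * np.exp(w * t)) @ U.T
        P = P / d[:, None] * d[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    # -- site counting (Yang's convention) -------------------------------
    @property
    def syn_flux_fraction_neutral(self) -> float:
        """rho_S of the omega=1 model: the fraction of mutational flux that is
        synonymous, i.e. the proportion of synonymous sites (S / 3L)."""
        if self.omega == 1.0:
            return self.rho_s
        if self._mutation_rho_s is None:
            self._mutation_rho_s = CodonModel(self.kappa, 1.0, self.pi).rho_s
        return self._mutation_rho_s

    def ks_ka_from_t(self, t: float) -> tuple[float, float]:
        """Decompose a total divergence of ``t`` substitutions/codon into
        synonymous and nonsynonymous substitutions per site."""
        rs1 = self.syn_flux_fraction_neutral
        ks = t * self.rho_s / (3.0 * rs1)
        ka = t * (1.0 - self.rho_s) / (3.0 * (1.0 - rs1))
        return ks, ka

    def t_for_ks(self, ks: float) -> float:
        """Total branch length (substitutions/codon) between two sequences
        whose expected synonymous divergence is ``ks``."""
        if ks < 0:
            raise ValueError("ks must be non-negative")
        return ks * 3.0 * self.syn_flux_fraction_neutral / self.rho_s
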