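"""Synonymous and nonsynonymous divergence of a codon alignment.

Two estimators of the same quantity:

* :func:`ng86` — Nei-Gojobori (1986) counting with Jukes-Cantor correction.
  Closed-form and hand-checkable; used as the oracle and as the starting
  point for the likelihood fit.
* :func:`ml_ks` — pairwise maximum likelihood under the GY94 codon model
  with F3x4 frequencies and free (t, kappa, omega), the estimator family
  CODEML implements.  Ks and Ka are decomposed from the fitted branch length
  by Yang's flux convention (see :mod:`paleoks.codon`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .codon import AA_OF, CODON_INDEX, N_SENSE, STOP_CODONS, CodonModel, f3x4_frequencies

T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 10.0)
MIN_CODONS_RECOMMENDED = 30


@dataclass(frozen=True)
class KsEstimate:
    """Per-pair divergence estimate.

    ``ks``/``ka`` are substitutions per synonymous / nonsynonymous site;
    ``t`` is the total branch length in substitutions per codon; ``saturated``
    marks estimates beyond the reliable range (pS >= 3/4 for NG86, branch
    length at its upper bound for ML).
    """

    ks: float
    ka: float
    omega: float
    t: float
    kappa: float | None
    method: str
    saturated: bool
    n_codons: int
    loglik: float | None = None
    converged: bool = True


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """NG86 synonymous sites of one codon: at each position, the fraction of
    the viable (non-stop) single-base changes that are synonymous.  Stop
    mutations are removed from the opportunity space entirely — sense codons
    are the only viable states — which keeps the site normalisation on the
    same footing as the 61-state codon model used for ML estimation and
    simulation.  (Implementations that instead count stop changes as
    nonsynonymous opportunities give Ks values a few percent lower on
    stop-adjacent codons.)"""
    total = 0.0
    for pos in range(3):
        syn = viable = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            viable += 1
            if AA_OF[alt] == AA_OF[codon]:
                syn += 1
        if viable:
            total += syn / viable
    return total


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all mutational pathways; pathways through stop codons are
    excluded (all pathways used if every ordering is blocked)."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0
        current = c1
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nonsyn += 1
            elif current in STOP_CODONS:
                nonsyn += 1
            elif AA_OF[current] == AA_OF[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn, blocked

    results = [walk(order) for order in itertools.permutations(positions)]
    valid = [(s, n) for s, n, blocked in results if not blocked]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei-Gojobori counting estimate for a codon alignment."""
    if aln.n_codons < 1:
        raise ValueError("empty alignment")
    s_a = sum(_syn_sites(c) for c in aln.codons_a)
    s_b = sum(_syn_sites(c) for c in aln.codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * aln.n_codons - S
    sd = nd = 0.0
    for ca, cb in aln.columns():
        ds, dn = _pair_differences(ca, cb)
        sd += ds
        nd += dn
    if S <= 0:
        raise ValueError("zero synonymous sites; Ks undefined")
    p_s = sd / S
    p_n = nd / N
    ks = _jukes_cantor(p_s)
    ka = _jukes_cantor(p_n)
    saturated = ks is None
    ks_val = np.nan if ks is None else float(ks)
    ka_val = np.nan if ka is None else float(ka)
    omega = ka_val / ks_val if (not saturated and ks_val > 0 and np.isfinite(ka_val)) else np.nan
    if np.isfinite(ks_val) and np.isfinite(ka_val):
        t = 3.0 * (S * ks_val + N * ka_val) / (S + N)
    else:
        t = np.nan
    return KsEstimate(
        ks=ks_val, ka=ka_val, omega=float(omega), t=float(t), kappa=None,
        method="NG86", saturated=saturated, n_codons=aln.n_codons,
    )


def _pair_counts(aln: CodonAlignment):
    idx_a = np.array([CODON_INDEX[c] for c in aln.codons_a], dtype=np.intp)
    idx_b = np.array([CODON_INDEX[c] for c in aln.codons_b], dtype=np.intp)
    counts = np.zeros((N_SENSE, N_SENSE))
    np.add.at(counts, (idx_a, idx_b), 1.0)
    ii, jj = np.nonzero(counts)
    return ii, jj, counts[ii, jj]


def ml_ks(
    aln: CodonAlignment,
    kappa_init: float = 2.0,
    ftol: float = 1e-8,
) -> KsEstimate:
    """Maximum-likelihood (GY94 + F3x4) estimate of Ks/Ka for one pair.

    The pair likelihood is sum over columns of ln(pi_x * P_xy(t)), maximised
    over (t, kappa, omega) on the log scale with L-BFGS-B from an
    NG86-informed start.  Falls back to NG86 (flagged) if the optimiser fails
    to improve on the start point.
    """
    if aln.n_codons < MIN_CODONS_RECOMMENDED:
        warnings.warn(
            f"only {aln.n_codons} codons; ML Ks is unreliable below "
            f"{MIN_CODONS_RECOMMENDED}",
            stacklevel=2,
        )
    pi = f3x4_frequencies(["".join(aln.codons_a), "".join(aln.codons_b)])
    ii, jj, cc = _pair_counts(aln)
    log_pi_i = np.log(pi[ii])

    def negloglik(x):
        t, kappa, omega = np.exp(x)
        model = CodonModel(kappa=kappa, omega=omega, codon_freqs=pi)
        P = model.transition_matrix(t)
        vals = np.maximum(P[ii, jj], 1e-300)
        return -float(np.sum(cc * (log_pi_i + np.log(vals))))

    start_est = ng86(aln)
    ks0 = start_est.ks if np.isfinite(start_est.ks) and start_est.ks > 0 else 2.0
    ka0 = start_est.ka if np.isfinite(start_est.ka) else ks0 * 0.3
    omega0 = np.clip(ka0 / ks0 if ks0 > 0 and ka0 > 0 else 0.3, 1e-3, 5.0)
    start_model = CodonModel(kappa=kappa_init, omega=float(omega0), codon_freqs=pi)
    t0 = np.clip(start_model.t_for_ks(ks0), *T_BOUNDS)
    x0 = np.log([t0, kappa_init, float(omega0)])
    bounds = [np.log(T_BOUNDS), np.log(KAPPA_BOUNDS), np.log(OMEGA_BOUNDS)]

    ll_start = -negloglik(x0)
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": ftol, "maxiter": 500})
    ll_opt = -res.fun
    if not np.isfinite(ll_opt) or ll_opt < ll_start:
        # optimiser failed outright: report the NG86 estimate, flagged
        return KsEstimate(
            ks=start_est.ks, ka=start_est.ka, omega=start_est.omega,
            t=start_est.t, kappa=kappa_init, method="NG86",
            saturated=start_est.saturated, n_codons=aln.n_codons,
            loglik=ll_start, converged=False,
        )
    t, kappa, omega = np.exp(res.x)
    model = CodonModel(kappa=kappa, omega=omega, codon_freqs=pi)
    ks, ka = model.ks_ka_from_t(t)
    saturated = t >= T_BOUNDS[1] * (1 - 1e-6)
    return KsEstimate(
        ks=float(ks), ka=float(ka), omega=float(omega), t=float(t),
        kappa=float(kappa), method="ML", saturated=saturated,
        n_codons=aln.n_codons, loglik=float(ll_opt), converged=bool(res.success),
    )


def estimate_ks(aln: CodonAlignment, method: str = "ML") -> KsEstimate:
    """Dispatch on estimator name ("ML" or "NG86")."""
    if method == "ML":
        return ml_ks(aln)
    if method == "NG86":
        return ng86(aln)
    raise ValueError(f"unknown method {method!r}")
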