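"""Absolute dating of Ks peaks and comparison of Ks distributions.

Under an approximately constant synonymous substitution rate r (per site per
year), a duplicate pair at divergence Ks split T = Ks / (2 r) years ago —
the factor 2 because substitutions accumulate along both descendant
lineages.  The same identity run backwards converts an independently dated
peak into a lineage-specific rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

#: average plant synonymous substitution rate (substitutions/site/year)
PLANT_AVERAGE_RATE = 6.1e-9


@dataclass(frozen=True)
class DatingResult:
    """A Ks peak tied to a substitution rate and an absolute age."""

    ks_peak: float
    rate: float  # substitutions per synonymous site per year
    age_years: float
    mode: str  # "age-from-rate" or "rate-from-age"

    @property
    def age_mya(self) -> int:
        """Age in Myr, rounded to the nearest integer (report convention)."""
        return int(round(self.age_years / 1e6))

    @property
    def rate_e9(self) -> float:
        """Rate in 1e-9/site/year units, two decimals (report convention)."""
        return round(self.rate * 1e9, 2)


def age_from_ks(ks: float, rate: float = PLANT_AVERAGE_RATE) -> DatingResult:
    """Divergence date T = Ks / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if ks < 0:
        raise ValueError("ks must be non-negative")
    return DatingResult(ks_peak=ks, rate=rate, age_years=ks / (2.0 * rate), mode="age-from-rate")


def rate_from_age(ks: float, age_years: float) -> DatingResult:
    """Rate r = Ks / (2 T) from an independently dated peak."""
    if age_years <= 0:
        raise ValueError("age must be positive")
    if ks < 0:
        raise ValueError("ks must be non-negative")
    return DatingResult(
        ks_peak=ks, rate=ks / (2.0 * age_years), age_years=age_years, mode="rate-from-age"
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    method: str


def wilcoxon_matched(freq_a, freq_b, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-bin frequencies.

    Zero differences are dropped (Wilcoxon's convention); the null
    distribution is exact up to ``exact_max_n`` non-zero pairs and a normal
    approximation with continuity correction beyond.  All-zero differences
    give p = 1 with a warning.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p reported as 1", stacklevel=2)
        return WilcoxonResult(statistic=np.nan, p_value=1.0, n_used=0, method="degenerate")
    method = "exact" if nz.size <= exact_max_n else "approx"
    res = wilcoxon(
        a, b,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=int(nz.size),
        method=method,
    )
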