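"""Gaussian mixture modelling of log-transformed Ks values.

WGD bursts appear as approximately Gaussian components on the ln(Ks) scale
superimposed on the small-scale-duplication background.  Components are fit
by (observation-weighted) EM with unequal variances, the number of
components is chosen by BIC = 2*logL - p*ln(n) (larger is better, mclust's
convention, p = 3k - 1), and components are summarised on the Ks scale with
bootstrap confidence intervals.  Components with back-transformed mean above
2 are reported but never labelled as WGD candidates: high-Ks peaks are
saturation-dominated and untrustworthy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

VAR_FLOOR = 1e-6
EM_TOL = 1e-8
EM_MAX_ITER = 2000
WGD_WINDOW = (0.5, 2.0)
WGD_MIN_PROPORTION = 0.1
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureFit:
    """A fitted k-component univariate Gaussian mixture on ln(Ks)."""

    k: int
    means_log: np.ndarray
    variances_log: np.ndarray
    proportions: np.ndarray
    loglik: float
    bic: float
    n: float  # effective sample size (sum of observation weights)
    converged: bool = True
    n_iter: int = 0

    @property
    def means_ks(self) -> np.ndarray:
        return np.exp(self.means_log)


def _log_joint(x, x2, means, variances, props):
    """ln(prop_k * N(x | mu_k, var_k)) as an (n, k) array, computed as a
    quadratic in x with per-component coefficients (one fused pass)."""
    inv2v = 0.5 / variances
    const = np.log(props) - 0.5 * (_LOG2PI + np.log(variances)) - means**2 * inv2v
    return (
        const[None, :]
        + x[:, None] * (2.0 * means * inv2v)[None, :]
        - x2[:, None] * inv2v[None, :]
    )


def _weighted_loglik(x, w, means, variances, props):
    x = np.asarray(x, dtype=float)
    comp = _log_joint(x, x * x, means, variances, props)
    m = comp.max(axis=1)
    lse = m + np.log(np.exp(comp - m[:, None]).sum(axis=1))
    return float(np.sum(w * lse))


def _em_once(x, w, means, variances, props, rng, tol, max_iter, equal_variance=False):
    W = w.sum()
    x2 = x * x
    wx = w * x
    wx2 = w * x2
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        comp = _log_joint(x, x2, means, variances, props)
        m = comp.max(axis=1)
        comp -= m[:, None]
        np.exp(comp, out=comp)  # comp is now unnormalised responsibilities
        tot = comp.sum(axis=1)
        ll = float(np.sum(w * (m + np.log(tot))))
        comp /= tot[:, None]

        Nk = w @ comp
        low = np.nonzero(Nk < 1e-12 * W)[0]
        if low.size:
            # empty component(s): reseat at weighted random observations
            for kk in low:
                j = rng.choice(len(x), p=w / W)
                means[kk] = x[j]
                variances[kk] = max(float(np.var(x)), VAR_FLOOR)
                props[kk] = 1.0 / len(props)
            props = props / props.sum()
            ll_prev = -np.inf
            continue
        props = Nk / W
        means = (wx @ comp) / Nk
        variances = (wx2 @ comp) / Nk - means**2
        if equal_variance:
            variances = np.full_like(variances, (variances * Nk).sum() / W)
        np.maximum(variances, VAR_FLOOR, out=variances)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    ll_final = _weighted_loglik(x, w, means, variances, props)
    return means, variances, props, max(ll_final, ll_prev), converged, n_iter


def _kmeans_init(x, w, k, rng, n_rounds: int = 25):
    """Weighted k-means++ seeding plus Lloyd rounds on the 1-d data; returns
    (means, variances, proportions) for one EM start."""
    W = w.sum()
    centers = np.empty(k)
    centers[0] = x[rng.choice(len(x), p=w / W)]
    d2 = (x - centers[0]) ** 2
    for c in range(1, k):
        p = w * d2
        total = p.sum()
        if total <= 0:
            centers[c:] = x[rng.choice(len(x), size=k - c, p=w / W)]
            break
        centers[c] = x[rng.choice(len(x), p=p / total)]
        d2 = np.minimum(d2, (x - centers[c]) ** 2)
    for _ in range(n_rounds):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for c in range(k):
            mask = assign == c
            if mask.any():
                centers[c] = np.average(x[mask], weights=w[mask])
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    means = np.empty(k)
    variances = np.empty(k)
    props = np.empty(k)
    for c in range(k):
        mask = assign == c
        if not mask.any():
            means[c] = centers[c]
            variances[c] = max(float(np.var(x)), VAR_FLOOR)
            props[c] = 1e-6
        else:
            wc = w[mask]
            means[c] = np.average(x[mask], weights=wc)
            variances[c] = max(
                float(np.average((x[mask] - means[c]) ** 2, weights=wc)), VAR_FLOOR
            )
            props[c] = wc.sum()
    props /= props.sum()
    order = np.argsort(means)
    return means[order], variances[order], props[order]


def _quantile_init(x, w, k):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cuts = np.searchsorted(cw, np.linspace(0, cw[-1], k + 1)[1:-1])
    blocks = np.split(order, cuts)
    means = np.array([x[b].mean() if len(b) else x.mean() for b in blocks])
    variances = np.array(
        [x[b].var() if len(b) > 1 else max(x.var(), VAR_FLOOR) for b in blocks]
    )
    variances = np.maximum(variances, VAR_FLOOR)
    props = np.array([max(w[b].sum(), 1e-6) for b in blocks])
    return means, variances, props / props.sum()


def em_fit(
    log_ks,
    weights=None,
    k: int = 1,
    seed: int = 0,
    n_init: int = 5,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    init_params=None,
    equal_variance: bool = False,
) -> MixtureFit:
    """Weighted EM fit of a k-component Gaussian mixture to ln(Ks) values.

    Initialised by a weighted quantile partition plus ``n_init - 1`` seeded
    k-means++ restarts, each run briefly; the best start is polished to full
    convergence.  ``init_params=(means, variances, proportions)`` warm-starts
    a single run (used by the bootstrap); ``equal_variance=True`` ties the
    component variances (the mclust "E" model; default is the unequal "V"
    model).  Reproducible bit-for-bit given (data, k, seed, n_init).
    """
    x = np.asarray(log_ks, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match data")
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 10 * k and init_params is None:
        warnings.warn(f"only {x.size} observations for k={k}", stacklevel=2)
    rng = np.random.default_rng(seed)
    W = float(w.sum())

    if np.ptp(x) < 1e-12:
        if k > 1:
            warnings.warn("degenerate data (all values equal); forcing k=1", stacklevel=2)
        k = 1
        means = np.array([x[0]])
        variances = np.array([VAR_FLOOR])
        props = np.array([1.0])
        ll = _weighted_loglik(x, w, means, variances, props)
        return MixtureFit(1, means, variances, props, ll, 2 * ll - 2 * np.log(W), W)

    inits = []
    if init_params is not None:
        m0, v0, p0 = (np.array(a, dtype=float) for a in init_params)
        inits.append((m0, np.maximum(v0, VAR_FLOOR), p0 / p0.sum()))
    else:
        inits.append(_quantile_init(x, w, k))
        for _ in range(max(0, n_init - 1)):
            inits.append(_kmeans_init(x, w, k, rng))

    # short-EM: every start runs briefly, only the best is polished fully
    short_iter = min(300, max_iter) if len(inits) > 1 else max_iter
    best = None
    for means0, variances0, props0 in inits:
        means, variances, props, ll, converged, n_iter = _em_once(
            x, w, means0.copy(), variances0.copy(), props0.copy(), rng, tol,
            short_iter, equal_variance,
        )
        if best is None or ll > best[3]:
            best = (means, variances, props, ll, converged, n_iter)

    means, variances, props, ll, converged, n_iter = best
    if not converged and n_iter >= short_iter and max_iter > short_iter:
        means, variances, props, ll, converged, extra = _em_once(
            x, w, means, variances, props, rng, tol, max_iter - short_iter,
            equal_variance,
        )
        n_iter += extra
    order = np.argsort(means)
    p_free = 2 * k if equal_variance else 3 * k - 1
    bic = 2.0 * ll - p_free * np.log(W)
    return MixtureFit(
        k=k,
        means_log=means[order],
        variances_log=variances[order],
        proportions=props[order],
        loglik=ll,
        bic=bic,
        n=W,
        converged=converged,
        n_iter=n_iter,
    )


def select_k(
    log_ks,
    weights=None,
    k_range=range(1, 11),
    seed: int = 0,
    n_init: int = 5,
    equal_variance: bool = False,
) -> tuple[MixtureFit, list[MixtureFit]]:
    """Fit every k in ``k_range`` and return (best-BIC fit, all fits)."""
    fits = [
        em_fit(log_ks, weights=weights, k=k, seed=seed + k, n_init=n_init,
               equal_variance=equal_variance)
        for k in k_range
    ]
    best = max(fits, key=lambda f: f.bic)
    return best, fits


@dataclass(frozen=True)
class ComponentSummary:
    """A mixture component on the Ks scale."""

    mean_ks: float
    ci95: tuple[float, float]
    proportion: float
    label: str  # "candidate-WGD" or "background"
    mean_log: float
    variance_log: float
    ci_unstable: bool = False


def summarize_components(
    fit: MixtureFit,
    data,
    weights=None,
    B: int = 200,
    seed: int = 0,
    wgd_window: tuple[float, float] = WGD_WINDOW,
    min_proportion: float = WGD_MIN_PROPORTION,
    refit_tol: float = 1e-6,
    refit_max_iter: int = 500,
) -> list[ComponentSummary]:
    """Back-transform components to the Ks scale with bootstrap 95% CIs.

    Each of B seeded bootstrap resamples (indices drawn with probability
    proportional to observation weight) is refit with k fixed, warm-started
    from the original fit; each original component is matched to the refit
    component with the nearest mean.  Components with Ks-scale mean inside
    ``wgd_window`` and proportion >= ``min_proportion`` are labelled
    candidate-WGD; anything above Ks 2 stays background regardless.
    """
    x = np.asarray(data, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    p = w / w.sum()

    boot_means = np.full((B, fit.k), np.nan)
    failures = 0
    for b in range(B):
        idx = rng.choice(len(x), size=len(x), replace=True, p=p)
        refit = em_fit(
            x[idx],
            k=fit.k,
            seed=seed,
            init_params=(fit.means_log, fit.variances_log, fit.proportions),
            tol=refit_tol,
            max_iter=refit_max_iter,
        )
        if not refit.converged:
            failures += 1
        for c in range(fit.k):
            j = int(np.argmin(np.abs(refit.means_log - fit.means_log[c])))
            boot_means[b, c] = refit.means_log[j]
    unstable = failures > 0.2 * B
    if unstable:
        warnings.warn(
            f"{failures}/{B} bootstrap refits failed to converge; CIs unstable",
            stacklevel=2,
        )

    out = []
    for c in range(fit.k):
        mean_ks = float(np.exp(fit.means_log[c]))
        lo, hi = np.exp(np.percentile(boot_means[:, c], [2.5, 97.5]))
        label = (
            "candidate-WGD"
            if wgd_window[0] <= mean_ks <= min(wgd_window[1], 2.0)
            and fit.proportions[c] >= min_proportion
            else "background"
        )
        out.append(
            ComponentSummary(
                mean_ks=mean_ks,
                ci95=(float(lo), float(hi)),
                proportion=float(fit.proportions[c]),
                label=label,
                mean_log=float(fit.means_log[c]),
                variance_log=float(fit.variances_log[c]),
                ci_unstable=unstable,
            )
        )
    return out


def mixture_report(fit: MixtureFit, summaries=None) -> dict:
    """JSON-ready report shaped like a mixture table: one row per component
    with Ks-scale mean, log-scale variance, and proportion."""
    rows = []
    for c in range(fit.k):
        row = {
            "mean_ks": float(np.exp(fit.means_log[c])),
            "mean_log": float(fit.means_log[c]),
            "variance_log": float(fit.variances_log[c]),
            "variance_ks_scale": float(
                (np.exp(fit.variances_log[c]) - 1.0)
                * np.exp(2 * fit.means_log[c] + fit.variances_log[c])
            ),
            "proportion": float(fit.proportions[c]),
        }
        if summaries is not None:
            row["ci95"] = list(summaries[c].ci95)
            row["label"] = summaries[c].label
        rows.append(row)
    return {
        "n_duplicates": fit.n,
        "k": fit.k,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "components": rows,
    }


def write_mixture_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
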