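import numpy as np
import pytest

from paleoks.mixture import (
    _em_once,
    _quantile_init,
    _weighted_loglik,
    em_fit,
    mixture_report,
    select_k,
    summarize_components,
)


def _sample_mixture(rng, n, means, sds, props):
    comp = rng.choice(len(means), size=n, p=props)
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


class TestEMFit:
    def test_single_gaussian_mean_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.3, size=2000)
        fit = em_fit(x, k=1, seed=0)
        assert abs(fit.means_log[0]) < 3 * 0.3 / np.sqrt(2000)
        assert fit.variances_log[0] == pytest.approx(0.09, rel=0.15)

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        x = _sample_mixture(rng, 5000, [-2.0, 0.0], [0.1, 0.1], [0.5, 0.5])
        fit = em_fit(x, k=2, seed=1)
        assert fit.means_log[0] == pytest.approx(-2.0, abs=0.05)
        assert fit.means_log[1] == pytest.approx(0.0, abs=0.05)

    def test_loglik_nondecreasing_over_iterations(self):
        """Running EM longer from the same start never lowers the
        log-likelihood (the EM guarantee)."""
        rng = np.random.default_rng(2)
        x = _sample_mixture(rng, 800, [-1.0, 0.5], [0.3, 0.2], [0.6, 0.4])
        w = np.ones_like(x)
        m0, v0, p0 = _quantile_init(x, w, 2)
        lls = []
        for iters in (1, 2, 5, 10, 50, 200):
            m, v, p, ll, *_ = _em_once(
                x, w, m0.copy(), v0.copy(), p0.copy(),
                np.random.default_rng(0), 0.0, iters,
            )
            lls.append(ll)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_final_loglik_at_least_initial(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        w = np.ones_like(x)
        m0, v0, p0 = _quantile_init(x, w, 3)
        ll0 = _weighted_loglik(x, w, m0, v0, p0)
        fit = em_fit(x, k=3, seed=3, n_init=1)
        assert fit.loglik >= ll0 - 1e-9

    def test_bit_reproducible(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=600)
        a = em_fit(x, k=3, seed=7, n_init=4)
        b = em_fit(x, k=3, seed=7, n_init=4)
        assert np.array_equal(a.means_log, b.means_log)
        assert a.loglik == b.loglik

    def test_degenerate_data_forces_k1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = em_fit(np.zeros(50), k=3, seed=0)
        assert fit.k == 1
        assert fit.variances_log[0] == pytest.approx(1e-6)

    def test_weighted_equals_replicated(self):
        """An observation with weight 2 acts like two copies of it."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        wfit = em_fit(x, weights=np.full(200, 2.0), k=2, seed=1, n_init=1)
        rfit = em_fit(np.concatenate([x, x]), k=2, seed=1, n_init=1)
        # trajectories differ only by floating summation order
        assert wfit.means_log == pytest.approx(rfit.means_log, abs=1e-3)
        assert wfit.bic == pytest.approx(rfit.bic, abs=0.05)

    def test_equal_variance_mode_ties_components(self):
        rng = np.random.default_rng(12)
        x = _sample_mixture(rng, 2000, [-2.0, 0.0], [0.3, 0.3], [0.5, 0.5])
        fit = em_fit(x, k=2, seed=0, equal_variance=True)
        assert fit.variances_log[0] == fit.variances_log[1]
        # tied variances cost one fewer free parameter per extra component
        free = em_fit(x, k=2, seed=0)
        assert free.loglik >= fit.loglik - 1e-6

    def test_matches_sklearn_on_unweighted_data(self):
        sklearn_mix = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(6)
        x = _sample_mixture(rng, 3000, [-1.5, 0.3], [0.2, 0.3], [0.4, 0.6])
        fit = em_fit(x, k=2, seed=0, n_init=4)
        gm = sklearn_mix.GaussianMixture(2, n_init=4, random_state=0, tol=1e-6)
        gm.fit(x[:, None])
        order = np.argsort(gm.means_[:, 0])
        assert fit.means_log == pytest.approx(gm.means_[order, 0], abs=0.02)
        assert fit.proportions == pytest.approx(gm.weights_[order], abs=0.02)


class TestSelectK:
    def test_bic_prefers_one_component_for_single_gaussian(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, size=2000)
        best, fits = select_k(x, k_range=range(1, 5), seed=0, n_init=2)
        assert best.k == 1
        assert len(fits) == 4

    def test_bic_closed_form_for_k1(self):
        """For k=1 the ML solution is analytic: check the BIC convention
        bic = 2 logL - p ln(n) with p = 2 free parameters."""
        rng = np.random.default_rng(8)
        x = rng.normal(1.0, 0.5, size=400)
        fit = em_fit(x, k=1, seed=0)
        mu, var = x.mean(), x.var()
        ll = -0.5 * len(x) * (np.log(2 * np.pi * var) + 1)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        assert fit.bic == pytest.approx(2 * ll - 2 * np.log(len(x)), abs=1e-6)

    def test_forced_k(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        best, fits = select_k(x, k_range=[3], seed=0, n_init=2)
        assert best.k == 3 and len(fits) == 1


class TestSummaries:
    def test_back_transform_and_labels(self):
        rng = np.random.default_rng(10)
        x = _sample_mixture(rng, 3000, [np.log(1.2), np.log(4.5)], [0.15, 0.1], [0.6, 0.4])
        fit = em_fit(x, k=2, seed=0)
        summaries = summarize_components(fit, x, B=50, seed=0)
        assert summaries[0].mean_ks == pytest.approx(1.2, abs=0.05)
        assert summaries[0].label == "candidate-WGD"
        assert summaries[1].label == "background"  # mean above Ks 2
        lo, hi = summaries[0].ci95
        assert lo < summaries[0].mean_ks < hi

    def test_ci_width_shrinks_with_n(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.normal(np.log(1.2), 0.3, size=n)
            fit = em_fit(x, k=1, seed=0)
            s = summarize_components(fit, x, B=80, seed=0)[0]
            return s.ci95[1] - s.ci95[0]

        assert width(5000, 1) < width(500, 1)

    def test_report_shape(self):
        rng = np.random.default_rng(11)
        x = rng.normal(np.log(1.2), 0.2, size=500)
        fit = em_fit(x, k=1, seed=0)
        rep = mixture_report(fit, summarize_components(fit, x, B=20, seed=0))
        assert rep["k"] == 1
        assert len(rep["components"]) == 1
        row = rep["components"][0]
        assert {"mean_ks", "variance_log", "proportion", "ci95", "label"} <= set(row)
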