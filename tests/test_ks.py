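import numpy as np
import pytest

from paleoks.alignment import align_codon_pair
from paleoks.codon import CodonModel
from paleoks.ks import ml_ks, ng86
from paleoks.simulate import simulate_codon_pair

from .conftest import make_alignment


def _codons(nt):
    return [nt[i : i + 3] for i in range(0, len(nt), 3)]


class TestNG86:
    def test_identical_sequences(self):
        aln = make_alignment(["GGT", "AAA"], ["GGT", "AAA"])
        est = ng86(aln)
        assert est.ks == 0.0 and est.ka == 0.0 and not est.saturated

    def test_hand_counted_synonymous_example(self):
        """9x(GGT,GGT) + 1x(GGT,GGC): S=10, N=20, pS=0.1,
        Ks = -0.75 ln(1 - 0.4/3) ~ 0.1073, Ka = 0."""
        aln = make_alignment(["GGT"] * 10, ["GGT"] * 9 + ["GGC"])
        est = ng86(aln)
        assert est.ks == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert est.ka == 0.0

    def test_single_codon_saturation(self):
        """(TTT,TTC): one synonymous difference over a third of a synonymous
        site; pS = 3 > 3/4, flagged saturated."""
        est = ng86(make_alignment(["TTT"], ["TTC"]))
        assert est.saturated
        assert np.isnan(est.ks)

    def test_symmetry(self, default_model):
        a, b = simulate_codon_pair(0.8, default_model, 60, seed=5)
        fwd = ng86(make_alignment(_codons(a.nt), _codons(b.nt)))
        rev = ng86(make_alignment(_codons(b.nt), _codons(a.nt)))
        assert fwd.ks == pytest.approx(rev.ks)
        assert fwd.ka == pytest.approx(rev.ka)

    def test_matches_biopython_counting(self):
        """Cross-check against Biopython's independent NG86 implementation
        on simulated moderate-divergence pairs.  The two differ slightly by
        convention (stop-adjacent site opportunities, multi-hit pathway
        weighting), so agreement is to a few percent, not exact."""
        cal_dn_ds = pytest.importorskip("Bio.codonalign.codonseq").cal_dn_ds
        CodonSeq = pytest.importorskip("Bio.codonalign.codonseq").CodonSeq
        model = CodonModel(kappa=1.0, omega=0.5)
        for seed in range(3):
            a, b = simulate_codon_pair(0.4, model, 120, seed=seed)
            aln = align_codon_pair(a, b)
            est = ng86(aln)
            dn, ds = cal_dn_ds(
                CodonSeq("".join(aln.codons_a)), CodonSeq("".join(aln.codons_b)),
                method="NG86",
            )
            assert est.ks == pytest.approx(ds, rel=0.07)
            assert est.ka == pytest.approx(dn, rel=0.07)


class TestCodonModel:
    def test_rate_matrix_rows_sum_to_zero(self, default_model):
        assert np.allclose(default_model.Q.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrices_are_stochastic(self, default_model, t):
        P = default_model.transition_matrix(t)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_stationarity(self, default_model):
        pi = default_model.pi
        assert np.allclose(pi @ default_model.transition_matrix(0.7), pi, atol=1e-10)

    def test_ks_decomposition_round_trip(self, default_model):
        t = default_model.t_for_ks(0.8)
        ks, ka = default_model.ks_ka_from_t(t)
        assert ks == pytest.approx(0.8)
        assert ka > 0


class TestMLKs:
    def test_identical_sequences_give_zero(self, default_model):
        a, b = simulate_codon_pair(0.0, default_model, 100, seed=0)
        est = ml_ks(align_codon_pair(a, b))
        assert est.ks < 1e-4
        assert not est.saturated

    def test_loglik_not_below_start(self, default_model):
        for seed in range(4):
            a, b = simulate_codon_pair(0.6, default_model, 200, seed=seed)
            est = ml_ks(align_codon_pair(a, b))
            assert est.method == "ML"
            assert np.isfinite(est.loglik)

    def test_mean_ks_monotone_in_true_divergence(self, default_model):
        """Average estimate increases with the simulated divergence."""
        means = []
        for true_ks in (0.1, 0.5, 1.0, 2.0):
            vals = []
            for seed in range(8):
                a, b = simulate_codon_pair(true_ks, default_model, 300, seed=100 + seed)
                vals.append(ml_ks(align_codon_pair(a, b)).ks)
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_concordance_with_ng86_at_low_divergence(self, unbiased_model):
        """Without transition or codon-usage bias the two estimators agree
        within 15% at low divergence on >= 90% of replicates."""
        agree = total = 0
        for true_ks in (0.15, 0.3):
            for seed in range(10):
                a, b = simulate_codon_pair(true_ks, unbiased_model, 400, seed=seed)
                aln = align_codon_pair(a, b)
                ml = ml_ks(aln).ks
                ng = ng86(aln).ks
                total += 1
                if abs(ml - ng) <= 0.15 * max(ml, ng):
                    agree += 1
        assert agree / total >= 0.9

    def test_saturated_pair_is_flagged(self, default_model):
        a, b = simulate_codon_pair(15.0, default_model, 120, seed=2)
        est = ml_ks(align_codon_pair(a, b))
        assert est.saturated or est.ks > 5.0
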