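import math

import numpy as np
import pytest

from paleoks.distribution import (
    WeightedKs,
    filter_ks,
    histogram,
    node_weight,
    select_peak_duplicates,
)


def _wks(fid, a, b, ks, w=1.0, node="n"):
    return WeightedKs(fid, a, b, ks, w, node)


class TestNodeWeight:
    def test_two_member_family(self):
        out = node_weight("F", ["A", "B"], {("A", "B"): 0.4})
        assert len(out) == 1
        assert out[0].weight == 1.0

    def test_three_member_merge_order(self):
        """(A,B)=0.2 joins first; (A,C) and (B,C) share the deeper node."""
        out = node_weight(
            "F", ["A", "B", "C"], {("A", "B"): 0.2, ("A", "C"): 1.0, ("B", "C"): 1.1}
        )
        by_pair = {(p.id_a, p.id_b): p for p in out}
        assert by_pair[("A", "B")].weight == 1.0
        assert by_pair[("A", "C")].weight == 0.5
        assert by_pair[("B", "C")].weight == 0.5
        assert by_pair[("A", "C")].node_id == by_pair[("B", "C")].node_id
        assert math.fsum(p.weight for p in out) == pytest.approx(2.0, abs=1e-12)

    def test_per_node_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            members = [f"g{i}" for i in range(n)]
            ks_map = {}
            for i in range(n):
                for j in range(i + 1, n):
                    # occasional saturated pair drops out of the weighting
                    ks_map[(members[i], members[j])] = (
                        np.nan if rng.random() < 0.1 else float(rng.exponential(1.0))
                    )
            out = node_weight("F", members, ks_map)
            nodes = {}
            for p in out:
                nodes.setdefault(p.node_id, []).append(p.weight)
            for weights in nodes.values():
                assert math.fsum(weights) == pytest.approx(1.0, abs=1e-9)
            assert len(nodes) <= n - 1

    def test_invariant_under_relabeling_and_order(self):
        ks = {("A", "B"): 0.3, ("A", "C"): 0.9, ("B", "C"): 0.8, ("A", "D"): 2.0,
              ("B", "D"): 2.1, ("C", "D"): 1.9}
        base = node_weight("F", ["A", "B", "C", "D"], ks)
        relabel = {"A": "W", "B": "Z", "C": "X", "D": "Y"}
        ks2 = {tuple(sorted((relabel[a], relabel[b]))): v for (a, b), v in ks.items()}
        out2 = node_weight("F", ["Z", "Y", "X", "W"], ks2)
        w1 = sorted((p.ks, p.weight) for p in base)
        w2 = sorted((p.ks, p.weight) for p in out2)
        assert w1 == pytest.approx(w2)

    def test_all_saturated_family_emits_nothing(self):
        assert node_weight("F", ["A", "B"], {("A", "B"): np.nan}) == []


class TestFilterAndHistogram:
    def test_filter_endpoints_inclusive(self):
        pairs = [_wks("F", "a", "b", ks) for ks in (0.05, 0.1, 3.0, 5.0, 5.01)]
        kept = filter_ks(pairs)
        assert [p.ks for p in kept] == [0.1, 3.0, 5.0]

    def test_histogram_bins_and_conservation(self):
        pairs = [_wks("F", "a", "b", 0.15, 1.0), _wks("F", "a", "c", 0.17, 0.5)]
        hist = histogram(pairs)
        assert hist.bin_weights[1] == pytest.approx(1.5)
        assert hist.total_weight == pytest.approx(1.5)
        assert len(hist.bin_edges) == 51

    def test_last_bin_closed_and_empty_input(self):
        hist = histogram([_wks("F", "a", "b", 5.0)])
        assert hist.bin_weights[-1] == 1.0
        empty = histogram([])
        assert empty.total_weight == 0.0
        assert np.all(empty.bin_weights == 0)

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(11)
        pairs = [
            _wks("F", "a", "b", float(ks), float(w))
            for ks, w in zip(rng.uniform(0.1, 5.0, 200), rng.uniform(0.1, 1.0, 200))
        ]
        hist = histogram(pairs)
        assert hist.total_weight == pytest.approx(math.fsum(p.weight for p in pairs))


class TestPeakDuplicates:
    def test_nearest_to_peak_mean(self):
        pairs = [_wks("F1", "a", "b", 0.5), _wks("F1", "a", "c", 1.0),
                 _wks("F1", "b", "c", 1.4), _wks("F2", "x", "y", 2.0)]
        rep = select_peak_duplicates(pairs, peak_mean=1.15)
        assert set(rep) == {"F1"}  # F2 has no in-window pair
        assert rep["F1"].ks == 1.0

    def test_tie_breaks_to_smaller_ks(self):
        pairs = [_wks("F", "a", "b", 1.1), _wks("F", "a", "c", 1.3)]
        rep = select_peak_duplicates(pairs, peak_mean=1.2)
        assert rep["F"].ks == 1.1

    def test_one_representative_per_family(self):
        rng = np.random.default_rng(2)
        pairs = [
            _wks(f"F{i % 7}", f"a{j}", f"b{j}", float(ks))
            for j, (i, ks) in enumerate(
                zip(rng.integers(0, 7, 60), rng.uniform(0.2, 3.0, 60))
            )
        ]
        rep = select_peak_duplicates(pairs, peak_mean=1.2)
        for fid, p in rep.items():
            assert p.family_id == fid
            assert 0.9 <= p.ks <= 1.5
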