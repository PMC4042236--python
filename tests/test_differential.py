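import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindpat import (
    Cutoffs,
    GenomicInterval,
    call_ders,
    region_ratio_difference,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from bindpat.binning import BinnedRegion, partition_region

from oracles import rank_sum_enumeration, signed_rank_enumeration


def make_region(x1, x2, source="A", start=0):
    x1 = np.asarray(x1, dtype=float)
    n = len(x1)
    region = GenomicInterval("chr1", start, start + 30 * n)
    return BinnedRegion(
        region, source, partition_region(region, 30), x1, np.asarray(x2, dtype=float)
    )


class TestSignedRank:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.p_greater == 1.0 and res.statistic == 0.0

    def test_all_positive_no_ties_exact_p(self):
        res = wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert res.p_greater == pytest.approx(1 / 32, abs=1e-15)
        assert res.statistic == 15.0

    def test_mixed_signs_match_enumeration(self):
        x1, x2 = [2.0, 0.0, 4.0], [1.0, 2.0, 1.0]  # z = [1, -2, 3]
        res = wilcoxon_signed_rank(x1, x2)
        t, pg, pl = signed_rank_enumeration(x1, x2)
        assert res.statistic == pytest.approx(t)
        assert res.p_greater == pytest.approx(pg, abs=1e-12)
        assert res.p_less == pytest.approx(pl, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=1, max_size=10
        )
    )
    def test_exact_agrees_with_enumeration(self, pairs):
        x1 = [a for a, _ in pairs]
        x2 = [b for _, b in pairs]
        res = wilcoxon_signed_rank(x1, x2)
        t, pg, pl = signed_rank_enumeration(x1, x2)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_greater == pytest.approx(pg, abs=1e-12)
        assert res.p_less == pytest.approx(pl, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x1 = rng.poisson(4, 12).astype(float)
            x2 = rng.poisson(4, 12).astype(float)
            fwd = wilcoxon_signed_rank(x1, x2)
            rev = wilcoxon_signed_rank(x2, x1)
            assert fwd.p_greater == pytest.approx(rev.p_less, abs=1e-12)
            assert fwd.statistic == pytest.approx(-rev.statistic, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        # n just above the enumeration limit: approximation should be sane
        rng = np.random.default_rng(4)
        x1 = rng.normal(0.5, 1, 30)
        x2 = rng.normal(0.0, 1, 30)
        res = wilcoxon_signed_rank(x1, x2)
        assert res.method == "normal" and 0 < res.p_greater < 0.5


class TestRankSum:
    def test_extreme_separation(self):
        res = wilcoxon_rank_sum([10, 11, 12], [1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_greater == pytest.approx(0.05, abs=1e-12)

    def test_identical_multisets_p_one_two_sided(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert min(1.0, 2 * min(res.p_greater, res.p_less)) == pytest.approx(1.0)

    def test_all_tied_degenerate(self):
        res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.p_greater == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_exact_agrees_with_enumeration(self, data):
        n1 = data.draw(st.integers(1, 8))
        n2 = data.draw(st.integers(1, 8))
        values = data.draw(
            st.lists(
                st.integers(0, 1000), min_size=n1 + n2, max_size=n1 + n2, unique=True
            )
        )
        x1, x2 = [float(v) for v in values[:n1]], [float(v) for v in values[n1:]]
        res = wilcoxon_rank_sum(x1, x2)
        w, pg, pl = rank_sum_enumeration(x1, x2)
        assert res.statistic == pytest.approx(w, abs=1e-12)
        assert res.p_greater == pytest.approx(pg, abs=1e-12)
        assert res.p_less == pytest.approx(pl, abs=1e-12)

    def test_antisymmetry_of_directions(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(1, 1, 15)
        x2 = rng.normal(0, 1, 10)
        fwd = wilcoxon_rank_sum(x1, x2)
        rev = wilcoxon_rank_sum(x2, x1)
        assert fwd.p_greater == pytest.approx(rev.p_less, abs=1e-12)


class TestRatioDifference:
    def test_formula(self):
        r, d = region_ratio_difference(make_region([3, 3], [2, 3]))
        assert r == pytest.approx(1.2) and d == pytest.approx(1.0)

    def test_all_zero_convention(self):
        r, d = region_ratio_difference(make_region([0, 0], [0, 0]))
        assert r == 1.0 and d == 0.0

    def test_zero_denominator_is_inf(self):
        r, d = region_ratio_difference(make_region([4], [0]))
        assert math.isinf(r) and d == 4.0

    def test_reporting_scale_applied_to_d_only(self):
        r1, d1 = region_ratio_difference(make_region([3, 3], [2, 3]), scale=10.0)
        assert r1 == pytest.approx(1.2) and d1 == pytest.approx(10.0)

    def test_swap_antisymmetry(self):
        br = make_region([5, 1, 7], [2, 2, 2])
        swapped = make_region([2, 2, 2], [5, 1, 7])
        r, d = region_ratio_difference(br)
        r2, d2 = region_ratio_difference(swapped)
        assert r2 == pytest.approx(1 / r) and d2 == pytest.approx(-d)


class TestCallDers:
    def strong_region(self, source="A", start=0):
        if source == "A":
            return make_region([9, 8, 9, 10, 9, 8, 9, 10], [1, 2, 1, 0, 1, 2, 1, 0],
                               source, start)
        return make_region([1, 2, 1, 0, 1, 2, 1, 0], [9, 8, 9, 10, 9, 8, 9, 10],
                           source, start)

    def test_a_der_called(self):
        (dr,) = call_ders([self.strong_region("A")])
        assert dr.enriched_in == "A" and dr.p_value < 0.05 and dr.r > 1.2

    def test_b_der_called_symmetrically(self):
        (dr,) = call_ders([self.strong_region("B")])
        assert dr.enriched_in == "B"

    def test_ratio_cutoff_blocks(self):
        # clear rank signal but ratio only ~1.1
        br = make_region([11, 12, 11, 12, 11, 12, 11, 12],
                         [10, 11, 10, 11, 10, 11, 10, 11])
        (dr,) = call_ders([br])
        assert dr.p_value < 0.05 and dr.r < 1.2 and dr.enriched_in is None

    def test_brute_force_cutoff_filter(self):
        rng = np.random.default_rng(12)
        regions = []
        for i in range(10):
            lam1 = rng.uniform(1, 12)
            lam2 = rng.uniform(1, 12)
            regions.append(
                make_region(rng.poisson(lam1, 12), rng.poisson(lam2, 12),
                            start=i * 1000)
            )
        cut = Cutoffs(alpha=0.05, ratio_min=1.2, diff_min=0.8)
        results = call_ders(regions, cut)
        for dr in results:
            expected = (
                dr.p_value < cut.alpha and dr.r >= cut.ratio_min and dr.d >= cut.diff_min
            )
            assert (dr.enriched_in == "A") == expected

    def test_monotonicity_in_cutoffs(self):
        rng = np.random.default_rng(13)
        regions = [
            make_region(rng.poisson(8, 10), rng.poisson(4, 10), start=i * 1000)
            for i in range(40)
        ]
        counts = []
        for alpha, ratio, diff in [(0.1, 1.1, 0.0), (0.05, 1.2, 0.8), (0.01, 1.5, 2.0)]:
            n = sum(
                dr.enriched_in is not None
                for dr in call_ders(regions, Cutoffs(alpha, ratio, diff))
            )
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]

    def test_degenerate_all_zero_never_der(self):
        (dr,) = call_ders([make_region([0, 0, 0], [0, 0, 0])])
        assert dr.enriched_in is None and dr.p_value == 1.0

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(14)
        regions = [
            make_region(rng.poisson(5, 10), rng.poisson(4, 10), start=i * 1000)
            for i in range(50)
        ]
        raw = sum(d.enriched_in is not None for d in call_ders(regions, Cutoffs()))
        bh = sum(
            d.enriched_in is not None
            for d in call_ders(regions, Cutoffs(correction="bh"))
        )
        assert bh <= raw

    def test_empty_comparison_set(self):
        assert call_ders([]) == []

    def test_rank_sum_mode(self):
        (dr,) = call_ders([self.strong_region("A")], Cutoffs(paired=False))
        assert dr.enriched_in == "A"
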