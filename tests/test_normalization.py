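import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindpat import (
    CountSpectrum,
    DegenerateInputError,
    GenomicInterval,
    build_count_spectrum,
    linear_normalize,
    neb_normalize,
    no_normalization,
    quantile_normalize,
    sgt_adjust,
)
from bindpat.normalization import NormalizedTrack, sgt_adjust_counts

from oracles import sgt_reference


def read(chrom, start, end=None, strand="+"):
    return GenomicInterval(chrom, start, end or start + 36, strand)


spectra = st.dictionaries(
    st.integers(min_value=1, max_value=30),
    st.integers(min_value=1, max_value=200),
    min_size=1,
    max_size=15,
)


def spectrum_of(d):
    return CountSpectrum(d, depth=sum(c * n for c, n in d.items()))


class TestLinearNormalize:
    def test_proportions(self):
        assert list(linear_normalize([2, 3, 5], 10)) == [0.2, 0.3, 0.5]

    def test_zeros_stay_zero(self):
        assert list(linear_normalize([0, 0], 7)) == [0.0, 0.0]

    def test_zero_total_raises(self):
        with pytest.raises(DegenerateInputError):
            linear_normalize([1], 0)


class TestCountSpectrum:
    def test_multiplicity_tally(self):
        reads = [read("chr1", 10), read("chr1", 10), read("chr1", 50), read("chr2", 10)]
        spec = build_count_spectrum(reads)
        assert spec.n_c == {1: 2, 2: 1} and spec.depth == 4

    def test_empty_input(self):
        spec = build_count_spectrum([])
        assert spec.n_c == {} and spec.depth == 0

    def test_all_singletons(self):
        reads = [read("chr1", i * 100) for i in range(5)]
        assert build_count_spectrum(reads).n_c == {1: 5}

    def test_strand_distinguishes_positions(self):
        reads = [read("chr1", 10, strand="+"), read("chr1", 10, strand="-")]
        assert build_count_spectrum(reads).n_c == {1: 2}


class TestSGT:
    def test_p0_is_singleton_fraction(self):
        res = sgt_adjust(spectrum_of({1: 3, 2: 2, 3: 1}))
        assert res.p0 == 0.3

    def test_example_spectrum_matches_reference(self):
        res = sgt_adjust(spectrum_of({1: 3, 2: 2, 3: 1}))
        c_star, p0, s_star, p_star = sgt_reference({1: 3, 2: 2, 3: 1})
        for c in (1, 2, 3):
            assert res.c_star[c] == pytest.approx(c_star[c], abs=1e-12)

    def test_empty_spectrum_raises(self):
        with pytest.raises(DegenerateInputError):
            sgt_adjust(CountSpectrum({}, 0))

    def test_no_singletons_gives_p0_zero(self, caplog):
        res = sgt_adjust(spectrum_of({2: 5, 3: 2}))
        assert res.p0 == 0.0

    @settings(max_examples=150, deadline=None)
    @given(spectra)
    def test_mass_conservation_and_eq4(self, d):
        spec = spectrum_of(d)
        res = sgt_adjust(spec)
        mass = sum(d[c] * res.p_star[c] for c in d) + res.p0
        assert mass == pytest.approx(1.0, abs=1e-9)
        assert res.s_star == pytest.approx(
            sum(d[c] * res.c_star[c] for c in d), abs=1e-9
        )
        assert res.p0 == d.get(1, 0) / spec.depth

    @settings(max_examples=100, deadline=None)
    @given(spectra)
    def test_agrees_with_independent_reference(self, d):
        res = sgt_adjust(spectrum_of(d))
        c_star, p0, s_star, p_star = sgt_reference(d)
        assert res.p0 == p0
        for c in d:
            assert res.c_star[c] == pytest.approx(c_star[c], rel=1e-9, abs=1e-9)
            assert res.p_star[c] == pytest.approx(p_star[c], rel=1e-9, abs=1e-12)

    def test_shrinks_singletons_below_naive_share(self):
        # rapidly decaying spectrum (2*n_2 < n_1, the shape of real read
        # data): singletons get less than their naive 1/S share
        rng = np.random.default_rng(11)
        for _ in range(150):
            n1 = int(rng.integers(50, 500))
            d, n_prev = {}, n1
            for c in range(1, int(rng.integers(3, 8))):
                d[c] = n_prev
                n_prev = max(1, int(n_prev * rng.uniform(0.1, 0.45)))
            spec = spectrum_of(d)
            res = sgt_adjust(spec)
            assert res.p_star[1] < 1.0 / spec.depth


class TestNEB:
    def test_uniform_sample_uniform_weights(self):
        reads = [read("chr1", i * 100) for i in range(20)]
        track_a, track_b = neb_normalize(reads, reads)
        for track in (track_a, track_b):
            w = track.weights["chr1"]
            assert np.allclose(w, w[0])

    def test_per_sample_independence(self):
        a = [read("chr1", i * 100) for i in range(10)]
        b = [read("chr1", i * 50) for i in range(8)] + [read("chr1", 0)]
        _, track_b1 = neb_normalize(a, b)
        _, track_b2 = neb_normalize(a + a, b)  # duplicating A leaves B unchanged
        assert np.array_equal(track_b1.weights["chr1"], track_b2.weights["chr1"])

    def test_identical_samples_identical_tracks(self):
        a = [read("chr1", i * 100) for i in range(10)] + [read("chr1", 0)]
        ta, tb = neb_normalize(a, list(a))
        assert np.array_equal(ta.weights["chr1"], tb.weights["chr1"])

    def test_empty_sample_raises(self):
        with pytest.raises(DegenerateInputError):
            neb_normalize([], [read("chr1", 1)])


class TestQuantileNormalize:
    def test_identity_on_same_distribution(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        out = quantile_normalize(x, x)
        assert sorted(out) == sorted(x)
        # rank order preserved
        assert list(np.argsort(out)) == list(np.argsort(x))

    def test_single_value_maps_to_reference_max(self):
        assert quantile_normalize([5.0], [1.0, 2.0, 3.0])[0] == 3.0

    def test_monotone(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=50)
        ref = rng.gamma(2.0, size=80)
        out = quantile_normalize(b, ref)
        order = np.argsort(b)
        assert np.all(np.diff(out[order]) >= 0)

    def test_empty_reference_raises(self):
        with pytest.raises(DegenerateInputError):
            quantile_normalize([1.0], [])

    def test_multiset_preserved_with_ties(self):
        x = np.array([1.0, 1.0, 2.0, 7.0, 7.0])
        out = quantile_normalize(x, x)
        assert sorted(out) == sorted(x)


class TestNoNormalization:
    def test_identity_and_idempotent(self):
        v = [1.0, 2.0, 3.0]
        out = no_normalization(v)
        assert list(out) == v
        assert list(no_normalization(out)) == v

    def test_empty(self):
        assert no_normalization([]).size == 0


class TestTrackBuilding:
    def test_linear_weights_sum_to_one(self):
        reads = [read("chr1", i * 10) for i in range(40)]
        track = NormalizedTrack.from_reads(reads, "linear")
        assert np.isclose(track.weights["chr1"].sum(), 1.0)

    def test_neb_track_mass_is_one_minus_p0(self):
        reads = [read("chr1", i) for i in range(50)] + [read("chr1", 0)] * 3
        track = NormalizedTrack.from_reads(reads, "neb")
        spec = build_count_spectrum(reads)
        res = sgt_adjust(spec)
        assert np.isclose(track.weights["chr1"].sum(), 1.0 - res.p0)


class TestSGTBinLevel:
    def test_zeros_map_to_zero_and_mass_conserved(self):
        counts = np.array([0, 1, 1, 2, 3, 0, 5, 1])
        out = sgt_adjust_counts(counts)
        assert out[0] == 0.0 and out[5] == 0.0
        assert np.all(out[counts > 0] > 0)

    def test_rejects_non_integer(self):
        with pytest.raises(ValueError):
            sgt_adjust_counts(np.array([1.5, 2.0]))
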