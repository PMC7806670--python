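import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from occupeak import (
    GenomicInterval,
    OverlapRule,
    PeakSet,
    binned_count_correlation,
    filter_supported,
    genes_with_peaks,
    length_histogram,
    max_overlap_fraction,
    merge_replicates,
    overlap_bases,
    overlap_fraction,
    shared_gene_fraction,
    support_by_min_fraction,
)
from occupeak.overlaps import binned_midpoint_counts

from .conftest import random_peakset
from .oracles import brute_overlap_bases, covered_bases_bitmap, spearman_oracle

iv_strategy = st.tuples(
    st.sampled_from(["chr1", "chr2"]), st.integers(0, 2000), st.integers(1, 300)
).map(lambda t: GenomicInterval(t[0], t[1], t[1] + t[2]))


class TestOverlapBases:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 100, 200), 100),
            (("chr1", 100, 200), ("chr1", 300, 400), 0),
            (("chr1", 0, 100), ("chr1", 50, 150), 50),
            (("chr1", 0, 100), ("chr2", 0, 100), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bases(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @given(iv_strategy, iv_strategy)
    def test_symmetry_and_brute_force(self, a, b):
        assert overlap_bases(a, b) == overlap_bases(b, a) == brute_overlap_bases(a, b)

    def test_strand_aware(self):
        plus = GenomicInterval("chr1", 0, 100, "+")
        minus = GenomicInterval("chr1", 0, 100, "-")
        none = GenomicInterval("chr1", 0, 100, ".")
        assert overlap_bases(plus, minus, strand_aware=True) == 0
        assert overlap_bases(plus, none, strand_aware=True) == 100


class TestOverlapFraction:
    def test_identical_is_one_in_both_modes(self):
        a = GenomicInterval("chr1", 10, 60)
        for mode in ("query", "reciprocal"):
            assert overlap_fraction(a, a, OverlapRule(mode=mode)) == 1.0

    def test_disjoint_is_zero(self):
        a, b = GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)
        assert overlap_fraction(a, b) == 0.0

    def test_query_vs_reciprocal(self):
        q = GenomicInterval("chr1", 0, 100)
        r = GenomicInterval("chr1", 50, 250)
        assert overlap_fraction(q, r, OverlapRule(mode="query")) == 0.5
        assert overlap_fraction(q, r, OverlapRule(mode="reciprocal")) == 0.25

    @given(iv_strategy, iv_strategy)
    def test_bounds_and_reciprocal_symmetry(self, a, b):
        rule = OverlapRule(mode="reciprocal")
        f = overlap_fraction(a, b, rule)
        assert 0.0 <= f <= 1.0
        assert f == overlap_fraction(b, a, rule)


class TestMergeReplicates:
    def test_overlapping_coalesce(self):
        ps = PeakSet([GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 40, 100)])
        merged = merge_replicates([ps])
        assert [(iv.start, iv.end) for iv in merged] == [(0, 100)]

    def test_book_ended_coalesce(self):
        ps = PeakSet([GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 50, 100)])
        assert [(iv.start, iv.end) for iv in merge_replicates([ps])] == [(0, 100)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])

    @given(st.lists(iv_strategy, min_size=1, max_size=40))
    def test_idempotent_and_base_conserving(self, ivs):
        ps = PeakSet(ivs)
        once = merge_replicates([ps])
        twice = merge_replicates([once])
        assert once == twice
        assert once.covered_bases() == covered_bases_bitmap(ps, 3000)


class TestFilterSupported:
    def test_self_support_is_total(self, rng):
        ps = random_peakset(rng, 50)
        _, frac = filter_supported(ps, ps)
        assert frac == 1.0

    def test_different_chromosome_no_support(self):
        q = PeakSet([GenomicInterval("chr1", 0, 100)])
        r = PeakSet([GenomicInterval("chr9", 0, 100)])
        _, frac = filter_supported(q, r)
        assert frac == 0.0

    def test_threshold_is_inclusive(self):
        q = PeakSet([GenomicInterval("chr1", 0, 100)])
        r = PeakSet([GenomicInterval("chr1", 50, 200)])
        _, frac = filter_supported(q, r, OverlapRule(min_fraction=0.5))
        assert frac == 1.0
        _, frac = filter_supported(q, r, OverlapRule(min_fraction=0.51))
        assert frac == 0.0

    def test_empty_inputs_rejected(self, rng):
        ps = random_peakset(rng, 5)
        with pytest.raises(ValueError):
            filter_supported(PeakSet([]), ps)


class TestSupportSweep:
    def test_monotone_non_increasing(self, rng):
        q = random_peakset(rng, 200)
        r = random_peakset(rng, 150)
        grid = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        table = support_by_min_fraction(q, r, grid)
        values = [table[f] for f in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_self_reference_is_one_everywhere(self, rng):
        q = random_peakset(rng, 60)
        table = support_by_min_fraction(q, q, (0.1, 0.5, 1.0))
        assert set(table.values()) == {1.0}

    def test_length_prefilter(self):
        q = PeakSet([GenomicInterval("chr1", 0, 40), GenomicInterval("chr1", 100, 400)])
        r = PeakSet([GenomicInterval("chr1", 0, 40)])
        table = support_by_min_fraction(q, r, (0.5,), max_peak_length=50)
        assert table[0.5] == 1.0

    def test_invalid_threshold_rejected(self, rng):
        q = random_peakset(rng, 5)
        with pytest.raises(ValueError):
            support_by_min_fraction(q, q, (0.0, 0.5))


class TestGeneSharing:
    def test_genes_with_peaks_one_bp_rule(self, tiny_model):
        peaks = PeakSet([GenomicInterval("chr1", 9999, 10050)])  # last bp of geneA
        assert genes_with_peaks(peaks, tiny_model) == {"geneA"}

    @pytest.mark.parametrize(
        "sets, expected",
        [
            (({"a", "b"}, {"a", "b"}), 1.0),
            (({"a"}, {"b"}), 0.0),
            (({"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}), 0.5),
        ],
    )
    def test_shared_fraction(self, sets, expected):
        assert shared_gene_fraction(list(sets)) == expected


class TestLengthHistogram:
    def test_fraction_below(self):
        ps = PeakSet([
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 100, 140),
            GenomicInterval("chr1", 200, 260),
        ])
        hist = length_histogram(ps)
        assert hist.fraction_below(50) == pytest.approx(2 / 3)

    def test_boundary_is_strict(self):
        ps = PeakSet([GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(4)])
        assert length_histogram(ps).fraction_below(50) == 0.0

    def test_counts_conserve_n(self, rng):
        ps = random_peakset(rng, 123)
        hist = length_histogram(ps)
        assert hist.counts.sum() == hist.n == len(ps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            length_histogram(PeakSet([]))


class TestBinnedCorrelation:
    SIZES = {"chr1": 100_000}

    def test_identity(self, rng):
        a = random_peakset(rng, 300, chroms=("chr1",), max_pos=99_000)
        rho, rho2 = binned_count_correlation(a, a, self.SIZES)
        assert rho == pytest.approx(1.0)
        assert rho2 == pytest.approx(1.0)

    def test_reversed_rank_fixture_is_minus_one(self):
        # peaks per bin: 1, 2, ..., 10 on side a; reversed on side b
        a_ivs, b_ivs = [], []
        for bin_idx in range(10):
            for j in range(bin_idx + 1):
                pos = bin_idx * 10_000 + j * 50
                a_ivs.append(GenomicInterval("chr1", pos, pos + 10))
                pos_b = (9 - bin_idx) * 10_000 + j * 50
                b_ivs.append(GenomicInterval("chr1", pos_b, pos_b + 10))
        rho, _ = binned_count_correlation(PeakSet(a_ivs), PeakSet(b_ivs), self.SIZES)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        a = random_peakset(rng, 400, chroms=("chr1",), max_pos=99_000, label="a")
        jittered = []
        for iv in a:
            s = (iv.start + int(rng.normal(0, 2000))) % 99_000
            jittered.append(GenomicInterval(iv.chrom, s, s + iv.length))
        b = PeakSet(jittered, label="b")
        rho, _ = binned_count_correlation(a, b, self.SIZES)
        ca = binned_midpoint_counts(a, self.SIZES)
        cb = binned_midpoint_counts(b, self.SIZES)
        assert rho == pytest.approx(spearman_oracle(ca, cb), abs=1e-12)

    def test_degenerate_input_rejected(self):
        a = PeakSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="degenerate"):
            binned_count_correlation(a, PeakSet([]), {"chr1": 50_000})
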