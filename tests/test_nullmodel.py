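from collections import Counter

import numpy as np
import pytest

from occupeak import (
    Gene,
    GeneModel,
    GenomicInterval,
    PeakSet,
    generate_null_profiles,
    null_profile_audit,
)
from occupeak.nullmodel import PlacementError


@pytest.fixture(scope="module")
def flat_model():
    """Ten simple single-exon genes of 10 kb on one chromosome."""
    genes = [
        Gene(f"g{i}", "chr1", i * 12_000, i * 12_000 + 10_000, "+", "other",
             exons=((i * 12_000, i * 12_000 + 10_000),))
        for i in range(10)
    ]
    return GeneModel(genes, chrom_sizes={"chr1": 130_000})


@pytest.fixture(scope="module")
def real_peaks(flat_model):
    rng = np.random.default_rng(5)
    ivs = []
    for _ in range(120):
        g = flat_model.genes[rng.integers(0, 10)]
        w = int(rng.integers(10, 80))
        s = int(rng.integers(g.start, g.end - w))
        ivs.append(GenomicInterval("chr1", s, s + w))
    return PeakSet(ivs, label="real")


class TestGeneration:
    def test_width_multiset_preserved_exactly(self, flat_model, real_peaks):
        nulls = generate_null_profiles(real_peaks, flat_model, k=3, seed=11)
        want = Counter(iv.length for iv in real_peaks)
        for profile in nulls:
            assert Counter(iv.length for iv in profile) == want
            assert len(profile) == len(real_peaks)

    def test_zero_overlap_with_real_peaks(self, flat_model, real_peaks):
        from occupeak import max_overlap_fraction
        from occupeak.regions import OverlapRule

        nulls = generate_null_profiles(real_peaks, flat_model, k=3, seed=11)
        for profile in nulls:
            fr = max_overlap_fraction(profile, real_peaks, OverlapRule(min_fraction=1e-9))
            assert (fr == 0).all()

    def test_profiles_lie_inside_gene_spans(self, flat_model, real_peaks):
        nulls = generate_null_profiles(real_peaks, flat_model, k=2, seed=3)
        for profile in nulls:
            for iv in profile:
                assert flat_model.genes_containing(iv.chrom, iv.start, iv.end)

    def test_profiles_internally_disjoint(self, flat_model, real_peaks):
        nulls = generate_null_profiles(real_peaks, flat_model, k=2, seed=3)
        for profile in nulls:
            ivs = sorted(profile, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_same_seed_bit_identical(self, flat_model, real_peaks):
        n1 = generate_null_profiles(real_peaks, flat_model, k=2, seed=42)
        n2 = generate_null_profiles(real_peaks, flat_model, k=2, seed=42)
        for p1, p2 in zip(n1, n2):
            assert p1 == p2

    def test_different_seeds_differ_but_match_widths(self, flat_model, real_peaks):
        n1 = generate_null_profiles(real_peaks, flat_model, k=1, seed=1)
        n2 = generate_null_profiles(real_peaks, flat_model, k=1, seed=2)
        assert n1[0] != n2[0]
        assert Counter(iv.length for iv in n1[0]) == Counter(iv.length for iv in n2[0])

    def test_insufficient_space_refused(self):
        g = Gene("g", "chr1", 0, 1000, "+", "other", exons=((0, 1000),))
        model = GeneModel([g])
        real = PeakSet([GenomicInterval("chr1", 0, 400)])
        with pytest.raises(PlacementError, match="insufficient eligible"):
            generate_null_profiles(real, model, k=1, seed=0)

    def test_k_zero_rejected(self, flat_model, real_peaks):
        with pytest.raises(ValueError):
            generate_null_profiles(real_peaks, flat_model, k=0, seed=0)


class TestTightPlacement:
    def test_exact_fallback_finds_the_only_gap(self):
        """Adversarial fixture: a single width-30 slot among hundreds of
        2-bp slivers; rejection sampling alone would essentially never land
        on it, exhaustive placement must."""
        g = Gene("g", "chr1", 0, 2000, "+", "other", exons=((0, 2000),))
        model = GeneModel([g])
        excl = [GenomicInterval("chr1", i * 4, i * 4 + 2) for i in range(400)]
        excl.append(GenomicInterval("chr1", 1630, 2000))
        exclusion = PeakSet(excl)
        real = PeakSet([GenomicInterval("chr1", 1700, 1730)])  # width 30
        nulls = generate_null_profiles(real, model, k=1, seed=0,
                                       exclusion=exclusion)
        iv = nulls[0][0]
        assert iv.length == 30
        assert 1598 <= iv.start <= 1600  # the single wide slot

    def test_impossible_width_errors_with_width_named(self):
        g = Gene("g", "chr1", 0, 2000, "+", "other", exons=((0, 2000),))
        model = GeneModel([g])
        excl = PeakSet([GenomicInterval("chr1", i * 4, i * 4 + 2) for i in range(500)])
        real = PeakSet([GenomicInterval("chr1", 100, 130)])
        with pytest.raises(PlacementError, match="width 30"):
            generate_null_profiles(real, model, k=1, seed=0, exclusion=excl)


class TestAudit:
    def test_valid_profiles_pass(self, flat_model, real_peaks):
        nulls = generate_null_profiles(real_peaks, flat_model, k=2, seed=9)
        audit = null_profile_audit(nulls, real_peaks, flat_model)
        assert audit.ok
        assert audit.exclusion_violations == 0
        assert audit.out_of_gene == 0

    def test_planted_exclusion_violation_detected(self, flat_model, real_peaks):
        from occupeak.nullmodel import NullProfileSet

        nulls = generate_null_profiles(real_peaks, flat_model, k=1, seed=9)
        tampered = list(nulls[0])
        victim = real_peaks[0]
        tampered[0] = GenomicInterval(victim.chrom, victim.start, victim.start + tampered[0].length)
        bad = NullProfileSet(profiles=(PeakSet(tampered),), seed=9)
        audit = null_profile_audit(bad, real_peaks, flat_model)
        assert audit.exclusion_violations >= 1
        assert not audit.ok

    def test_widened_interval_flags_width_mismatch(self, flat_model, real_peaks):
        from occupeak.nullmodel import NullProfileSet

        nulls = generate_null_profiles(real_peaks, flat_model, k=1, seed=9)
        tampered = list(nulls[0])
        iv = tampered[0]
        tampered[0] = GenomicInterval(iv.chrom, iv.start, iv.end + 1)
        bad = NullProfileSet(profiles=(PeakSet(tampered),), seed=9)
        audit = null_profile_audit(bad, real_peaks, flat_model)
        assert audit.width_multiset_ok == (False,)
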