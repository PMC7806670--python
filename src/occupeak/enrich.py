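"""Fisher's-exact enrichment of real peaks against reference feature sets,
relative to width-matched null profiles.

One 2x2 table per null profile: real intervals hitting / missing the
reference versus null intervals hitting / missing it.  The headline number
is the odds ratio averaged across profiles; infinite per-profile odds
ratios are counted separately, never silently averaged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .nullmodel import NullProfileSet
from .overlaps import max_overlap_fraction
from .regions import OverlapRule, PeakSet, VariantSet
from .stats import fisher_exact

Reference = Union[PeakSet, VariantSet]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b real hitting/missing, c/d null hitting/missing."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for x in (self.a, self.b, self.c, self.d):
            if x < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n_real(self) -> int:
        return self.a + self.b

    @property
    def n_null(self) -> int:
        return self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class ProfileEnrichment:
    profile_index: int
    table: ContingencyTable
    odds_ratio: float
    p_value: float


@dataclass
class EnrichmentResult:
    """Per-profile tables plus the averaged odds ratio.

    ``mean_odds_ratio`` is the arithmetic mean of the *finite* per-profile
    odds ratios; ``n_infinite`` counts profiles whose OR was infinite (b*c=0
    with a*d>0) and is reported instead of being folded into the mean.
    """

    reference_label: str
    profiles: list[ProfileEnrichment]
    mean_odds_ratio: float
    n_infinite: int
    flags: list[str] = field(default_factory=list)

    @property
    def p_values(self) -> list[float]:
        return [p.p_value for p in self.profiles]

    @property
    def min_p(self) -> float:
        return min(self.p_values)


def hit_indicator(
    intervals: PeakSet, reference: Reference, rule: OverlapRule = OverlapRule()
) -> np.ndarray:
    """Boolean per interval: does it hit the reference?

    Against an interval reference, a hit is max overlap_fraction >=
    rule.min_fraction.  Against a variant catalog (point set) a hit is >= 1
    variant position inside the interval; the overlap rule is ignored.
    """
    if isinstance(reference, VariantSet):
        out = np.zeros(len(intervals), dtype=bool)
        for i, iv in enumerate(intervals):
            out[i] = reference.count_in(iv.chrom, iv.start, iv.end) > 0
        return out
    return max_overlap_fraction(intervals, reference, rule) >= rule.min_fraction


def _variant_unit_counts(intervals: PeakSet, reference: VariantSet) -> tuple[int, int]:
    """(variants inside the set, variants outside) for the per-variant table."""
    from .regions import _merge_pairs

    inside = 0
    covered: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        covered.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pos in reference.positions_by_chrom.items():
        ivs = _merge_pairs(covered.get(chrom, []))
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        idx = np.searchsorted(starts, pos, "right") - 1
        ok = idx >= 0
        inside += int((ok & (pos < ends[np.clip(idx, 0, None)])).sum())
    return inside, len(reference) - inside


def enrichment_vs_nulls(
    real: PeakSet,
    nulls: NullProfileSet,
    reference: Reference,
    rule: OverlapRule = OverlapRule(),
    unit: str = "peak",
) -> EnrichmentResult:
    """Fisher's-exact enrichment of the real peaks over each null profile.

    ``unit="peak"`` (default) counts intervals containing a hit;
    ``unit="variant"`` counts variant positions inside/outside the interval
    sets instead (only meaningful for variant references).
    """
    if len(reference) == 0:
        raise ValueError("enrichment_vs_nulls: empty reference")
    if unit not in ("peak", "variant"):
        raise ValueError(f"unit must be 'peak' or 'variant', got {unit!r}")
    if unit == "variant" and not isinstance(reference, VariantSet):
        raise ValueError("unit='variant' requires a VariantSet reference")

    label = getattr(reference, "label", None) or getattr(reference, "cohort", "reference")
    if unit == "peak":
        a = int(hit_indicator(real, reference, rule).sum())
        b = len(real) - a
    else:
        a, b = _variant_unit_counts(real, reference)

    profiles = []
    finite = []
    n_inf = 0
    flags: list[str] = []
    for i, profile in enumerate(nulls):
        if unit == "peak":
            c = int(hit_indicator(profile, reference, rule).sum())
            d = len(profile) - c
        else:
            c, d = _variant_unit_counts(profile, reference)
        table = ContingencyTable(a, b, c, d)
        odds, p = fisher_exact(a, b, c, d)
        profiles.append(ProfileEnrichment(i, table, odds, p))
        if math.isinf(odds):
            n_inf += 1
        elif not math.isnan(odds):
            finite.append(odds)
    mean_or = float(np.mean(finite)) if finite else math.nan
    if n_inf:
        flags.append(f"{n_inf} profile(s) with infinite odds ratio excluded from mean")
    if unit == "peak" and b == 0:
        flags.append("degenerate: every real interval hits the reference")
    return EnrichmentResult(
        reference_label=label,
        profiles=profiles,
        mean_odds_ratio=mean_or,
        n_infinite=n_inf,
        flags=flags,
    )


@dataclass
class DualReferenceContrast:
    result_a: EnrichmentResult
    result_b: EnrichmentResult
    verdict: str  # "A>B", "B>A", or "similar"
    log2_ratio: float


def dual_reference_contrast(
    real: PeakSet,
    nulls: NullProfileSet,
    ref_a: Reference,
    ref_b: Reference,
    rule: OverlapRule = OverlapRule(),
    similar_log2: float = 1.0,
) -> DualReferenceContrast:
    """Enrichment against two references from identical real/null inputs,
    e.g. a protein's RNA-side (CLIP) versus DNA-side (ChIP) binding profile.

    The contrast is "similar" when the mean odds ratios are within
    ``similar_log2`` doublings of each other.
    """
    if len(ref_a) == 0 or len(ref_b) == 0:
        raise ValueError("dual_reference_contrast: references must be non-empty")
    ra = enrichment_vs_nulls(real, nulls, ref_a, rule)
    rb = enrichment_vs_nulls(real, nulls, ref_b, rule)
    oa, ob = ra.mean_odds_ratio, rb.mean_odds_ratio
    if oa > 0 and ob > 0 and math.isfinite(oa) and math.isfinite(ob):
        log2_ratio = math.log2(oa / ob)
    else:
        log2_ratio = math.inf if oa > ob else (-math.inf if ob > oa else 0.0)
    if abs(log2_ratio) <= similar_log2:
        verdict = "similar"
    else:
        verdict = "A>B" if log2_ratio > 0 else "B>A"
    return DualReferenceContrast(result_a=ra, result_b=rb, verdict=verdict,
                                 log2_ratio=log2_ratio)
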