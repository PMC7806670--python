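"""Overlap arithmetic on peak sets.

This module carries the primitives under every downstream claim: base-level
overlap, the "end-to-end 50%" support rule, replicate merging, cross-protocol
gene sharing, the peak length distribution, and the binned replicate
correlation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import spearmanr

from .regions import GeneModel, GenomicInterval, OverlapRule, PeakSet


def _strands_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def overlap_bases(
    a: GenomicInterval, b: GenomicInterval, strand_aware: bool = False
) -> int:
    """Number of shared bases between two intervals; 0 on different
    chromosomes (or incompatible strands when strand_aware).  Symmetric."""
    if a.chrom != b.chrom:
        return 0
    if strand_aware and not _strands_compatible(a.strand, b.strand):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(
    query: GenomicInterval, ref: GenomicInterval, rule: OverlapRule = OverlapRule()
) -> float:
    """Fraction of the query (mode="query") or of both intervals
    (mode="reciprocal") covered by the pairwise overlap."""
    ov = overlap_bases(query, ref, strand_aware=rule.strand_aware)
    if ov == 0:
        return 0.0
    if rule.mode == "reciprocal":
        return min(ov / query.length, ov / ref.length)
    return ov / query.length


def _reference_trees(reference: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def max_overlap_fraction(
    query: PeakSet, reference: PeakSet, rule: OverlapRule = OverlapRule()
) -> np.ndarray:
    """For each query peak, the maximum overlap_fraction achieved against
    any single reference interval."""
    trees = _reference_trees(reference)
    out = np.zeros(len(query), dtype=float)
    for i, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        best = 0.0
        for hit in tree.overlap(q.start, q.end):
            best = max(best, overlap_fraction(q, hit.data, rule))
            if best >= 1.0:
                break
        out[i] = best
    return out


def merge_replicates(sets: Sequence[PeakSet], label: str = "") -> PeakSet:
    """Union of peak sets with overlapping or book-ended intervals coalesced
    (bedtools-merge semantics).  Idempotent; strand-blind."""
    if not sets:
        raise ValueError("merge_replicates: need at least one PeakSet")
    ivs = sorted(
        (iv for ps in sets for iv in ps), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[GenomicInterval] = []
    cur = None
    for iv in ivs:
        if cur is None or iv.chrom != cur[0] or iv.start > cur[2]:
            if cur is not None:
                merged.append(GenomicInterval(*cur))
            cur = [iv.chrom, iv.start, iv.end]
        else:
            cur[2] = max(cur[2], iv.end)
    if cur is not None:
        merged.append(GenomicInterval(*cur))
    if not label:
        label = "+".join(sorted({ps.label for ps in sets if ps.label})) or "merged"
    return PeakSet(merged, label=label)


def filter_supported(
    query: PeakSet, reference: PeakSet, rule: OverlapRule = OverlapRule()
) -> tuple[PeakSet, float]:
    """Peaks supported by the reference under ``rule``.

    A query peak is supported iff some single reference interval yields
    ``overlap_fraction >= rule.min_fraction``.  Returns the supported subset
    and the support fraction |supported| / |query|.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("filter_supported: query and reference must be non-empty")
    fracs = max_overlap_fraction(query, reference, rule)
    keep = fracs >= rule.min_fraction
    supported = PeakSet(
        [iv for iv, k in zip(query, keep) if k], label=f"{query.label}|supported"
    )
    return supported, float(keep.mean())


def support_by_min_fraction(
    query: PeakSet,
    reference: PeakSet,
    fractions: Sequence[float],
    mode: str = "query",
    max_peak_length: int | None = None,
) -> dict[float, float]:
    """Support fraction at each overlap threshold in ``fractions``.

    Monotonically non-increasing in the threshold.  ``max_peak_length``
    restricts the query to peaks of at most that length first (the ribosome
    footprint comparison uses <= 50 bp peaks).
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"thresholds must lie in (0, 1], got {f}")
    if max_peak_length is not None:
        query = PeakSet(
            [iv for iv in query if iv.length <= max_peak_length], label=query.label
        )
    if len(query) == 0:
        return {float(f): 0.0 for f in fractions}
    # one pass at the loosest rule: per-peak max fraction decides all thresholds
    fracs = max_overlap_fraction(
        query, reference, OverlapRule(min_fraction=min(fractions), mode=mode)
    )
    return {float(f): float((fracs >= f).mean()) for f in fractions}


def genes_with_peaks(peaks: PeakSet, model: GeneModel) -> set[str]:
    """Gene ids with >= 1 bp overlap between any peak and the gene span."""
    hit: set[str] = set()
    for iv in peaks:
        for g in model.genes_overlapping(iv.chrom, iv.start, iv.end):
            hit.add(g.gene_id)
    return hit


def shared_gene_fraction(sets: Sequence[set[str]]) -> float:
    """|intersection| / |union| over >= 2 gene-id sets."""
    if len(sets) < 2:
        raise ValueError("shared_gene_fraction: need >= 2 sets")
    union = set().union(*sets)
    if not union:
        return 0.0
    inter = set(sets[0]).intersection(*sets[1:])
    return len(inter) / len(union)


@dataclass(frozen=True)
class LengthHistogram:
    """Peak length distribution; counts conserve n."""

    edges: np.ndarray
    counts: np.ndarray
    n: int
    lengths: np.ndarray

    def fraction_below(self, length_bp: int) -> float:
        """Fraction of peaks with length strictly below ``length_bp``."""
        return float((self.lengths < length_bp).mean())


def length_histogram(peaks: PeakSet, bin_width: int = 10) -> LengthHistogram:
    if len(peaks) == 0:
        raise ValueError("length_histogram: empty PeakSet")
    lengths = peaks.widths()
    hi = int(np.ceil((lengths.max() + 1) / bin_width)) * bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    assert counts.sum() == len(peaks)
    return LengthHistogram(edges=edges, counts=counts, n=len(peaks), lengths=lengths)


def binned_midpoint_counts(
    peaks: PeakSet, chrom_sizes: Mapping[str, int], bin_size: int = 10_000
) -> np.ndarray:
    """Counts of interval midpoints per fixed genomic bin, concatenated over
    chromosomes in sorted name order."""
    parts = []
    by = peaks.by_chrom()
    for chrom in sorted(chrom_sizes):
        nbins = max(1, -(-chrom_sizes[chrom] // bin_size))
        counts = np.zeros(nbins, dtype=np.int64)
        arrs = by.get(chrom)
        if arrs is not None:
            mids = (arrs["starts"] + arrs["ends"]) // 2
            binned = np.clip(mids // bin_size, 0, nbins - 1)
            np.add.at(counts, binned, 1)
        parts.append(counts)
    return np.concatenate(parts)


def binned_count_correlation(
    a: PeakSet,
    b: PeakSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10_000,
) -> tuple[float, float]:
    """Spearman rank correlation of per-bin midpoint counts between two peak
    sets (default 10-kb bins), with average-rank ties.

    Returns (rho, rho**2); the field's replicate-reproducibility figure is
    reported as "R^2" so both are exposed.
    """
    ca = binned_midpoint_counts(a, chrom_sizes, bin_size)
    cb = binned_midpoint_counts(b, chrom_sizes, bin_size)
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("binned_count_correlation: degenerate input (all-zero bins)")
    rho = float(spearmanr(ca, cb).statistic)
    return rho, rho * rho
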