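"""Independent brute-force oracles used to verify the package's optimized
implementations.  Everything here is deliberately naive: per-position scans,
all-pairs loops, exact rational arithmetic, explicit enumerations."""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def brute_overlap_bases(a, b) -> int:
    """Count shared integer positions one by one."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def brute_max_fraction(query, reference, min_fraction=0.5, mode="query"):
    """All-pairs max overlap fraction per query peak."""
    out = np.zeros(len(query))
    for i, q in enumerate(query):
        best = 0.0
        for r in reference:
            if q.chrom != r.chrom:
                continue
            ov = max(0, min(q.end, r.end) - max(q.start, r.start))
            if ov == 0:
                continue
            frac = ov / q.length
            if mode == "reciprocal":
                frac = min(frac, ov / r.length)
            best = max(best, frac)
        out[i] = best
    return out


def brute_support_fraction(query, reference, min_fraction=0.5, mode="query") -> float:
    fr = brute_max_fraction(query, reference, min_fraction, mode)
    return float((fr >= min_fraction).mean())


def covered_bases_bitmap(intervals, genome_len: int) -> int:
    """Covered-base count via explicit per-chromosome bitmaps (<= 1e5 bp)."""
    masks: dict[str, np.ndarray] = {}
    for iv in intervals:
        masks.setdefault(iv.chrom, np.zeros(genome_len, dtype=bool))[iv.start: iv.end] = True
    return int(sum(m.sum() for m in masks.values()))


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals,
    applying the same relative-tolerance-1e-7 inclusion rule on the
    probability comparison as the implementation under test."""
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    tol = Fraction(10_000_001, 10_000_000)  # 1 + 1e-7
    total = sum(w for w in weights.values() if Fraction(w) <= Fraction(obs) * tol)
    return min(Fraction(total, denom), Fraction(1))


def ranksum_exact_oracle(n1: int, n2: int, u_obs: int) -> Fraction:
    """Two-sided exact rank-sum p by explicit enumeration of all
    C(n1+n2, n1) rank labelings (no ties)."""
    n = n1 + n2
    us = []
    for combo in itertools.combinations(range(1, n + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) // 2)
    us = np.array(us)
    total = len(us)
    cdf = Fraction(int((us <= u_obs).sum()), total)
    sf = Fraction(int((us >= u_obs).sum()), total)
    return min(Fraction(1), 2 * min(cdf, sf))


def brute_annotate(pos_chrom: str, pos: int, model, tss_window=1000, tts_window=1000,
                   priority=None):
    """Label one genomic position by scanning every gene's elements directly."""
    if priority is None:
        priority = ("promoter-TSS", "TTS", "5UTR", "exon", "3UTR",
                    "non-coding-exon", "intron", "intergenic")
    candidates = []
    for g in model:
        if g.chrom != pos_chrom:
            continue
        tss, tts = g.tss(), g.tts()
        if tss - tss_window <= pos < tss + tss_window:
            candidates.append(("promoter-TSS", g.gene_id))
        if tts - tts_window <= pos < tts + tts_window:
            candidates.append(("TTS", g.gene_id))
        if g.is_coding:
            for s, e in g.cds:
                if s <= pos < e:
                    candidates.append(("exon", g.gene_id))
            for s, e in g.utr5():
                if s <= pos < e:
                    candidates.append(("5UTR", g.gene_id))
            for s, e in g.utr3():
                if s <= pos < e:
                    candidates.append(("3UTR", g.gene_id))
        else:
            for s, e in g.merged_exons():
                if s <= pos < e:
                    candidates.append(("non-coding-exon", g.gene_id))
        for s, e in g.introns():
            if s <= pos < e:
                candidates.append(("intron", g.gene_id))
    if not candidates:
        return "intergenic", ""
    rank = {lab: i for i, lab in enumerate(priority)}
    return min(candidates, key=lambda t: (rank[t[0]], t[1]))


def brute_proximal_gap(exon, anchors) -> int:
    """Nearest end-to-end gap by scanning all anchors."""
    best = None
    for a in anchors:
        if a.chrom != exon.chrom:
            continue
        if a.start < exon.end and a.end > exon.start:
            return 0
        gap = a.start - exon.end if a.start >= exon.end else exon.start - a.end
        best = gap if best is None else min(best, gap)
    return best if best is not None else 10 ** 18


def spearman_oracle(x, y) -> float:
    """Spearman rho from average ranks + the Pearson formula, written out."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
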