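"""Width-matched random non-peak interval profiles.

The chance model of the whole analysis: each null profile contains exactly
as many intervals as the real peak set, with the identical width multiset,
placed uniformly inside gene bodies but outside the real peak territory
(and outside the other intervals of the same profile).
"""
from __future__ import annotations

from bisect import bisect_right, insort
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regions import GeneModel, GenomicInterval, OverlapRule, PeakSet


class PlacementError(RuntimeError):
    pass


@dataclass
class NullProfileSet:
    """k width-matched random non-peak profiles plus the generation record."""

    profiles: tuple[PeakSet, ...]
    seed: int
    constraints: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, i) -> PeakSet:
        return self.profiles[i]


def _clip_to_gene(iv: GenomicInterval, gene) -> tuple[int, int] | None:
    s, e = max(iv.start, gene.start), min(iv.end, gene.end)
    return (s, e) if s < e else None


class _BlockedSpace:
    """Per-gene sorted non-overlapping blocked intervals with O(log n)
    free-space checks and insertion."""

    __slots__ = ("starts", "ends")

    def __init__(self, blocks: Sequence[tuple[int, int]]) -> None:
        merged: list[list[int]] = []
        for s, e in sorted(blocks):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = [s for s, _ in merged]
        self.ends = [e for _, e in merged]

    def is_free(self, s: int, e: int) -> bool:
        i = bisect_right(self.starts, s)
        if i > 0 and self.ends[i - 1] > s:
            return False
        if i < len(self.starts) and self.starts[i] < e:
            return False
        return True

    def add(self, s: int, e: int) -> None:
        i = bisect_right(self.starts, s)
        self.starts.insert(i, s)
        self.ends.insert(i, e)

    def blocked_bases(self) -> int:
        return sum(e - s for s, e in zip(self.starts, self.ends))

    def free_gaps(self, lo: int, hi: int) -> list[tuple[int, int]]:
        gaps = []
        cursor = lo
        for s, e in zip(self.starts, self.ends):
            if s > cursor:
                gaps.append((cursor, min(s, hi)))
            cursor = max(cursor, e)
            if cursor >= hi:
                break
        if cursor < hi:
            gaps.append((cursor, hi))
        return [(s, e) for s, e in gaps if s < e]


def generate_null_profiles(
    real: PeakSet,
    model: GeneModel,
    k: int = 5,
    seed: int = 0,
    exclusion: PeakSet | None = None,
    max_attempts: int = 64,
) -> NullProfileSet:
    """Generate ``k`` width-matched random non-peak profiles.

    For each real peak width (processed in descending order) a gene is drawn
    with probability proportional to the number of fitting start positions,
    a uniform start is drawn inside it, and the placement is redrawn when it
    touches the exclusion set (default: the real peaks) or an interval
    already placed in the same profile.  After ``max_attempts`` rejections
    the generator falls back to exact enumeration of the remaining free
    placements, so placement fails only when no placement exists at all.
    Deterministic given ``seed``; profile i uses the stream (seed, i).
    """
    if len(real) == 0:
        raise ValueError("generate_null_profiles: empty real PeakSet")
    if k < 1:
        raise ValueError("generate_null_profiles: k must be >= 1")
    if exclusion is None:
        exclusion = real

    genes = list(model.genes)
    # static per-gene exclusion blocks (real peaks clipped to the gene span)
    excl_blocks: list[list[tuple[int, int]]] = [[] for _ in genes]
    gene_pos = {g.gene_id: i for i, g in enumerate(genes)}
    for iv in exclusion:
        for g in model.genes_overlapping(iv.chrom, iv.start, iv.end):
            clipped = _clip_to_gene(iv, g)
            if clipped:
                excl_blocks[gene_pos[g.gene_id]].append(clipped)

    total_gene = model.total_gene_bases
    blocked0 = sum(_BlockedSpace(b).blocked_bases() for b in excl_blocks)
    eligible = total_gene - blocked0
    need = 2 * real.total_bases
    if eligible < need:
        raise PlacementError(
            f"insufficient eligible gene space: {eligible} bp free but "
            f"{need} bp (2x total peak bases) required"
        )

    widths = sorted((iv.length for iv in real), reverse=True)
    span_lens = np.array([g.length for g in genes], dtype=np.int64)

    profiles = []
    for pi in range(k):
        rng = np.random.default_rng(np.random.SeedSequence([seed, pi]))
        blocked = [_BlockedSpace(b) for b in excl_blocks]
        placed: list[GenomicInterval] = []
        weights_cache: dict[int, np.ndarray] = {}

        def _commit(chrom: str, s: int, e: int) -> None:
            # block the territory in every gene the interval touches, so
            # profiles stay non-overlapping even when gene spans overlap
            for g2 in model.genes_overlapping(chrom, s, e):
                cs, ce = max(s, g2.start), min(e, g2.end)
                blocked[gene_pos[g2.gene_id]].add(cs, ce)
            placed.append(GenomicInterval(chrom, s, e))

        for w in widths:
            cum = weights_cache.get(w)
            if cum is None:
                fit = np.maximum(0, span_lens - w + 1)
                cum = np.cumsum(fit, dtype=np.float64)
                if cum[-1] <= 0:
                    raise PlacementError(f"no gene can fit an interval of width {w}")
                weights_cache[w] = cum
            placed_ok = False
            for _ in range(max_attempts):
                gi = int(np.searchsorted(cum, rng.random() * cum[-1], "right"))
                g = genes[gi]
                s = g.start + int(rng.integers(0, g.length - w + 1))
                if blocked[gi].is_free(s, s + w):
                    _commit(g.chrom, s, s + w)
                    placed_ok = True
                    break
            if not placed_ok:
                # exact fallback: enumerate every remaining free start
                choices: list[tuple[int, int, int]] = []  # (gene idx, gap start, count)
                total = 0
                for gi, g in enumerate(genes):
                    if g.length < w:
                        continue
                    for gs, ge in blocked[gi].free_gaps(g.start, g.end):
                        cnt = ge - gs - w + 1
                        if cnt > 0:
                            choices.append((gi, gs, cnt))
                            total += cnt
                if total == 0:
                    raise PlacementError(
                        f"profile {pi}: no free placement for interval width {w}"
                    )
                j = int(rng.integers(0, total))
                for gi, gs, cnt in choices:
                    if j < cnt:
                        s = gs + j
                        break
                    j -= cnt
                g = genes[gi]
                _commit(g.chrom, s, s + w)
        profiles.append(PeakSet(placed, label=f"null/{pi}"))

    constraints = {
        "k": k,
        "max_attempts": max_attempts,
        "exclusion_n": len(exclusion),
        "exclusion_label": exclusion.label,
        "n_genes": len(genes),
        "eligible_bases": int(eligible),
    }
    return NullProfileSet(profiles=tuple(profiles), seed=seed, constraints=constraints)


@dataclass(frozen=True)
class NullAudit:
    width_multiset_ok: tuple[bool, ...]
    exclusion_violations: int
    out_of_gene: int

    @property
    def ok(self) -> bool:
        return (
            all(self.width_multiset_ok)
            and self.exclusion_violations == 0
            and self.out_of_gene == 0
        )

    def as_dict(self) -> dict:
        return {
            "width_multiset_ok": list(self.width_multiset_ok),
            "exclusion_violations": self.exclusion_violations,
            "out_of_gene": self.out_of_gene,
            "ok": self.ok,
        }


def null_profile_audit(
    nulls: NullProfileSet,
    real: PeakSet,
    model: GeneModel,
    exclusion: PeakSet | None = None,
) -> NullAudit:
    """Check the three invariants of a null profile set: exact width-multiset
    equality with the real set, zero overlap with the exclusion set, and
    containment of every interval in some gene span."""
    from .overlaps import max_overlap_fraction  # local import avoids cycle

    if exclusion is None:
        exclusion = real
    real_widths = Counter(int(iv.length) for iv in real)
    width_ok = []
    violations = 0
    out_of_gene = 0
    for profile in nulls:
        width_ok.append(Counter(int(iv.length) for iv in profile) == real_widths)
        if len(profile) and len(exclusion):
            fr = max_overlap_fraction(profile, exclusion, OverlapRule(min_fraction=1e-9))
            violations += int((fr > 0).sum())
        for iv in profile:
            if not model.genes_containing(iv.chrom, iv.start, iv.end):
                out_of_gene += 1
    return NullAudit(
        width_multiset_ok=tuple(width_ok),
        exclusion_violations=violations,
        out_of_gene=out_of_gene,
    )
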