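"""Peak-to-transcript-element annotation.

Each peak is assigned exactly one element label by looking up its midpoint
in a precomputed genome partition, with a fixed priority ladder resolving
positions covered by several candidate elements (the behaviour of
HOMER-style peak annotators: peak centre, priority annotation).
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .regions import GeneModel, GenomicInterval, PeakSet

PROMOTER = "promoter-TSS"
TTS = "TTS"
UTR5 = "5UTR"
EXON = "exon"
UTR3 = "3UTR"
NC_EXON = "non-coding-exon"
INTRON = "intron"
INTERGENIC = "intergenic"

#: Highest priority first; a position covered by several candidates gets the
#: earliest label in this ladder.
DEFAULT_PRIORITY: tuple[str, ...] = (
    PROMOTER, TTS, UTR5, EXON, UTR3, NC_EXON, INTRON, INTERGENIC
)

ELEMENT_LABELS = DEFAULT_PRIORITY


@dataclass(frozen=True)
class ElementSegment:
    start: int
    end: int
    label: str
    gene_id: str
    biotype: str


class ElementIndex:
    """Partition of each chromosome into winner element segments.

    Lookup is a binary search over non-overlapping segments; positions not
    covered by any segment resolve to intergenic.
    """

    def __init__(self, segments: dict[str, list[ElementSegment]],
                 priority: Sequence[str] = DEFAULT_PRIORITY) -> None:
        self._segments = {c: sorted(segs, key=lambda s: s.start)
                          for c, segs in segments.items()}
        self._starts = {c: [s.start for s in segs] for c, segs in self._segments.items()}
        self.priority = tuple(priority)

    def lookup(self, chrom: str, pos: int) -> tuple[str, str, str]:
        """(label, gene_id, biotype) at a single position."""
        segs = self._segments.get(chrom)
        if segs:
            i = bisect_right(self._starts[chrom], pos) - 1
            if i >= 0 and segs[i].start <= pos < segs[i].end:
                s = segs[i]
                return s.label, s.gene_id, s.biotype
        return INTERGENIC, "", ""

    def segments_by_label(self, label: str) -> list[tuple[str, ElementSegment]]:
        out = []
        for chrom in sorted(self._segments):
            for seg in self._segments[chrom]:
                if seg.label == label:
                    out.append((chrom, seg))
        return out

    def all_segments(self) -> dict[str, list[ElementSegment]]:
        return self._segments


def _gene_candidates(gene, tss_window: int, tts_window: int):
    """(start, end, label) candidate element intervals for one gene."""
    cands: list[tuple[int, int, str]] = []
    tss, tts = gene.tss(), gene.tts()
    if tss_window > 0:
        cands.append((max(0, tss - tss_window), tss + tss_window, PROMOTER))
    if tts_window > 0:
        cands.append((max(0, tts - tts_window), tts + tts_window, TTS))
    if gene.is_coding:
        for s, e in gene.cds:
            cands.append((s, e, EXON))
        for s, e in gene.utr5():
            cands.append((s, e, UTR5))
        for s, e in gene.utr3():
            cands.append((s, e, UTR3))
    else:
        for s, e in gene.merged_exons():
            cands.append((s, e, NC_EXON))
    for s, e in gene.introns():
        cands.append((s, e, INTRON))
    return cands


def build_element_index(
    model: GeneModel,
    tss_window: int = 1000,
    tts_window: int = 1000,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> ElementIndex:
    """Build the genome partition from a gene model.

    CDS intervals are labeled exon; exons of non-coding genes are labeled
    non-coding-exon; UTRs are derived from the CDS extent; +-window
    neighbourhoods of the transcript start / end get promoter-TSS / TTS
    labels.  A gene without exons is an error.
    """
    rank = {lab: i for i, lab in enumerate(priority)}
    by_chrom: dict[str, list[tuple[int, int, int, str, str, str]]] = {}
    for g in model:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        for s, e, lab in _gene_candidates(g, tss_window, tts_window):
            if s < e:
                by_chrom.setdefault(g.chrom, []).append(
                    (s, e, rank[lab], lab, g.gene_id, g.biotype)
                )

    segments: dict[str, list[ElementSegment]] = {}
    for chrom, cands in by_chrom.items():
        bounds = sorted({s for s, *_ in cands} | {e for _, e, *_ in cands})
        # sweep elementary intervals; winner = best (rank, gene_id) covering it
        events: list[tuple[int, int, int]] = []  # (pos, +1/-1, cand idx)
        for idx, (s, e, *_rest) in enumerate(cands):
            events.append((s, 1, idx))
            events.append((e, -1, idx))
        events.sort()
        active: set[int] = set()
        segs: list[ElementSegment] = []
        ei = 0
        for bi in range(len(bounds) - 1):
            lo, hi = bounds[bi], bounds[bi + 1]
            while ei < len(events) and events[ei][0] <= lo:
                _, delta, idx = events[ei]
                if delta > 0:
                    active.add(idx)
                else:
                    active.discard(idx)
                ei += 1
            if not active:
                continue
            win = min(active, key=lambda i: (cands[i][2], cands[i][4], i))
            _, _, _, lab, gid, bt = cands[win]
            if segs and segs[-1].end == lo and segs[-1].label == lab and segs[-1].gene_id == gid:
                segs[-1] = ElementSegment(segs[-1].start, hi, lab, gid, bt)
            else:
                segs.append(ElementSegment(lo, hi, lab, gid, bt))
        segments[chrom] = segs
    return ElementIndex(segments, priority)


def annotate_peak(peak: GenomicInterval, index: ElementIndex) -> tuple[str, str]:
    """(element label, gene id) at the peak midpoint; exactly one label."""
    label, gid, _ = index.lookup(peak.chrom, peak.midpoint)
    return label, gid


def annotate_peaks(peaks: PeakSet, index: ElementIndex) -> pd.DataFrame:
    """One row per peak: coordinates, element label, gene id, biotype."""
    rows = []
    for iv in peaks:
        label, gid, bt = index.lookup(iv.chrom, iv.midpoint)
        rows.append((iv.chrom, iv.start, iv.end, iv.strand, label, gid, bt))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "element", "gene_id", "biotype"]
    )


def element_composition(peaks: PeakSet, index: ElementIndex) -> pd.Series:
    """Proportion of peaks per element label; proportions sum to 1."""
    if len(peaks) == 0:
        raise ValueError("element_composition: empty PeakSet")
    labels = [index.lookup(iv.chrom, iv.midpoint)[0] for iv in peaks]
    counts = pd.Series(labels).value_counts()
    props = counts / counts.sum()
    return props.reindex(list(index.priority), fill_value=0.0)


def gene_type_fractions(peaks: PeakSet, model: GeneModel) -> pd.Series:
    """Per biotype: fraction of that biotype's genes hit by >= 1 bp of peak.

    Denominators are per-biotype gene totals, so fractions across biotypes
    need not sum to 1.
    """
    if len(peaks) == 0:
        raise ValueError("gene_type_fractions: empty PeakSet")
    from .overlaps import genes_with_peaks  # local import avoids cycle

    hit = genes_with_peaks(peaks, model)
    totals = model.biotype_counts()
    hit_counts: dict[str, int] = {bt: 0 for bt in totals}
    for gid in hit:
        hit_counts[model.get(gid).biotype] += 1
    return pd.Series(
        {bt: hit_counts[bt] / totals[bt] for bt in sorted(totals)}, dtype=float
    )
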