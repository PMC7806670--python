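"""Expression-association analyses.

Two functional readouts of occupancy peaks:

* knockout dysregulation — the expression of exons lying within 1 kb of
  RBP-supported peaks, compared between a CRISPR knockout and its
  non-targeting control with a rank-sum test;
* the lncRNA "sponge" association — per-gene peak density (peaks per bp of
  gene length) compared between low- and high-expression gene groups split
  at the median TPM.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .overlaps import filter_supported
from .regions import ExpressionMatrix, GeneModel, GenomicInterval, OverlapRule, PeakSet
from .stats import RankSumResult, rank_sum_test

logger = logging.getLogger("occupeak")


@dataclass
class ProximalExonSet:
    """Exons within ``max_distance`` bp of at least one anchor peak."""

    exon_ids: list[str]
    intervals: dict[str, GenomicInterval]
    anchors: PeakSet
    max_distance: int

    def __len__(self) -> int:
        return len(self.exon_ids)


@dataclass
class DensityBins:
    """Per-gene peak density with a low/high expression group label."""

    density: pd.Series  # gene id -> peaks per bp
    group: pd.Series  # gene id -> "low" | "high"
    biotype: str
    median_tpm: float

    def group_values(self, name: str) -> np.ndarray:
        return self.density[self.group == name].to_numpy()


def exon_id(gene_id: str, index: int) -> str:
    """Canonical exon feature id used by the simulator and the expression
    matrices: ``<gene_id>.e<index>`` with 1-based exon index."""
    return f"{gene_id}.e{index}"


def model_exons(model: GeneModel) -> dict[str, GenomicInterval]:
    """All exons of the model keyed by canonical exon id."""
    out = {}
    for g in model:
        for i, (s, e) in enumerate(g.exons, 1):
            out[exon_id(g.gene_id, i)] = GenomicInterval(g.chrom, s, e, g.strand)
    return out


def supported_peaks_for_rbp(
    peaks: PeakSet, rbp_profile: PeakSet, rule: OverlapRule | None = None
) -> PeakSet:
    """Peaks with >= 50% of their bases covered by one of the RBP's binding
    intervals (query-mode overlap); the anchors of the knockout analysis."""
    if rule is None:
        rule = OverlapRule(min_fraction=0.5, mode="query")
    if len(peaks) == 0 or len(rbp_profile) == 0:
        logger.warning("supported_peaks_for_rbp: empty input, returning empty set")
        return PeakSet([], label=f"{peaks.label}|supported")
    supported, frac = filter_supported(peaks, rbp_profile, rule)
    if len(supported) == 0:
        logger.warning("supported_peaks_for_rbp: no peak reaches the support threshold")
    return supported


def _nearest_gap(
    exon: GenomicInterval, starts: np.ndarray, end_prefmax: np.ndarray,
    ends_sorted: np.ndarray
) -> int:
    """Smallest end-to-end gap (0 on overlap) between an exon and anchors on
    one chromosome.  ``starts`` sorted; ``end_prefmax`` is the running max
    of ends in start order."""
    # overlap?
    i = np.searchsorted(starts, exon.end, "left")
    if i > 0 and end_prefmax[i - 1] > exon.start:
        return 0
    best = None
    # nearest anchor entirely to the right
    if i < len(starts):
        best = int(starts[i] - exon.end)
    # nearest anchor entirely to the left (largest end <= exon.start)
    j = np.searchsorted(ends_sorted, exon.start, "right") - 1
    if j >= 0:
        gap = int(exon.start - ends_sorted[j])
        best = gap if best is None else min(best, gap)
    return best if best is not None else np.iinfo(np.int64).max


def proximal_exons(
    anchors: PeakSet, model: GeneModel, max_distance: int = 1000
) -> ProximalExonSet:
    """Exons whose gap to the nearest anchor on the same chromosome is
    strictly below ``max_distance`` bp (gap 0 when overlapping);
    strand-blind."""
    by = anchors.by_chrom()
    ends_sorted = {c: np.sort(d["ends"]) for c, d in by.items()}
    prefmax = {c: np.maximum.accumulate(d["ends"]) for c, d in by.items()}
    ids, ivs = [], {}
    for eid, exon in model_exons(model).items():
        arrs = by.get(exon.chrom)
        if arrs is None:
            continue
        gap = _nearest_gap(exon, arrs["starts"], prefmax[exon.chrom],
                           ends_sorted[exon.chrom])
        if gap < max_distance:
            ids.append(eid)
            ivs[eid] = exon
    return ProximalExonSet(exon_ids=ids, intervals=ivs, anchors=anchors,
                           max_distance=max_distance)


def ko_dysregulation(
    expr_kd: ExpressionMatrix,
    expr_ctrl: ExpressionMatrix,
    exons: ProximalExonSet,
) -> tuple[RankSumResult, pd.DataFrame]:
    """Rank-sum comparison of proximal-exon expression between knockout and
    control.

    Each condition's per-exon expression is the mean TPM across that
    condition's replicates; the two per-exon vectors are compared with
    :func:`rank_sum_test`.  ``direction`` of the result is
    median(KD) - median(control): negative means reduced expression after
    knockout.
    """
    shared = [
        eid for eid in exons.exon_ids
        if eid in expr_kd.data.index and eid in expr_ctrl.data.index
    ]
    if len(shared) < 2:
        raise ValueError(
            f"ko_dysregulation: only {len(shared)} proximal exons shared between "
            "the two matrices (need >= 2)"
        )
    kd = expr_kd.data.loc[shared].mean(axis=1)
    ctrl = expr_ctrl.data.loc[shared].mean(axis=1)
    result = rank_sum_test(kd.to_numpy(), ctrl.to_numpy())
    summary = pd.DataFrame(
        {
            "condition": ["KD", "control"],
            "n_exons": [len(shared), len(shared)],
            "median_tpm": [float(kd.median()), float(ctrl.median())],
            "mean_tpm": [float(kd.mean()), float(ctrl.mean())],
        }
    )
    return result, summary


def peak_density(
    peaks: PeakSet, model: GeneModel, biotype: str | None = None
) -> pd.Series:
    """Per-gene peak density: peaks with >= 1 bp span overlap divided by the
    gene span length in bp.  A peak overlapping two genes counts once for
    each."""
    genes = [g for g in model if biotype is None or g.biotype == biotype]
    counts = {g.gene_id: 0 for g in genes}
    wanted = set(counts)
    for iv in peaks:
        for g in model.genes_overlapping(iv.chrom, iv.start, iv.end):
            if g.gene_id in wanted:
                counts[g.gene_id] += 1
    return pd.Series(
        {gid: counts[gid] / model.get(gid).length for gid in sorted(counts)},
        dtype=float,
        name="density",
    )


def expression_density_test(
    densities: pd.Series,
    expr: ExpressionMatrix,
    model: GeneModel,
    biotype: str = "lncRNA",
    min_tpm: float = 0.0,
) -> tuple[RankSumResult, DensityBins]:
    """Peak density of high- versus low-expression genes of one biotype.

    Expressed genes (mean TPM > ``min_tpm``) are split at their median TPM,
    ties to the low group; the density distributions of the two groups are
    compared with :func:`rank_sum_test`.  ``direction`` of the result is
    median(high) - median(low).
    """
    mean_tpm = expr.mean_tpm()
    gene_ids = [
        gid for gid in densities.index
        if gid in mean_tpm.index
        and model.get(gid).biotype == biotype
        and mean_tpm[gid] > min_tpm
    ]
    if len(gene_ids) < 4:
        raise ValueError(
            f"expression_density_test: need >= 4 expressed {biotype} genes, "
            f"got {len(gene_ids)}"
        )
    tpm = mean_tpm[gene_ids]
    median = float(tpm.median())
    if (tpm == median).all():
        raise ValueError("expression_density_test: degenerate split (all TPM equal)")
    group = pd.Series(np.where(tpm > median, "high", "low"), index=gene_ids)
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError("expression_density_test: degenerate split (one group empty)")
    dens = densities[gene_ids]
    result = rank_sum_test(
        dens[group == "high"].to_numpy(), dens[group == "low"].to_numpy()
    )
    bins = DensityBins(density=dens, group=group, biotype=biotype, median_tpm=median)
    return result, bins
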