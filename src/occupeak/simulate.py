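"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of a protein-occupancy
peak study: a multi-gene genome with exon/UTR/intron substructure, three
protocols x two replicates of peak sets with a right-skewed width
distribution (majority < 50 bp), a reference binding profile with a planted
per-peak support probability over a diffuse background, variant catalogs
with planted in-peak enrichment, and gene/exon TPM matrices with a planted
knockout effect on peak-proximal exons and a planted density-expression
association on lncRNAs.

All planted effects are injected structurally (placement, assignment,
scaling of means) rather than by post-hoc label flipping, and every planted
parameter is recorded in a JSON-serializable :class:`SyntheticTruth`
sidecar from which the whole dataset can be regenerated bit-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .annotate import build_element_index
from .expression import exon_id, model_exons, proximal_exons, supported_peaks_for_rbp
from .io import (
    write_bed,
    write_chrom_sizes,
    write_expression,
    write_gtf,
    write_variants_vcf,
)
from .overlaps import merge_replicates
from .regions import (
    ExpressionMatrix,
    Gene,
    GeneModel,
    GenomicInterval,
    OverlapRule,
    PeakSet,
    VariantSet,
)

logger = logging.getLogger("occupeak")

# fixed stream salts so every stage has its own reproducible substream
_SALT_GENOME, _SALT_EXPR, _SALT_PEAKS, _SALT_VAR, _SALT_KO = 11, 22, 33, 44, 55


def _rng(seed: int, *salts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salts)]))


# ---------------------------------------------------------------------------
# specs


@dataclass
class GenomeSpec:
    """Genome layout: chromosome count/length and gene architecture."""

    n_chroms: int = 3
    chrom_length: int = 700_000
    n_genes: int = 200
    biotype_mix: dict = field(
        default_factory=lambda: {"protein_coding": 0.6, "lncRNA": 0.3, "snoRNA": 0.1}
    )
    spacing: tuple[int, int] = (600, 1800)
    coding_exons: tuple[int, int] = (5, 8)
    coding_exon_len: tuple[int, int] = (100, 300)
    coding_intron_len: tuple[int, int] = (800, 3000)
    utr5_exonic: tuple[int, int] = (150, 450)
    utr3_exonic: tuple[int, int] = (400, 800)
    lnc_exons: tuple[int, int] = (2, 4)
    lnc_exon_len: tuple[int, int] = (200, 500)
    lnc_intron_len: tuple[int, int] = (500, 2000)
    sno_exon_len: tuple[int, int] = (80, 200)


@dataclass
class PeakSpec:
    """Peak placement: per-protocol/replicate counts, width distribution,
    element mixture, planted reference support and background coverage."""

    protocols: tuple[str, ...] = ("NPOP", "FPOP", "UPOP")
    replicates: int = 2
    n_peaks: int = 6000
    frac_below_50: float = 0.85
    width_sigma: float = 0.9
    element_mixture: dict = field(
        default_factory=lambda: {
            "exon": 0.48,
            "intron": 0.19,
            "3UTR": 0.16,
            "5UTR": 0.05,
            "promoter-TSS": 0.05,
            "TTS": 0.04,
            "non-coding-exon": 0.03,
        }
    )
    p_support: float = 0.68
    support_protocol: str = "NPOP"
    p_background: float = 0.10
    background_block: int = 300
    background_mode: str = "non-peak"  # or "independent"
    replicate_keep: float = 0.9
    jitter_sd: float = 5.0


@dataclass
class ExpressionSpec:
    """Expression matrices: baseline log-normal TPM, replicate noise, the
    knockout folds on proximal exons and the lncRNA density multiplier."""

    n_samples: int = 5
    log_tpm_mu: float = 1.5
    log_tpm_sigma: float = 1.0
    noise_cv: float = 0.2
    density_multiplier: float = 3.0
    ko_folds: dict = field(default_factory=lambda: {"DGCR8": 0.5, "IGF2BP1": 2.0})
    kd_samples: dict = field(default_factory=lambda: {"DGCR8": 6, "IGF2BP1": 2})
    ctrl_samples: int = 8
    max_distance: int = 1000


@dataclass
class VariantSpec:
    """Variant cohorts with target analytic odds ratios for in-peak
    enrichment; the in-peak rate is solved from the target."""

    cohort_targets: dict = field(
        default_factory=lambda: {
            "GWAS": 1.45,
            "PhenVar": 22.0,
            "ClinVar": 22.0,
            "SomaticVar": 22.0,
        }
    )
    rate_out: float = 5e-4


@dataclass
class SimulationConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    variants: VariantSpec = field(default_factory=VariantSpec)
    with_expression: bool = True
    with_variants: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        def tup(x):
            return tuple(x) if isinstance(x, list) else x

        g = {k: tup(v) for k, v in d["genome"].items()}
        p = {k: tup(v) for k, v in d["peaks"].items()}
        return cls(
            genome=GenomeSpec(**g),
            peaks=PeakSpec(**p),
            expression=ExpressionSpec(**d["expression"]),
            variants=VariantSpec(**d["variants"]),
            with_expression=d.get("with_expression", True),
            with_variants=d.get("with_variants", True),
        )


def paper_like() -> SimulationConfig:
    """The default study conditions: 3 protocols x 2 replicates, 85% of peak
    widths below 50 bp, the Fig-2D-like element mixture, 68% planted
    reference support, 10% background coverage, cohort odds-ratio targets
    1.45 (GWAS) and 22 (others), knockout folds 0.5 and 2.0, and a 3x
    density multiplier on highly expressed lncRNAs."""
    return SimulationConfig()


def small_test() -> SimulationConfig:
    """A miniature configuration for fast smoke tests."""
    cfg = SimulationConfig(
        genome=GenomeSpec(n_chroms=1, chrom_length=550_000, n_genes=40),
        peaks=PeakSpec(n_peaks=400),
    )
    return cfg


# ---------------------------------------------------------------------------
# genome


def _build_gene(gid: str, chrom: str, start: int, biotype: str,
                spec: GenomeSpec, rng: np.random.Generator) -> Gene:
    strand = "+" if rng.random() < 0.5 else "-"
    if biotype == "protein_coding":
        k = int(rng.integers(spec.coding_exons[0], spec.coding_exons[1] + 1))
        ex_len = rng.integers(spec.coding_exon_len[0], spec.coding_exon_len[1] + 1, k)
        in_len = rng.integers(spec.coding_intron_len[0], spec.coding_intron_len[1] + 1,
                              max(0, k - 1))
    elif biotype == "lncRNA":
        k = int(rng.integers(spec.lnc_exons[0], spec.lnc_exons[1] + 1))
        ex_len = rng.integers(spec.lnc_exon_len[0], spec.lnc_exon_len[1] + 1, k)
        in_len = rng.integers(spec.lnc_intron_len[0], spec.lnc_intron_len[1] + 1,
                              max(0, k - 1))
    else:  # snoRNA and anything else: single short exon
        k = 1
        ex_len = rng.integers(spec.sno_exon_len[0], spec.sno_exon_len[1] + 1, 1)
        in_len = np.array([], dtype=int)

    exons = []
    cursor = start
    for i in range(k):
        exons.append((cursor, cursor + int(ex_len[i])))
        cursor += int(ex_len[i])
        if i < k - 1:
            cursor += int(in_len[i])
    end = cursor

    cds: tuple = ()
    if biotype == "protein_coding":
        # UTR lengths in exonic bp; they may cross introns, so UTR bases can
        # lie genomically outside the TSS/TTS windows (as real UTRs do)
        ex_total = int(ex_len.sum())
        utr5_e = int(rng.integers(spec.utr5_exonic[0], spec.utr5_exonic[1] + 1))
        utr3_e = int(rng.integers(spec.utr3_exonic[0], spec.utr3_exonic[1] + 1))
        if utr5_e + utr3_e + 100 > ex_total:
            scale = (ex_total - 100) / (utr5_e + utr3_e)
            utr5_e = max(1, int(utr5_e * scale))
            utr3_e = max(1, int(utr3_e * scale))
        left_e = utr5_e if strand == "+" else utr3_e
        right_e = utr3_e if strand == "+" else utr5_e

        def exonic_to_genomic_from_left(off: int) -> int:
            for s, e in exons:
                if off < e - s:
                    return s + off
                off -= e - s
            return exons[-1][1]

        def exonic_to_genomic_from_right(off: int) -> int:
            for s, e in reversed(exons):
                if off < e - s:
                    return e - off
                off -= e - s
            return exons[0][0]

        cds_lo = exonic_to_genomic_from_left(left_e)
        cds_hi = exonic_to_genomic_from_right(right_e)
        cds = tuple(
            (max(s, cds_lo), min(e, cds_hi))
            for s, e in exons
            if max(s, cds_lo) < min(e, cds_hi)
        )
    return Gene(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                biotype=biotype, exons=tuple(exons), cds=cds)


def make_genome(spec: GenomeSpec, seed: int) -> GeneModel:
    """Generate a gene model of non-overlapping genes with valid exon/CDS
    structure and the requested biotype mix.  Deterministic given seed."""
    rng = _rng(seed, _SALT_GENOME)
    biotypes = sorted(spec.biotype_mix)  # canonical order: independent of dict order
    probs = np.array([spec.biotype_mix[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()
    chosen = rng.choice(len(biotypes), size=spec.n_genes, p=probs)

    chrom_sizes = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    chrom_names = sorted(chrom_sizes)
    genes = []
    ci = 0
    cursor = int(rng.integers(spec.spacing[0], spec.spacing[1] + 1))
    for gi in range(spec.n_genes):
        biotype = biotypes[chosen[gi]]
        gid = f"G{gi + 1:04d}"
        placed = False
        while ci < len(chrom_names):
            g = _build_gene(gid, chrom_names[ci], cursor, biotype, spec, rng)
            if g.end + spec.spacing[0] <= chrom_sizes[chrom_names[ci]]:
                genes.append(g)
                cursor = g.end + int(rng.integers(spec.spacing[0], spec.spacing[1] + 1))
                placed = True
                break
            ci += 1
            cursor = int(rng.integers(spec.spacing[0], spec.spacing[1] + 1))
        if not placed:
            raise ValueError(
                f"make_genome: cannot fit {spec.n_genes} genes into "
                f"{spec.n_chroms} x {spec.chrom_length} bp (placed {len(genes)})"
            )
    return GeneModel(genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# widths


def width_mu(frac_below_50: float, sigma: float) -> float:
    """Location of the log-normal width distribution such that
    P(round(width) < 50) = frac_below_50: the exact solution of
    Phi((ln 49.5 - mu) / sigma) = frac_below_50."""
    return math.log(49.5) - sigma * norm.ppf(frac_below_50)


def draw_widths(n: int, frac_below_50: float, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    mu = width_mu(frac_below_50, sigma)
    w = np.rint(rng.lognormal(mean=mu, sigma=sigma, size=n)).astype(np.int64)
    return np.maximum(w, 1)


# ---------------------------------------------------------------------------
# peaks


_JITTER_MARGIN = 15  # bp kept clear of segment borders so jitter cannot relabel


def _segment_tables(model: GeneModel, mixture: dict, gene_weights: dict | None):
    """Per mixture label: arrays of winner-partition segments with weights
    proportional to segment length (times any per-gene weight)."""
    index = build_element_index(model)
    gene_weights = gene_weights or {}
    tables = {}
    for label in mixture:
        segs = index.segments_by_label(label)
        if not segs:
            continue
        chroms = [c for c, _ in segs]
        starts = np.array([s.start for _, s in segs], dtype=np.int64)
        ends = np.array([s.end for _, s in segs], dtype=np.int64)
        w = (ends - starts).astype(float)
        w *= np.array([gene_weights.get(s.gene_id, 1.0) for _, s in segs])
        tables[label] = (chroms, starts, ends, w / w.sum())
    missing = set(mixture) - set(tables)
    if missing:
        logger.warning("element mixture: no segments for %s; renormalizing",
                       sorted(missing))
    return tables, index


def _draw_peaks(n: int, tables: dict, mixture: dict, widths: np.ndarray,
                chrom_sizes: dict, rng: np.random.Generator) -> list[GenomicInterval]:
    labels = sorted(lab for lab in mixture if lab in tables)
    probs = np.array([mixture[lab] for lab in labels], dtype=float)
    probs = probs / probs.sum()
    lab_idx = rng.choice(len(labels), size=n, p=probs)
    out: list[GenomicInterval] = []
    for li, lab in enumerate(labels):
        sel = np.where(lab_idx == li)[0]
        if sel.size == 0:
            continue
        chroms, starts, ends, w = tables[lab]
        seg = rng.choice(len(starts), size=sel.size, p=w)
        seg_len = ends[seg] - starts[seg]
        margin = np.minimum(_JITTER_MARGIN, (seg_len - 1) // 2)
        span = np.maximum(seg_len - 2 * margin, 1)
        mids = starts[seg] + margin + (rng.random(sel.size) * span).astype(np.int64)
        for k, si in enumerate(seg):
            wdt = int(widths[sel[k]])
            chrom = chroms[si]
            s = int(mids[k]) - wdt // 2
            s = max(0, min(s, chrom_sizes[chrom] - wdt))
            out.append(GenomicInterval(chrom, s, s + wdt))
    return out


def _jitter(peaks: list[GenomicInterval], sd: float, chrom_sizes: dict,
            rng: np.random.Generator) -> list[GenomicInterval]:
    shifts = np.rint(rng.normal(0.0, sd, len(peaks))).astype(int)
    shifts = np.clip(shifts, -_JITTER_MARGIN, _JITTER_MARGIN)
    out = []
    for iv, sh in zip(peaks, shifts):
        s = max(0, min(iv.start + int(sh), chrom_sizes[iv.chrom] - iv.length))
        out.append(GenomicInterval(iv.chrom, s, s + iv.length))
    return out


def _gene_space_gaps(model: GeneModel, blocked: PeakSet | None) -> list[tuple[str, int, int]]:
    """Free (chrom, start, end) gaps inside gene spans, minus ``blocked``."""
    from .regions import _merge_pairs

    blocked_by: dict[str, tuple] = {}
    if blocked is not None:
        tmp: dict[str, list] = {}
        for iv in blocked:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        blocked_by = {c: _merge_pairs(v) for c, v in tmp.items()}
    gaps = []
    for g in model:
        pieces = [(g.start, g.end)]
        for bs, be in blocked_by.get(g.chrom, ()):
            if be <= g.start or bs >= g.end:
                continue
            nxt = []
            for s, e in pieces:
                if be <= s or bs >= e:
                    nxt.append((s, e))
                else:
                    if s < bs:
                        nxt.append((s, bs))
                    if be < e:
                        nxt.append((be, e))
            pieces = nxt
        gaps.extend((g.chrom, s, e) for s, e in pieces if s < e)
    return gaps


def _background_reference(gaps, p_cov: float, block: int,
                          rng: np.random.Generator) -> tuple[list[GenomicInterval], float]:
    """Disjoint background blocks covering ~``p_cov`` of the gap space via a
    renewal process with exponential spacings."""
    if p_cov <= 0:
        return [], 0.0
    mean_gap = block * (1.0 - p_cov) / p_cov
    out = []
    covered = 0
    total = 0
    for chrom, s, e in gaps:
        total += e - s
        t = s + rng.exponential(mean_gap)
        while t + 1 < e:
            b_end = min(int(t) + block, e)
            if b_end - int(t) >= 1:
                out.append(GenomicInterval(chrom, int(t), b_end))
                covered += b_end - int(t)
            t = b_end + rng.exponential(mean_gap)
    return out, (covered / total if total else 0.0)


def make_peaks(
    model: GeneModel,
    spec: PeakSpec,
    seed: int,
    gene_weights: dict | None = None,
):
    """Generate peak sets per protocol/replicate plus the reference profile.

    Returns ``(replicates, merged, reference, realized)`` where
    ``replicates[protocol]`` is a list of per-replicate PeakSets,
    ``merged[protocol]`` the coalesced union of that protocol's replicates,
    ``reference`` the planted+background binding profile, and ``realized``
    a dict of realized planted quantities for the truth sidecar.
    """
    rng = _rng(seed, _SALT_PEAKS)
    tables, _index = _segment_tables(model, spec.element_mixture, gene_weights)
    if not tables:
        raise ValueError("make_peaks: no element segments available")
    sizes = model.chrom_sizes

    replicates: dict[str, list[PeakSet]] = {}
    merged: dict[str, PeakSet] = {}
    for protocol in spec.protocols:
        widths = draw_widths(spec.n_peaks, spec.frac_below_50, spec.width_sigma, rng)
        base = _draw_peaks(spec.n_peaks, tables, spec.element_mixture, widths, sizes, rng)
        reps = [PeakSet(base, label=f"{protocol}/rep1")]
        for r in range(2, spec.replicates + 1):
            keep = rng.random(len(base)) < spec.replicate_keep
            kept = [iv for iv, k in zip(base, keep) if k]
            kept = _jitter(kept, spec.jitter_sd, sizes, rng)
            n_fresh = len(base) - len(kept)
            fw = draw_widths(n_fresh, spec.frac_below_50, spec.width_sigma, rng)
            fresh = _draw_peaks(n_fresh, tables, spec.element_mixture, fw, sizes, rng)
            reps.append(PeakSet(kept + fresh, label=f"{protocol}/rep{r}"))
        replicates[protocol] = reps
        merged[protocol] = merge_replicates(reps, label=f"{protocol}/merged")

    # planted per-peak support on the support protocol's merged peaks
    support_set = merged[spec.support_protocol]
    supported_mask = rng.random(len(support_set)) < spec.p_support
    planted = [
        GenomicInterval(iv.chrom, iv.start, iv.end)
        for iv, m in zip(support_set, supported_mask)
        if m
    ]

    all_peaks = merge_replicates(list(merged.values()), label="all")
    if spec.background_mode == "non-peak":
        gaps = _gene_space_gaps(model, all_peaks)
    elif spec.background_mode == "independent":
        gaps = _gene_space_gaps(model, None)
    else:
        raise ValueError(f"unknown background_mode {spec.background_mode!r}")
    background, cov = _background_reference(gaps, spec.p_background,
                                            spec.background_block, rng)
    reference = PeakSet(planted + background, label="reference")

    p_s = float(supported_mask.mean()) if len(support_set) else 0.0
    analytic_or = math.nan
    if 0 < p_s < 1 and 0 < cov < 1:
        analytic_or = (p_s / (1 - p_s)) / (cov / (1 - cov))
    realized = {
        "n_peaks": {p: [len(r) for r in reps] for p, reps in replicates.items()},
        "n_merged": {p: len(m) for p, m in merged.items()},
        "planted_support_fraction": p_s,
        "background_coverage": cov,
        "analytic_support_or": analytic_or,
        "supported_peaks": [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in planted],
    }
    return replicates, merged, reference, realized


# ---------------------------------------------------------------------------
# variants


def analytic_variant_or(widths: np.ndarray, rate_in: float, rate_out: float) -> float:
    """Expected per-interval odds ratio for Poisson variant placement at
    per-base rates rate_in (inside peaks) / rate_out (outside), averaged
    over the realized width multiset."""
    w = np.asarray(widths, dtype=float)
    p_in = float(np.mean(1.0 - np.exp(-rate_in * w)))
    p_out = float(np.mean(1.0 - np.exp(-rate_out * w)))
    return (p_in / (1 - p_in)) / (p_out / (1 - p_out))


def rate_in_for_target_or(widths: np.ndarray, target_or: float,
                          rate_out: float) -> float:
    """Solve the in-peak rate whose analytic odds ratio hits ``target_or``."""

    def f(r):
        return analytic_variant_or(widths, r, rate_out) - target_or

    return float(brentq(f, 1e-9, 5.0, xtol=1e-12, rtol=1e-12))


def make_variants(
    model: GeneModel,
    peaks: PeakSet,
    rate_in: float,
    rate_out: float,
    seed: int,
    cohort: str = "other",
    salt: int = 0,
) -> VariantSet:
    """Poisson point placement: per-base rate ``rate_in`` inside the peak
    territory, ``rate_out`` elsewhere in gene space."""
    rng = _rng(seed, _SALT_VAR, salt)

    def sample(regions: list[tuple[str, int, int]], rate: float):
        lens = np.array([e - s for _, s, e in regions], dtype=np.int64)
        total = int(lens.sum())
        if total == 0 or rate <= 0:
            return []
        n = rng.poisson(total * rate)
        if n == 0:
            return []
        offs = np.sort(rng.integers(0, total, n))
        cum = np.concatenate([[0], np.cumsum(lens)])
        idx = np.searchsorted(cum, offs, "right") - 1
        return [
            (regions[i][0], regions[i][1] + int(o - cum[i])) for i, o in zip(idx, offs)
        ]

    peak_regions = [(iv.chrom, iv.start, iv.end) for iv in merge_replicates([peaks])]
    out_regions = _gene_space_gaps(model, peaks)
    positions = sample(peak_regions, rate_in) + sample(out_regions, rate_out)
    return VariantSet(positions, cohort=cohort)


# ---------------------------------------------------------------------------
# expression


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def make_gene_expression(model: GeneModel, spec: ExpressionSpec,
                         seed: int) -> tuple[ExpressionMatrix, pd.Series]:
    """Baseline log-normal gene TPM matrix plus the per-gene true means."""
    rng = _rng(seed, _SALT_EXPR)
    ids = model.gene_ids()
    means = pd.Series(
        np.exp(rng.normal(spec.log_tpm_mu, spec.log_tpm_sigma, len(ids))), index=ids
    )
    noise = _lognormal_noise(rng, spec.noise_cv, (len(ids), spec.n_samples))
    df = pd.DataFrame(
        means.to_numpy()[:, None] * noise,
        index=ids,
        columns=[f"S{i + 1}" for i in range(spec.n_samples)],
    )
    return ExpressionMatrix(df, feature_kind="gene"), means


def high_expression_lncRNAs(model: GeneModel, gene_means: pd.Series,
                            min_tpm: float = 0.0) -> set[str]:
    """lncRNA genes above the median mean-TPM of expressed lncRNAs (ties
    low), mirroring the analysis-side binning."""
    lnc = [g.gene_id for g in model if g.biotype == "lncRNA"
           and gene_means[g.gene_id] > min_tpm]
    if not lnc:
        return set()
    med = float(gene_means[lnc].median())
    return {gid for gid in lnc if gene_means[gid] > med}


def make_exon_expression(
    model: GeneModel,
    spec: ExpressionSpec,
    proximal_ids: set[str],
    seed: int,
) -> tuple[dict[str, ExpressionMatrix], ExpressionMatrix]:
    """KD matrices (one per knocked-out RBP, proximal exons scaled by the
    planted fold) and the shared non-targeting control matrix."""
    rng = _rng(seed, _SALT_KO)
    exons = model_exons(model)
    ids = list(exons)
    means = np.exp(rng.normal(spec.log_tpm_mu, spec.log_tpm_sigma, len(ids)))
    prox = np.array([eid in proximal_ids for eid in ids])

    ctrl_noise = _lognormal_noise(rng, spec.noise_cv, (len(ids), spec.ctrl_samples))
    ctrl = ExpressionMatrix(
        pd.DataFrame(means[:, None] * ctrl_noise, index=ids,
                     columns=[f"C{i + 1}" for i in range(spec.ctrl_samples)]),
        feature_kind="exon",
        feature_intervals=exons,
    )
    kds = {}
    for rbp in sorted(spec.ko_folds):
        fold = spec.ko_folds[rbp]
        n = spec.kd_samples.get(rbp, 2)
        scaled = means * np.where(prox, fold, 1.0)
        noise = _lognormal_noise(rng, spec.noise_cv, (len(ids), n))
        kds[rbp] = ExpressionMatrix(
            pd.DataFrame(scaled[:, None] * noise, index=ids,
                         columns=[f"K{i + 1}" for i in range(n)]),
            feature_kind="exon",
            feature_intervals=exons,
        )
    return kds, ctrl


# ---------------------------------------------------------------------------
# dataset orchestration


@dataclass
class SyntheticTruth:
    """Planted ground truth: seed + full config + realized quantities.

    Serializable to a JSON sidecar; :func:`make_dataset` applied to
    (config, seed) reconstructed from the sidecar reproduces the dataset
    bit-identically.
    """

    seed: int
    config: dict
    realized: dict

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], config=d["config"], realized=d["realized"])


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    model: GeneModel
    replicates: dict
    merged: dict
    reference: PeakSet
    variants: dict
    gene_expression: ExpressionMatrix | None
    kd_expression: dict
    ctrl_expression: ExpressionMatrix | None
    truth: SyntheticTruth

    def peaks_union(self, protocol: str) -> PeakSet:
        """Deduplicated union of a protocol's replicate peaks (widths and
        element labels as generated, before coalescing)."""
        ivs = [iv for rep in self.replicates[protocol] for iv in rep]
        return PeakSet(ivs, label=f"{protocol}/union")

    def write(self, outdir: str | os.PathLike) -> None:
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        (out / "variants").mkdir(exist_ok=True)
        (out / "expression").mkdir(exist_ok=True)
        write_gtf(self.model, out / "genome.gtf")
        write_chrom_sizes(self.model.chrom_sizes, out / "chrom.sizes")
        for protocol, reps in self.replicates.items():
            for i, rep in enumerate(reps, 1):
                write_bed(rep, out / "peaks" / f"{protocol}_rep{i}.bed")
            write_bed(self.merged[protocol], out / "peaks" / f"{protocol}_merged.bed")
        write_bed(self.reference, out / "reference.bed")
        for cohort, vs in self.variants.items():
            write_variants_vcf(vs, out / "variants" / f"{cohort}.vcf")
        if self.gene_expression is not None:
            write_expression(self.gene_expression, out / "expression" / "gene_tpm.tsv")
        for rbp, mat in self.kd_expression.items():
            write_expression(mat, out / "expression" / f"exon_{rbp}_kd.tsv")
        if self.ctrl_expression is not None:
            write_expression(self.ctrl_expression, out / "expression" / "exon_ctrl.tsv")
        self.truth.to_json(out / "truth.json")


def make_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete synthetic study: genome, expression, peaks,
    reference profile, variant cohorts and knockout matrices, with all
    planted parameters recorded in the truth sidecar."""
    if config is None:
        config = paper_like()
    realized: dict = {}

    model = make_genome(config.genome, seed)
    realized["biotype_counts"] = model.biotype_counts()

    gene_expr = None
    gene_weights: dict | None = None
    high_lnc: set[str] = set()
    if config.with_expression:
        gene_expr, gene_means = make_gene_expression(model, config.expression, seed)
        high_lnc = high_expression_lncRNAs(model, gene_means)
        mult = config.expression.density_multiplier
        if mult != 1.0 and high_lnc:
            gene_weights = {gid: mult for gid in high_lnc}
        realized["high_lncRNA_ids"] = sorted(high_lnc)

    replicates, merged, reference, peaks_realized = make_peaks(
        model, config.peaks, seed, gene_weights
    )
    realized.update(peaks_realized)

    variants: dict[str, VariantSet] = {}
    if config.with_variants:
        target_set = merged[config.peaks.support_protocol]
        widths = target_set.widths()
        realized["variant_rates"] = {}
        for si, cohort in enumerate(sorted(config.variants.cohort_targets)):
            target = config.variants.cohort_targets[cohort]
            rate_in = rate_in_for_target_or(widths, target, config.variants.rate_out)
            variants[cohort] = make_variants(
                model, target_set, rate_in, config.variants.rate_out, seed,
                cohort=cohort, salt=si,
            )
            realized["variant_rates"][cohort] = {
                "rate_in": rate_in,
                "rate_out": config.variants.rate_out,
                "analytic_or": analytic_variant_or(
                    widths, rate_in, config.variants.rate_out
                ),
            }

    kds: dict[str, ExpressionMatrix] = {}
    ctrl = None
    if config.with_expression:
        anchors = supported_peaks_for_rbp(
            merged[config.peaks.support_protocol], reference,
            OverlapRule(min_fraction=0.5, mode="query"),
        )
        prox = proximal_exons(anchors, model, config.expression.max_distance)
        realized["proximal_exon_ids"] = list(prox.exon_ids)
        kds, ctrl = make_exon_expression(model, config.expression,
                                         set(prox.exon_ids), seed)

    truth = SyntheticTruth(seed=seed, config=config.to_dict(), realized=realized)
    return SyntheticDataset(
        config=config,
        seed=seed,
        model=model,
        replicates=replicates,
        merged=merged,
        reference=reference,
        variants=variants,
        gene_expression=gene_expr,
        kd_expression=kds,
        ctrl_expression=ctrl,
        truth=truth,
    )


def regenerate(truth: SyntheticTruth) -> SyntheticDataset:
    """Rebuild the identical dataset from a truth sidecar."""
    return make_dataset(SimulationConfig.from_dict(truth.config), truth.seed)
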