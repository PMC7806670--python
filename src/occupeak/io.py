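"""Readers and writers for the interval, annotation, variant and expression
formats the pipeline consumes.

Everything is normalized to the package's internal 0-based half-open
convention at this boundary: BED is taken as-is, GTF (1-based closed) start
``s`` end ``e`` becomes ``[s-1, e)``, and a VCF POS ``p`` becomes the point
``p-1``.
"""
from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd

from .regions import (
    ExpressionMatrix,
    Gene,
    GeneModel,
    GenomicInterval,
    PeakSet,
    VariantSet,
)

logger = logging.getLogger("occupeak")

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "snoRNA": "snoRNA",
}


def _norm_biotype(raw: str) -> str:
    return _BIOTYPE_MAP.get(raw, "other")


def read_bed(path: str | os.PathLike, label: str = "") -> PeakSet:
    """Read a BED3/BED6 file into a sorted, deduplicated :class:`PeakSet`.

    Strand is read from column 6 when present, otherwise unstranded.
    Malformed lines raise with the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return PeakSet(intervals, label=label or str(path))


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> None:
    """Write a PeakSet as BED6.  ``read_bed(write_bed(P)) == P``."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def _gtf_attrs(feature) -> dict:
    return {k: v[0] if isinstance(v, list) else v for k, v in feature.attributes.items()}


def read_gene_model(path: str | os.PathLike) -> GeneModel:
    """Load a GTF gene model via gffutils.

    Gene spans come from ``gene`` rows when present, otherwise from the
    extent of each gene's exons.  Introns and UTRs are always derived, not
    read; unknown feature types are skipped with a logged count.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    known = {"gene", "exon", "CDS", "transcript"}
    skipped = 0
    spans: dict[str, tuple[str, int, int, str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        attrs = _gtf_attrs(feat)
        gid = attrs.get("gene_id")
        if feat.featuretype not in known:
            skipped += 1
            continue
        if gid is None:
            raise ValueError(f"{path}: {feat.featuretype} feature without gene_id")
        start, end = feat.start - 1, feat.end  # GTF 1-based closed -> half-open
        if feat.featuretype == "gene":
            biotype = _norm_biotype(attrs.get("gene_biotype", attrs.get("gene_type", "other")))
            spans[gid] = (feat.seqid, start, end, feat.strand or ".", biotype)
        elif feat.featuretype == "exon":
            exons.setdefault(gid, []).append((start, end))
        elif feat.featuretype == "CDS":
            cds.setdefault(gid, []).append((start, end))
    if skipped:
        logger.info("read_gene_model: skipped %d unknown feature rows", skipped)

    genes = []
    all_ids = sorted(set(spans) | set(exons))
    for gid in all_ids:
        ex = exons.get(gid, [])
        if gid in spans:
            chrom, start, end, strand, biotype = spans[gid]
            for s, e in ex:
                if s < start or e > end:
                    raise ValueError(
                        f"{path}: gene {gid}: exon [{s}, {e}) outside gene span [{start}, {end})"
                    )
        else:
            if not ex:
                continue
            chrom = strand = None  # inferred below from first exon feature
            start = min(s for s, _ in ex)
            end = max(e for _, e in ex)
            # re-scan for chrom/strand of this gene's exons
            for feat in db.features_of_type("exon"):
                if _gtf_attrs(feat).get("gene_id") == gid:
                    chrom, strand = feat.seqid, feat.strand or "."
                    break
            biotype = "other"
        genes.append(
            Gene(
                gene_id=gid,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand if strand in ("+", "-") else ".",
                biotype=biotype,
                exons=tuple(ex),
                cds=tuple(cds.get(gid, [])),
            )
        )
    return GeneModel(genes)


def write_gtf(model: GeneModel, path: str | os.PathLike, source: str = "occupeak") -> None:
    """Write a GeneModel as GTF 2.2 (1-based closed coordinates)."""

    def row(chrom, src, feat, start, end, strand, attrs):
        attr_s = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{src}\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}\n"

    with open(path, "w") as fh:
        for g in model:
            attrs = [("gene_id", g.gene_id), ("gene_biotype", g.biotype)]
            fh.write(row(g.chrom, source, "gene", g.start, g.end, g.strand, attrs))
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    row(g.chrom, source, "exon", s, e, g.strand,
                        attrs + [("exon_number", str(i))])
                )
            for s, e in g.cds:
                fh.write(row(g.chrom, source, "CDS", s, e, g.strand, attrs))


def read_variants(path: str | os.PathLike, cohort: str = "other") -> VariantSet:
    """Read variant positions from a VCF (positions only, genotypes ignored)
    or a BED-like >= 2 column TSV (0-based position in column 2).

    VCF POS is 1-based and converted to a 0-based point; multi-allelic rows
    collapse to one position; duplicates within the cohort are removed.
    """
    positions: list[tuple[str, int]] = []
    is_vcf = str(path).endswith((".vcf",)) or _sniff_vcf(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 tab-separated fields")
            try:
                raw = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric position") from exc
            pos = raw - 1 if is_vcf else raw
            if pos < 0:
                raise ValueError(f"{path}: line {lineno}: position out of range")
            positions.append((fields[0], pos))
    if not positions:
        logger.warning("read_variants: %s is empty", path)
    return VariantSet(positions, cohort=cohort)


def _sniff_vcf(path: str | os.PathLike) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def write_variants_vcf(variants: VariantSet, path: str | os.PathLike) -> None:
    """Write a minimal positions-only VCF 4.2 file (1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=occupeak cohort={variants.cohort}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in variants.all_positions():
            fh.write(f"{chrom}\t{pos + 1}\t.\tN\t.\t.\t.\t.\n")


def read_expression(
    path: str | os.PathLike,
    feature_kind: str = "gene",
    feature_intervals: Mapping[str, GenomicInterval] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column feature id, remaining
    columns samples, values TPM.  Negative values are an error; missing
    cells become 0 with a warning."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    return ExpressionMatrix(df, feature_kind=feature_kind, feature_intervals=feature_intervals)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = matrix.data.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column TSV (name, length)."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")
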