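"""Core genomic containers.

All coordinates in this package are 0-based half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` bases.  GTF and VCF
inputs are converted to this convention at the I/O boundary and never
mixed internally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("occupeak")

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; empty
    intervals are rejected so ``length`` is strictly positive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} (expected +, - or .)")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint position, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class OverlapRule:
    """How much of an interval a reference must cover for it to count as a hit.

    ``mode="query"`` requires >= ``min_fraction`` of the query interval's
    bases covered by a single reference interval (bedtools ``-f``);
    ``mode="reciprocal"`` additionally requires the same fraction of the
    reference interval (bedtools ``-f -r``).  Overlaps are strand-blind
    unless ``strand_aware`` is set.
    """

    min_fraction: float = 0.5
    mode: str = "query"
    strand_aware: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        if self.mode not in ("query", "reciprocal"):
            raise ValueError(f"mode must be 'query' or 'reciprocal', got {self.mode!r}")


class PeakSet:
    """An ordered, deduplicated collection of occupancy peaks.

    Intervals are kept sorted by (chrom, start, end); duplicate
    (chrom, start, end, strand) entries are dropped on construction, so a
    PeakSet holds unique peaks.  ``label`` carries provenance (protocol,
    replicate) and does not take part in equality.
    """

    __slots__ = ("_intervals", "label", "_by_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        seen: set[tuple] = set()
        uniq: list[GenomicInterval] = []
        ordered = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand, iv.name)
        )
        for iv in ordered:
            k = iv.key()
            if k not in seen:
                seen.add(k)
                uniq.append(iv)
        self._intervals: tuple[GenomicInterval, ...] = tuple(uniq)
        self.label = label
        self._by_chrom: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [iv.key() for iv in self] == [iv.key() for iv in other]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PeakSet(n={len(self)}, label={self.label!r})"

    def widths(self) -> np.ndarray:
        return np.array([iv.length for iv in self._intervals], dtype=np.int64)

    @property
    def total_bases(self) -> int:
        """Sum of interval lengths (overlapping intervals counted twice)."""
        return int(self.widths().sum()) if len(self) else 0

    def covered_bases(self) -> int:
        """Number of distinct genomic bases covered by the set."""
        total = 0
        cur_chrom, cur_s, cur_e = None, 0, 0
        for iv in self._intervals:
            if iv.chrom != cur_chrom or iv.start > cur_e:
                total += cur_e - cur_s
                cur_chrom, cur_s, cur_e = iv.chrom, iv.start, iv.end
            else:
                cur_e = max(cur_e, iv.end)
        total += cur_e - cur_s
        return total

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-chromosome arrays: starts, ends (sorted by start) and the
        index of each row in :attr:`intervals`."""
        if self._by_chrom is None:
            out: dict[str, dict[str, list]] = {}
            for i, iv in enumerate(self._intervals):
                d = out.setdefault(iv.chrom, {"starts": [], "ends": [], "index": []})
                d["starts"].append(iv.start)
                d["ends"].append(iv.end)
                d["index"].append(i)
            self._by_chrom = {
                c: {k: np.asarray(v, dtype=np.int64) for k, v in d.items()}
                for c, d in out.items()
            }
        return self._by_chrom

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "name": [iv.name for iv in self],
                "score": [iv.score for iv in self],
                "strand": [iv.strand for iv in self],
            }
        )


def _merge_pairs(pairs: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Coalesce overlapping or book-ended (s, e) pairs."""
    if not pairs:
        return ()
    pairs = sorted(pairs)
    out = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


@dataclass(frozen=True)
class Gene:
    """A gene with exon substructure and optional CDS.

    Exons are (start, end) pairs in gene coordinates on the genome;
    introns, 5'UTR and 3'UTR are derived, never stored.  The intron set
    is the gene span minus the exon union, so exons and introns always
    partition the span exactly.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "other"
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", tuple(sorted(tuple(p) for p in self.exons)))
        object.__setattr__(self, "cds", tuple(sorted(tuple(p) for p in self.cds)))
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene span "
                    f"[{self.start}, {self.end})"
                )
        for s, e in self.cds:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: CDS [{s}, {e}) outside gene span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    def merged_exons(self) -> tuple[tuple[int, int], ...]:
        return _merge_pairs(self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene span minus the exon union."""
        out = []
        cursor = self.start
        for s, e in self.merged_exons():
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return tuple(out)

    def _exonic_outside_cds(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        if not self.cds:
            return [], []
        cds_lo = min(s for s, _ in self.cds)
        cds_hi = max(e for _, e in self.cds)
        left, right = [], []
        for s, e in self.merged_exons():
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        return left, right

    def utr5(self) -> tuple[tuple[int, int], ...]:
        left, right = self._exonic_outside_cds()
        return tuple(left if self.strand != "-" else right)

    def utr3(self) -> tuple[tuple[int, int], ...]:
        left, right = self._exonic_outside_cds()
        return tuple(right if self.strand != "-" else left)

    def tss(self) -> int:
        """Transcription start position (0-based)."""
        return self.start if self.strand != "-" else self.end - 1

    def tts(self) -> int:
        return self.end - 1 if self.strand != "-" else self.start


class GeneModel:
    """A collection of genes with fast span lookup.

    ``chrom_sizes`` is optional; when absent it is inferred as the maximal
    gene end per chromosome (useful for simulated genomes where the true
    sizes are supplied explicitly).
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
        self._genes: tuple[Gene, ...] = tuple(ordered)
        self._by_id: dict[str, Gene] = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
        if chrom_sizes is None:
            sizes: dict[str, int] = {}
            for g in self._genes:
                sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
            self.chrom_sizes = sizes
        else:
            self.chrom_sizes = dict(chrom_sizes)
        self._spans: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def genes(self) -> tuple[Gene, ...]:
        return self._genes

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self) -> Iterator[Gene]:
        return iter(self._genes)

    def biotype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self._genes:
            out[g.biotype] = out.get(g.biotype, 0) + 1
        return out

    def _span_arrays(self) -> dict[str, dict[str, np.ndarray]]:
        if self._spans is None:
            tmp: dict[str, dict[str, list]] = {}
            for i, g in enumerate(self._genes):
                d = tmp.setdefault(g.chrom, {"starts": [], "ends": [], "index": []})
                d["starts"].append(g.start)
                d["ends"].append(g.end)
                d["index"].append(i)
            self._spans = {
                c: {k: np.asarray(v, dtype=np.int64) for k, v in d.items()}
                for c, d in tmp.items()
            }
        return self._spans

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span overlaps [start, end) by >= 1 bp."""
        arrs = self._span_arrays().get(chrom)
        if arrs is None:
            return []
        mask = (arrs["starts"] < end) & (arrs["ends"] > start)
        return [self._genes[i] for i in arrs["index"][mask]]

    def genes_containing(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span fully contains [start, end)."""
        arrs = self._span_arrays().get(chrom)
        if arrs is None:
            return []
        mask = (arrs["starts"] <= start) & (arrs["ends"] >= end)
        return [self._genes[i] for i in arrs["index"][mask]]

    @property
    def total_gene_bases(self) -> int:
        return sum(g.length for g in self._genes)


class VariantSet:
    """Single-base variant positions for one cohort.

    Positions are 0-based points; duplicates within the cohort are removed.
    """

    __slots__ = ("cohort", "_positions")

    KNOWN_COHORTS = ("GWAS", "PhenVar", "ClinVar", "SomaticVar", "other")

    def __init__(self, positions: Iterable[tuple[str, int]], cohort: str = "other") -> None:
        self.cohort = cohort
        tmp: dict[str, set[int]] = {}
        for chrom, pos in positions:
            if pos < 0:
                raise ValueError(f"negative variant position {pos} on {chrom}")
            tmp.setdefault(chrom, set()).add(int(pos))
        self._positions: dict[str, np.ndarray] = {
            c: np.array(sorted(s), dtype=np.int64) for c, s in sorted(tmp.items())
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self._positions.values())

    @property
    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        return self._positions

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self._positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def all_positions(self) -> Iterator[tuple[str, int]]:
        for chrom, pos in self._positions.items():
            for p in pos:
                yield chrom, int(p)


class ExpressionMatrix:
    """Feature x sample TPM matrix.

    Values are non-negative; missing cells are filled with 0 (with a logged
    warning).  ``feature_kind`` is "gene" or "exon"; for exon matrices,
    ``feature_intervals`` maps feature id -> :class:`GenomicInterval`.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        feature_kind: str = "gene",
        feature_intervals: Mapping[str, GenomicInterval] | None = None,
    ) -> None:
        if feature_kind not in ("gene", "exon"):
            raise ValueError(f"feature_kind must be 'gene' or 'exon', got {feature_kind!r}")
        values = values.copy()
        values.index = values.index.astype(str)
        if values.isna().any().any():
            n = int(values.isna().sum().sum())
            logger.warning("expression matrix: %d missing cells set to 0", n)
            values = values.fillna(0.0)
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValueError("expression matrix contains negative TPM values")
        self.data = values
        self.feature_kind = feature_kind
        self.feature_intervals = dict(feature_intervals) if feature_intervals else {}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def mean_tpm(self) -> pd.Series:
        """Per-feature mean TPM across samples."""
        return self.data.mean(axis=1)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids if f in self.data.index]
        return ExpressionMatrix(
            self.data.loc[ids],
            feature_kind=self.feature_kind,
            feature_intervals={k: v for k, v in self.feature_intervals.items() if k in ids},
        )
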