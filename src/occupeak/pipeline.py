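"""End-to-end analysis driver.

Runs the full downstream analysis in a fixed stage order — descriptive
statistics, element annotation, null-profile generation, enrichment,
knockout association, lncRNA density association — writing one TSV per
stage plus a JSON summary, a plain-text report and the fully serialized run
configuration, so a run is reproducible from config + inputs alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as oio
from .annotate import build_element_index, element_composition, gene_type_fractions
from .enrich import enrichment_vs_nulls
from .expression import (
    expression_density_test,
    ko_dysregulation,
    peak_density,
    proximal_exons,
    supported_peaks_for_rbp,
)
from .nullmodel import generate_null_profiles, null_profile_audit
from .overlaps import (
    binned_count_correlation,
    filter_supported,
    genes_with_peaks,
    length_histogram,
    merge_replicates,
    shared_gene_fraction,
)
from .regions import OverlapRule, PeakSet

logger = logging.getLogger("occupeak")

_FLOAT_FMT = "%.6g"


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed: the run seed salted with the stage name, so
    every stage is individually reproducible."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Inputs and parameters of one full analysis run."""

    peak_beds: dict  # protocol -> list of replicate BED paths
    gtf: str
    out_dir: str
    reference_bed: str | None = None
    chrom_sizes: str | None = None
    variant_files: dict = field(default_factory=dict)  # cohort -> path
    kd_expr: dict = field(default_factory=dict)  # RBP -> exon TSV path
    ctrl_expr: str | None = None
    gene_expr: str | None = None
    min_fraction: float = 0.5
    overlap_mode: str = "query"
    k: int = 5
    seed: int = 0
    max_distance: int = 1000
    tss_window: int = 1000
    tts_window: int = 1000
    lncrna_biotype: str = "lncRNA"
    support_protocol: str | None = None

    def rule(self) -> OverlapRule:
        return OverlapRule(min_fraction=self.min_fraction, mode=self.overlap_mode)

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("RunConfig: k must be >= 1")
        if not self.peak_beds:
            raise ValueError("RunConfig: no peak BED files given")
        missing = []
        for paths in self.peak_beds.values():
            missing += [p for p in paths if not Path(p).exists()]
        for p in [self.gtf, self.reference_bed, self.chrom_sizes,
                  self.ctrl_expr, self.gene_expr]:
            if p is not None and not Path(p).exists():
                missing.append(p)
        missing += [p for p in self.variant_files.values() if not Path(p).exists()]
        missing += [p for p in self.kd_expr.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {', '.join(map(str, missing))}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def from_sim_dir(sim_dir: str, out_dir: str, **kw) -> RunConfig:
    """Build a RunConfig from the file layout of a simulated dataset."""
    d = Path(sim_dir)
    protocols = sorted({p.name.split("_rep")[0] for p in (d / "peaks").glob("*_rep*.bed")})
    peak_beds = {
        prot: [str(p) for p in sorted((d / "peaks").glob(f"{prot}_rep*.bed"))]
        for prot in protocols
    }
    variant_files = {p.stem: str(p) for p in sorted((d / "variants").glob("*.vcf"))}
    kd_expr = {
        p.stem.removeprefix("exon_").removesuffix("_kd"): str(p)
        for p in sorted((d / "expression").glob("exon_*_kd.tsv"))
    }
    ctrl = d / "expression" / "exon_ctrl.tsv"
    gene = d / "expression" / "gene_tpm.tsv"
    ref = d / "reference.bed"
    sizes = d / "chrom.sizes"
    return RunConfig(
        peak_beds=peak_beds,
        gtf=str(d / "genome.gtf"),
        out_dir=out_dir,
        reference_bed=str(ref) if ref.exists() else None,
        chrom_sizes=str(sizes) if sizes.exists() else None,
        variant_files=variant_files,
        kd_expr=kd_expr,
        ctrl_expr=str(ctrl) if ctrl.exists() else None,
        gene_expr=str(gene) if gene.exists() else None,
        **kw,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_full_analysis(config: RunConfig) -> dict:
    """Run all stages; abort on the first failing stage with its name."""
    config.validate()  # fail fast before any computation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    summary: dict = {"seed": config.seed, "stages": []}
    report: list[str] = [f"occupeak full analysis (seed={config.seed})", ""]
    stage = "load"
    try:
        model = oio.read_gene_model(config.gtf)
        reps = {
            prot: [oio.read_bed(p, label=f"{prot}/rep{i + 1}")
                   for i, p in enumerate(paths)]
            for prot, paths in config.peak_beds.items()
        }
        merged = {prot: merge_replicates(r, label=f"{prot}/merged")
                  for prot, r in reps.items()}
        reference = (oio.read_bed(config.reference_bed, label="reference")
                     if config.reference_bed else None)
        sizes = (oio.read_chrom_sizes(config.chrom_sizes)
                 if config.chrom_sizes else model.chrom_sizes)
        rule = config.rule()

        stage = "descriptive"
        rows = []
        support_fractions = {}
        for prot in sorted(reps):
            union = PeakSet([iv for r in reps[prot] for iv in r], label=f"{prot}/union")
            hist = length_histogram(union)
            rows.append((prot, "n_replicate_peaks", len(union)))
            rows.append((prot, "n_merged_peaks", len(merged[prot])))
            rows.append((prot, "fraction_length_below_50bp",
                         hist.fraction_below(50)))
            if len(reps[prot]) >= 2:
                rho, rho2 = binned_count_correlation(reps[prot][0], reps[prot][1], sizes)
                rows.append((prot, "replicate_spearman_rho", rho))
                rows.append((prot, "replicate_spearman_rho_squared", rho2))
            if reference is not None:
                _, frac = filter_supported(merged[prot], reference, rule)
                support_fractions[prot] = frac
                rows.append((prot, "reference_support_fraction", frac))
        gene_sets = [genes_with_peaks(merged[p], model) for p in sorted(merged)]
        if len(gene_sets) >= 2:
            shared = shared_gene_fraction(gene_sets)
            rows.append(("all", "shared_gene_fraction", shared))
            summary["shared_gene_fraction"] = shared
        _write_tsv(pd.DataFrame(rows, columns=["protocol", "metric", "value"]),
                   out / "descriptive.tsv")
        summary["support_fractions"] = support_fractions
        summary["stages"].append(stage)
        report.append(f"[descriptive] support fractions: {support_fractions}")

        stage = "annotation"
        index = build_element_index(model, config.tss_window, config.tts_window)
        comp_rows = []
        for prot in sorted(merged):
            comp = element_composition(merged[prot], index)
            for label, value in comp.items():
                comp_rows.append((prot, label, value))
        _write_tsv(pd.DataFrame(comp_rows, columns=["protocol", "element", "proportion"]),
                   out / "annotation.tsv")
        gt_rows = []
        for prot in sorted(merged):
            for bt, frac in gene_type_fractions(merged[prot], model).items():
                gt_rows.append((prot, bt, frac))
        _write_tsv(pd.DataFrame(gt_rows, columns=["protocol", "biotype", "fraction"]),
                   out / "gene_types.tsv")
        summary["stages"].append(stage)

        stage = "null"
        nulls = {}
        audits = {}
        for prot in sorted(merged):
            ns = generate_null_profiles(
                merged[prot], model, k=config.k,
                seed=stage_seed(config.seed, f"null/{prot}"),
            )
            nulls[prot] = ns
            audits[prot] = null_profile_audit(ns, merged[prot], model).as_dict()
            if not audits[prot]["ok"]:
                raise RuntimeError(f"null audit failed for {prot}")
        with open(out / "null_audit.json", "w") as fh:
            json.dump(audits, fh, indent=1, sort_keys=True)
            fh.write("\n")
        summary["stages"].append(stage)
        report.append(f"[null] k={config.k} profiles per protocol, audits clean")

        stage = "enrichment"
        enr_rows = []
        mean_ors: dict[str, dict[str, float]] = {}
        refs: list[tuple[str, object]] = []
        if reference is not None:
            refs.append(("reference", reference))
        for cohort, path in sorted(config.variant_files.items()):
            refs.append((cohort, oio.read_variants(path, cohort=cohort)))
        for prot in sorted(merged):
            mean_ors[prot] = {}
            for name, ref in refs:
                res = enrichment_vs_nulls(merged[prot], nulls[prot], ref, rule)
                mean_ors[prot][name] = res.mean_odds_ratio
                for pe in res.profiles:
                    enr_rows.append(
                        (prot, name, pe.profile_index, *pe.table.as_tuple(),
                         pe.odds_ratio, pe.p_value, res.mean_odds_ratio)
                    )
        _write_tsv(
            pd.DataFrame(enr_rows, columns=["protocol", "reference", "profile",
                                            "a", "b", "c", "d", "odds_ratio",
                                            "p_value", "mean_odds_ratio"]),
            out / "enrichment.tsv",
        )
        summary["mean_odds_ratios"] = mean_ors
        summary["stages"].append(stage)
        report.append(f"[enrichment] mean odds ratios: {mean_ors}")

        stage = "crispr"
        if config.kd_expr and config.ctrl_expr and reference is not None:
            prot = config.support_protocol or sorted(merged)[0]
            anchors = supported_peaks_for_rbp(merged[prot], reference, rule)
            prox = proximal_exons(anchors, model, config.max_distance)
            ctrl = oio.read_expression(config.ctrl_expr, feature_kind="exon")
            ko_rows = []
            for rbp in sorted(config.kd_expr):
                kd = oio.read_expression(config.kd_expr[rbp], feature_kind="exon")
                res, _ = ko_dysregulation(kd, ctrl, prox)
                ko_rows.append((rbp, len(prox), res.u, res.p, res.direction, res.method))
                summary.setdefault("ko", {})[rbp] = {
                    "p": res.p, "direction": res.direction, "n_exons": len(prox)
                }
            _write_tsv(
                pd.DataFrame(ko_rows, columns=["rbp", "n_proximal_exons", "u",
                                               "p_value", "direction", "method"]),
                out / "crispr.tsv",
            )
            summary["stages"].append(stage)
            report.append(f"[crispr] {summary.get('ko')}")

        stage = "lncrna"
        if config.gene_expr:
            expr = oio.read_expression(config.gene_expr, feature_kind="gene")
            ln_rows = []
            for prot in sorted(merged):
                dens = peak_density(merged[prot], model)
                for biotype in (config.lncrna_biotype, "protein_coding"):
                    try:
                        res, bins = expression_density_test(dens, expr, model, biotype)
                    except ValueError as exc:
                        logger.warning("lncrna stage: %s/%s skipped: %s",
                                       prot, biotype, exc)
                        continue
                    ln_rows.append((prot, biotype, res.u, res.p, res.direction,
                                    res.method, res.n_x, res.n_y))
                    if biotype == config.lncrna_biotype:
                        summary.setdefault("lncrna", {})[prot] = {
                            "p": res.p, "direction": res.direction
                        }
            _write_tsv(
                pd.DataFrame(ln_rows, columns=["protocol", "biotype", "u", "p_value",
                                               "direction", "method",
                                               "n_high", "n_low"]),
                out / "lncrna.tsv",
            )
            summary["stages"].append(stage)
            report.append(f"[lncrna] {summary.get('lncrna')}")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write("\n".join(report) + "\n")
    return summary
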