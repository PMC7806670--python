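import filecmp
import json
from pathlib import Path

import numpy as np
import pytest

from occupeak import (
    GeneModel,
    SimulationConfig,
    build_element_index,
    element_composition,
    filter_supported,
    length_histogram,
    make_dataset,
    make_genome,
    paper_like,
    regenerate,
    small_test,
)
from occupeak.simulate import (
    GenomeSpec,
    PeakSpec,
    SyntheticTruth,
    analytic_variant_or,
    draw_widths,
    rate_in_for_target_or,
)


@pytest.fixture(scope="module")
def small_ds():
    return make_dataset(small_test(), seed=101)


class TestGenome:
    def test_model_invariants_hold(self, small_ds):
        model = small_ds.model
        assert len(model) == 40
        for g in model:
            assert g.exons
            assert g.start >= 0 and g.end <= model.chrom_sizes[g.chrom]
        # non-overlapping genes
        for chrom in model.chrom_sizes:
            spans = sorted((g.start, g.end) for g in model if g.chrom == chrom)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_same_seed_identical_model(self):
        spec = GenomeSpec(n_chroms=1, chrom_length=300_000, n_genes=20)
        m1, m2 = make_genome(spec, 7), make_genome(spec, 7)
        assert [(g.gene_id, g.start, g.end, g.exons, g.cds) for g in m1] == \
               [(g.gene_id, g.start, g.end, g.exons, g.cds) for g in m2]

    def test_biotype_mix_within_multinomial_bound(self):
        spec = GenomeSpec(n_chroms=10, chrom_length=1_200_000, n_genes=1000)
        model = make_genome(spec, 3)
        counts = model.biotype_counts()
        for bt, target in (("protein_coding", 0.6), ("lncRNA", 0.3), ("snoRNA", 0.1)):
            assert counts.get(bt, 0) / 1000 == pytest.approx(target, abs=0.05)

    def test_infeasible_packing_rejected(self):
        spec = GenomeSpec(n_chroms=1, chrom_length=20_000, n_genes=50)
        with pytest.raises(ValueError, match="cannot fit"):
            make_genome(spec, 0)


class TestWidths:
    def test_calibrated_fraction_below_50(self, rng):
        w = draw_widths(20_000, 0.85, 0.9, rng)
        assert (w < 50).mean() == pytest.approx(0.85, abs=0.02)

    def test_all_positive(self, rng):
        assert (draw_widths(5000, 0.85, 0.9, rng) >= 1).all()


class TestPeaks:
    def test_support_ceiling_and_floor(self):
        cfg = small_test()
        cfg.peaks.p_support = 1.0
        cfg.peaks.p_background = 0.0
        cfg.with_variants = False
        ds = make_dataset(cfg, seed=5)
        _, frac = filter_supported(ds.merged["NPOP"], ds.reference)
        assert frac == 1.0

        cfg.peaks.p_support = 0.0
        cfg.peaks.p_background = 0.05  # keep reference non-empty
        ds = make_dataset(cfg, seed=5)
        _, frac = filter_supported(ds.merged["NPOP"], ds.reference)
        assert frac == 0.0  # background avoids peak territory entirely

    def test_planted_support_probability_recovered(self):
        cfg = SimulationConfig(
            genome=GenomeSpec(n_chroms=3, chrom_length=700_000, n_genes=200),
            peaks=PeakSpec(protocols=("NPOP",), replicates=2, n_peaks=6000,
                           p_support=0.68),
            with_variants=False, with_expression=False,
        )
        ds = make_dataset(cfg, seed=9)
        _, frac = filter_supported(ds.merged["NPOP"], ds.reference)
        assert frac == pytest.approx(0.68, abs=0.02)
        assert frac == ds.truth.realized["planted_support_fraction"]

    def test_replicates_share_most_peaks(self, small_ds):
        r1, r2 = small_ds.replicates["NPOP"]
        from occupeak import max_overlap_fraction
        from occupeak.regions import OverlapRule

        frac = (max_overlap_fraction(r2, r1, OverlapRule(min_fraction=0.5)) >= 0.5).mean()
        assert frac > 0.6


class TestVariants:
    def test_rate_solver_hits_target(self, small_ds):
        widths = small_ds.merged["NPOP"].widths()
        rate_in = rate_in_for_target_or(widths, 20.0, 5e-4)
        assert analytic_variant_or(widths, rate_in, 5e-4) == pytest.approx(20.0, rel=1e-9)

    def test_zero_outside_rate_puts_all_variants_in_peaks(self):
        from occupeak.simulate import make_variants

        cfg = small_test()
        ds = make_dataset(cfg, seed=2)
        vs = make_variants(ds.model, ds.merged["NPOP"], 0.02, 0.0, seed=2)
        from occupeak import hit_indicator

        peaks = ds.merged["NPOP"]
        for chrom, positions in vs.positions_by_chrom.items():
            for pos in positions:
                assert any(
                    iv.start <= pos < iv.end for iv in peaks if iv.chrom == chrom
                )


class TestTruthSidecar:
    def test_regeneration_is_bit_identical(self, tmp_path, small_ds):
        small_ds.write(tmp_path / "a")
        truth = SyntheticTruth.from_json(tmp_path / "a" / "truth.json")
        regenerate(truth).write(tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes(), rel

    def test_written_files_pass_io_invariants(self, tmp_path, small_ds):
        from occupeak import read_bed, read_expression, read_gene_model, read_variants

        small_ds.write(tmp_path / "ds")
        d = tmp_path / "ds"
        model = read_gene_model(d / "genome.gtf")
        assert len(model) == len(small_ds.model)
        back = read_bed(d / "peaks" / "NPOP_rep1.bed")
        assert back == small_ds.replicates["NPOP"][0]
        vs = read_variants(d / "variants" / "GWAS.vcf", cohort="GWAS")
        assert sorted(vs.all_positions()) == sorted(small_ds.variants["GWAS"].all_positions())
        mat = read_expression(d / "expression" / "exon_ctrl.tsv", feature_kind="exon")
        assert len(mat) == len(small_ds.ctrl_expression.data)


class TestConfigRoundTrip:
    def test_to_from_dict(self):
        cfg = paper_like()
        back = SimulationConfig.from_dict(json.loads(json.dumps(cfg.to_dict())))
        assert back.to_dict() == cfg.to_dict()
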