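import numpy as np
import pandas as pd
import pytest

from occupeak import (
    ExpressionMatrix,
    GenomicInterval,
    PeakSet,
    expression_density_test,
    ko_dysregulation,
    peak_density,
    proximal_exons,
    supported_peaks_for_rbp,
)
from occupeak.expression import ProximalExonSet, exon_id, model_exons

from .conftest import random_peakset
from .oracles import brute_proximal_gap


class TestSupportedPeaks:
    def test_self_profile_retains_everything(self, rng):
        peaks = random_peakset(rng, 40)
        assert supported_peaks_for_rbp(peaks, peaks) == peaks

    def test_disjoint_profile_yields_empty(self):
        peaks = PeakSet([GenomicInterval("chr1", 0, 50)])
        profile = PeakSet([GenomicInterval("chr9", 0, 50)])
        assert len(supported_peaks_for_rbp(peaks, profile)) == 0


class TestProximalExons:
    def test_overlapping_exon_included(self, tiny_model):
        anchors = PeakSet([GenomicInterval("chr1", 1100, 1160)])  # inside geneA exon1
        prox = proximal_exons(anchors, tiny_model)
        assert exon_id("geneA", 1) in prox.exon_ids

    def test_exactly_1000bp_away_excluded(self, tiny_model):
        # geneA exon2 spans [3000,3500); anchor ending at 2000 leaves a gap of
        # exactly 1000 -> excluded by the strict < rule
        anchors = PeakSet([GenomicInterval("chr1", 1950, 2000)])
        prox = proximal_exons(anchors, tiny_model, max_distance=1000)
        assert exon_id("geneA", 2) not in prox.exon_ids
        anchors = PeakSet([GenomicInterval("chr1", 1951, 2001)])
        prox = proximal_exons(anchors, tiny_model, max_distance=1000)
        assert exon_id("geneA", 2) in prox.exon_ids

    def test_matches_brute_force_scan(self, tiny_model, rng):
        anchors = random_peakset(rng, 300, max_pos=25_000)
        prox = proximal_exons(anchors, tiny_model, max_distance=1000)
        for eid, exon in model_exons(tiny_model).items():
            gap = brute_proximal_gap(exon, anchors)
            assert (eid in prox.exon_ids) == (gap < 1000), eid


def _matrix(values: dict, n_samples: int, rng, cv=0.0) -> ExpressionMatrix:
    data = {}
    for eid, mean in values.items():
        noise = rng.lognormal(0, cv, n_samples) if cv else np.ones(n_samples)
        data[eid] = mean * noise
    return ExpressionMatrix(pd.DataFrame(data).T, feature_kind="exon")


class TestKoDysregulation:
    def _prox(self, ids):
        return ProximalExonSet(exon_ids=list(ids), intervals={}, anchors=PeakSet([]),
                               max_distance=1000)

    def test_identical_matrices_give_p_one(self, rng):
        values = {f"g.e{i}": float(i + 1) for i in range(20)}
        kd = _matrix(values, 3, rng)
        ctrl = _matrix(values, 4, rng)
        res, _ = ko_dysregulation(kd, ctrl, self._prox(values))
        assert res.p == pytest.approx(1.0, abs=0.05)
        assert res.direction == 0.0

    def test_planted_reduction_detected_with_negative_direction(self, rng):
        means = {f"g.e{i}": float(np.exp(rng.normal(1.5, 1.0))) for i in range(200)}
        ctrl = _matrix(means, 8, rng, cv=0.2)
        kd = _matrix({k: v * 0.5 for k, v in means.items()}, 6, rng, cv=0.2)
        res, summary = ko_dysregulation(kd, ctrl, self._prox(means))
        assert res.p < 0.01
        assert res.direction < 0

    def test_planted_increase_recovers_positive_direction(self, rng):
        means = {f"g.e{i}": float(np.exp(rng.normal(1.5, 1.0))) for i in range(200)}
        ctrl = _matrix(means, 8, rng, cv=0.2)
        kd = _matrix({k: v * 2.0 for k, v in means.items()}, 2, rng, cv=0.2)
        res, _ = ko_dysregulation(kd, ctrl, self._prox(means))
        assert res.p < 0.01
        assert res.direction > 0

    def test_too_few_shared_exons_rejected(self, rng):
        kd = _matrix({"g.e1": 1.0}, 2, rng)
        ctrl = _matrix({"g.e1": 1.0}, 2, rng)
        with pytest.raises(ValueError, match="proximal exons"):
            ko_dysregulation(kd, ctrl, self._prox(["g.e1"]))


class TestPeakDensity:
    def test_arithmetic(self, tiny_model):
        # geneA spans [1000,10000) = 9000 bp; 5 peaks inside
        peaks = PeakSet([GenomicInterval("chr1", 2000 + i * 500, 2000 + i * 500 + 50)
                         for i in range(5)])
        dens = peak_density(peaks, tiny_model)
        assert dens["geneA"] == pytest.approx(5 / 9000)
        assert dens["geneB"] == 0.0

    def test_peak_overlapping_two_genes_counts_for_each(self):
        from occupeak import Gene, GeneModel

        g1 = Gene("g1", "chr1", 0, 1000, "+", "other", exons=((0, 1000),))
        g2 = Gene("g2", "chr1", 900, 2000, "+", "other", exons=((900, 2000),))
        model = GeneModel([g1, g2])
        peaks = PeakSet([GenomicInterval("chr1", 890, 910)])
        dens = peak_density(peaks, model)
        assert dens["g1"] == pytest.approx(1 / 1000)
        assert dens["g2"] == pytest.approx(1 / 1100)

    def test_invariant_to_peak_order_and_chunking(self, tiny_model, rng):
        peaks = random_peakset(rng, 300, max_pos=25_000)
        full = peak_density(peaks, tiny_model)
        chunk_a = PeakSet(list(peaks)[:150])
        chunk_b = PeakSet(list(peaks)[150:])
        combined = peak_density(chunk_a, tiny_model) + peak_density(chunk_b, tiny_model)
        assert np.allclose(full.values, combined.values)


class TestExpressionDensityTest:
    def _setup(self, rng, multiplier: float, n_genes: int = 60):
        from occupeak import Gene, GeneModel

        genes = [
            Gene(f"L{i}", "chr1", i * 5000, i * 5000 + 4000, "+", "lncRNA",
                 exons=((i * 5000, i * 5000 + 4000),))
            for i in range(n_genes)
        ]
        model = GeneModel(genes)
        tpm = np.exp(rng.normal(1.0, 1.0, n_genes))
        order = np.argsort(tpm)
        high = {genes[i].gene_id for i in order[n_genes // 2:]}
        ivs = []
        for g in genes:
            lam = 3.0 * (multiplier if g.gene_id in high else 1.0)
            for _ in range(rng.poisson(lam)):
                s = int(rng.integers(g.start, g.end - 20))
                ivs.append(GenomicInterval("chr1", s, s + 20))
        peaks = PeakSet(ivs)
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": tpm, "s2": tpm}, index=[g.gene_id for g in genes])
        )
        return model, peaks, expr

    def test_planted_link_detected(self, rng):
        model, peaks, expr = self._setup(rng, multiplier=3.0, n_genes=100)
        dens = peak_density(peaks, model)
        res, bins = expression_density_test(dens, expr, model, "lncRNA")
        assert res.p < 0.01
        assert res.direction > 0
        assert np.median(bins.group_values("high")) > np.median(bins.group_values("low"))

    def test_small_sample_exact_path(self, rng):
        model, peaks, expr = self._setup(rng, multiplier=3.0, n_genes=4)
        dens = peak_density(peaks, model)
        res, _ = expression_density_test(dens, expr, model, "lncRNA")
        assert 0.0 < res.p <= 1.0

    def test_group_sizes_balanced(self, rng):
        model, peaks, expr = self._setup(rng, multiplier=1.0, n_genes=61)
        dens = peak_density(peaks, model)
        res, bins = expression_density_test(dens, expr, model, "lncRNA")
        assert abs(res.n_x - res.n_y) <= 1

    def test_degenerate_all_equal_tpm_rejected(self, tiny_model):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0] * 4},
                         index=["geneA", "geneB", "geneC", "geneD"])
        )
        dens = pd.Series(0.0, index=["geneA", "geneB", "geneC", "geneD"])
        with pytest.raises(ValueError):
            expression_density_test(dens, expr, tiny_model, "lncRNA")

    def test_too_few_genes_rejected(self, tiny_model):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["geneB"]))
        dens = pd.Series(0.0, index=["geneB"])
        with pytest.raises(ValueError, match=">= 4"):
            expression_density_test(dens, expr, tiny_model, "lncRNA")
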