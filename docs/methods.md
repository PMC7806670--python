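# Methods

This note documents the models, conventions and numerical choices behind
`occupeak`, and what the simulation-based tests do and do not establish.

## Coordinates and input handling

All internal coordinates are 0-based half-open (BED convention). GTF
(1-based closed) and VCF (1-based positions) are converted at the I/O
boundary: GTF `s..e` → `[s−1, e)`, VCF `POS p` → point `p−1`. One
convention everywhere removes the silent mixing of tool conventions that
plagues multi-tool occupancy pipelines. Duplicate intervals are dropped on
load (peak sets hold *unique* peaks); introns and UTRs are always derived
from exons and the CDS extent, never read from the annotation, so the
exon/intron partition of a gene span is exact by construction.

Strand is carried on every interval but all overlap operations are
strand-blind by default, with an opt-in `strand_aware` flag. bedtools-style
peak comparisons in this field are typically strand-blind, and occupancy
peak callers do not always emit strand; the flag preserves the stricter
behaviour where it is wanted.

## Overlap and support

The support rule "at least half the peak covered" is implemented as
query-mode fraction — a peak is supported when one reference interval
covers ≥ `min_fraction` (default 0.5) of *its* bases, which is what
`bedtools -f 0.5` computes. A reciprocal mode (both intervals ≥ the
fraction, `bedtools -f -r`) is exposed because the phrase "end-to-end
overlap" also admits the stricter reading; both are first-class and the
support-vs-threshold sweep works with either. Replicate merging coalesces
overlapping *and book-ended* intervals (bedtools-merge default) and is
idempotent.

Replicate reproducibility is measured as the Spearman correlation of
interval-midpoint counts per fixed 10-kb bin. This deliberately deviates
from read-level coverage correlation (deepTools-style): the package
consumes peaks, not alignments. Because the literature labels this number
"R²" ambiguously, both ρ and ρ² are returned.

## Element annotation

A winner partition of the genome is precomputed: candidate intervals
(±`tss_window` around the transcription start, ±`tts_window` around the
end, CDS, derived UTRs, non-coding exons, introns) are swept per
chromosome and every elementary segment is assigned the highest-priority
candidate, ties broken by gene id for determinism. A peak is annotated by
binary-searching its midpoint, `floor((start+end)/2)`. The priority ladder
promoter-TSS > TTS > 5UTR > exon > 3UTR > non-coding-exon > intron >
intergenic mimics midpoint-priority annotators (HOMER-style) and is
configurable. The window default of ±1000 bp is a package choice; the
"promoter/TTS" categories require *some* window and no canonical value
exists. Gene-type fractions use per-biotype denominators (genes of that
biotype hit / genes of that biotype annotated), so fractions across
biotypes need not sum to 1.

## The width-matched null

Each null profile preserves the real set's interval count and exact width
multiset, lies wholly within gene spans, and overlaps neither the
exclusion set (default: the real peaks) nor previously placed intervals of
the same profile. Placement processes widths in descending order (the
hardest intervals first): a gene is drawn with probability proportional to
its number of fitting start positions, a uniform start is drawn, and
collisions are rejected. After a bounded number of rejections (64) the
generator switches to exact enumeration of every remaining free placement
and samples uniformly among them, so generation fails only when no
placement exists at all — the rejection stage is purely an optimization and
the adversarially tight cases (single free slot among slivers) are solved
exactly. Profile *i* draws from the dedicated stream `(seed, i)`, making
the k profiles independent yet individually reproducible. Placement is not
restricted to the source peak's own gene: "within the gene boundary" is
read as within genic space generally. A precondition refuses generation
when free genic space is below twice the total peak bases, where rejection
geometry degrades. The audit operation re-verifies all three invariants
from scratch and is run inside the pipeline on every invocation.

Not modelled: GC- or mappability-matched placement, and circular
permutation. Nulls within one profile are mutually disjoint (real merged
peaks are too, which keeps the comparison symmetric).

## Exact tests

`fisher_exact` evaluates the hypergeometric likelihood of every table with
the observed margins via log-gamma, and sums those with probability ≤ the
observed one — the conventional minimum-likelihood two-sided test — with a
relative tolerance of 1e−7 on the comparison to absorb floating-point ties.
No normal approximation is used at any table size. The sample odds ratio
(a·d)/(b·c) is reported as ∞ when b·c = 0 with a·d > 0 and NaN for 0/0; the
profile-averaged odds ratio is the arithmetic mean of the *finite* ORs with
the infinite count reported alongside, because silently averaging
infinities would fabricate the headline number.

`rank_sum_test` computes Mann–Whitney U from midranks. With both samples ≤
12 and no ties, the exact U distribution is built by dynamic programming
(equivalent to full enumeration of the C(n₁+n₂, n₁) labelings) and the
two-sided p is min(1, 2·min(P(U≤u), P(U≥u))). Otherwise a normal
approximation with tie-corrected variance and a 0.5 continuity correction
is used. A pooled sample with zero variance returns p = 1 with a warning.

## Association analyses

Knockout dysregulation: anchors are the peaks with ≥ 50 % overlap with the
RBP's binding profile; proximal exons are those whose end-to-end gap to the
nearest anchor is strictly below 1000 bp (0 when overlapping),
strand-blind, within-chromosome. Each condition's per-exon expression is
the mean TPM across that condition's replicates *before* testing — the
replicate counts are unequal by design (knockout n = 6 or 2 vs control
n = 8 in the emulated study) and pooling raw replicates would weight
conditions unevenly. The "cumulative expression" comparison is the pooled
per-exon distribution (a distributional test), not a summed scalar, which
admits no test. The reported direction is median(KO) − median(control).

lncRNA density: density(g) = peaks overlapping the gene span by ≥ 1 bp,
divided by span length. Expressed genes (mean TPM > 0; the cutoff is a
parameter) are split at their median TPM with ties to the low group, and
the high/low density distributions are compared by rank-sum. The same test
runs on protein-coding genes as the contrast.

## The synthetic-data generator

The generator emulates the statistical structure of an occupancy study at
desk scale; its defaults are the study conditions all tests run under.

* **Genome** — 200 non-overlapping genes on 3 × 700 kb chromosomes,
  biotype mix 0.6 protein-coding / 0.3 lncRNA / 0.1 snoRNA. Coding genes:
  5–8 exons of 100–300 bp, introns 800–3000 bp, UTR lengths drawn in
  exonic bp (5′ 150–450, 3′ 400–800) so UTRs can cross introns and hence
  lie genomically outside the TSS/TTS windows, as real UTRs do. lncRNAs:
  2–4 exons of 200–500 bp; snoRNAs: one 80–200 bp exon.
* **Peak widths** — log-normal with σ = 0.9 and location
  μ = ln 49.5 − σ·Φ⁻¹(q) so that P(rounded width < 50 bp) equals the target
  q = 0.85 exactly (the closed-form solution of the CDF calibration),
  rounded to ≥ 1 bp.
* **Element mixture** — each peak's element is drawn from the target
  mixture (0.48 exon / 0.19 intron / 0.16 3′UTR / 0.05 5′UTR / 0.05
  promoter / 0.04 TTS / 0.03 non-coding-exon) and its midpoint placed
  uniformly inside a winner-partition segment of that label, weighted by
  segment length, keeping a 15-bp margin from segment borders so replicate
  jitter (σ = 5 bp, clipped at ±15) cannot relabel it. Placement through
  the package's own element index makes the planted mixture exactly what
  the composition operation measures.
* **Replicates** — 6000 peaks per replicate, 2 replicates, 3 protocols;
  replicate 2 keeps 90 % of replicate 1's peaks with jitter and redraws
  the rest.
* **Reference profile** — each merged peak of the support protocol is,
  with probability 0.68, covered by a planted reference interval equal to
  itself; background blocks of 300 bp are laid down by a renewal process
  with exponential spacings tuned to ~10 % coverage of non-peak genic
  space (or of all genic space in "independent" mode, used for null
  calibration with no planted support). Planted support probability and
  realized background coverage give an analytic odds ratio stored in the
  truth sidecar.
* **Variants** — Poisson placement at per-base rate `rate_in` inside peak
  territory and `rate_out` elsewhere in genic space. The per-interval hit
  probability is 1 − exp(−rate·w) averaged over the realized width
  multiset, so `rate_in` is solved by root-finding to hit a target
  analytic odds ratio exactly (targets: 22 for PhenVar/ClinVar/SomaticVar,
  1.45 for GWAS, `rate_out` = 5·10⁻⁴).
* **Expression** — log-normal gene and exon means (ln-mean 1.5, ln-σ 1.0)
  with multiplicative log-normal replicate noise (CV 0.2). The knockout
  effect multiplies proximal-exon means by the planted fold (0.5
  DGCR8-like with 6 replicates, 2.0 IGF2BP1-like with 2, against an 8
  replicate control). The lncRNA association is injected structurally:
  segments of lncRNAs above their median expression receive 3× placement
  weight, so density couples to expression through peak assignment, not by
  editing expression values.

Every dataset writes a `truth.json` sidecar (seed + full configuration +
realized planted quantities) from which regeneration is bit-identical; all
recovery tests read planted truth only from that sidecar. Determinism
comes from per-stage substreams `SeedSequence([seed, salt])` and canonical
(sorted) iteration orders everywhere randomness touches a dict.

## What the simulations do and do not show

Passing recovery and calibration tests shows the estimators and tests are
correctly implemented and calibrated *under the generator's assumptions*:
independent peaks, homogeneous background, no mappability or GC structure,
no overdispersion beyond log-normal noise, annotation-faithful gene
models. Real occupancy data violate several of these (clustered binding,
expression-coupled peak discovery, incomplete annotations), so the
simulation results validate the machinery, not any biological claim about
a particular dataset.

## Problem sizes and tolerances in the test suite

The suite runs at deliberately small scale: calibration uses 200 simulated
datasets of ~300 peaks over 40 genes (mean null odds ratio asserted within
[0.9, 1.1], rejection rate ≤ 10 % at α = 0.05); planted-recovery uses one
5000-peak dataset with 5 null profiles (odds-ratio targets 13.5 and 20
within ±20–25 %, the binomial/Poisson sampling tolerance at that size) and
100 seeds each for the knockout fold and density multiplier (≥ 95/100
correct-sign detections at p < 0.01); the Fisher implementation is checked
against an exact-rational enumeration oracle exhaustively for all tables
with N ≤ 14 and on random tables up to N = 200, plus a 2000-table
cross-check against an independent library implementation; the rank-sum
exact path is checked against full subset enumeration for all group sizes
≤ 8. Support fractions and mixture proportions on synthetic data are
always asserted within sampling tolerance (±0.02 at the sizes used), never
exactly.

## Known limitations

* Annotation is midpoint-based and transcript-model-free: no isoform
  awareness, no nearest-gene distances for intergenic peaks.
* The null model matches widths and genic placement only.
* Variant parsing is positions-only (alleles, genotypes and INFO are
  ignored by design).
* The per-variant (rather than per-peak) enrichment unit is available but
  secondary; margins then count variants, not intervals.
* Overlapping gene spans are handled, but a null interval is required to
  lie within a *single* gene span.
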