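# occupeak

Downstream analysis of transcriptome-wide protein–RNA occupancy peak sets.

Phase-separation and CLIP-style protocols produce, after peak calling,
hundreds of thousands of short genomic intervals ("peaks") marking
protein-occupied sites on RNA. `occupeak` is a library for everything that
happens *after* the peak caller: describing the peak universe, annotating
peaks to transcript elements, building the matched chance model, testing
enrichment against reference binding profiles and variant catalogs, and
relating occupancy to expression. It is written for computational
biologists analysing such data in Python, and ships a fully seeded
synthetic-data generator so that every stage can be verified end-to-end
without downloading anything.

## The statistics at the core

**Width-matched permutation null.** For a real peak set
\(P = \{p_1,\dots,p_n\}\), each null profile is a random interval set
\(Q\) with \(|Q| = n\) and the *identical multiset of widths*, placed
uniformly inside gene bodies, outside the territory of \(P\) and of the
other intervals of the same profile. By default \(k = 5\) profiles are
drawn, and an audit operation re-checks all three invariants exactly.

**Fisher's-exact enrichment.** For a reference feature set \(R\) (a binding
profile, or a variant catalog), a peak is a *hit* when a single reference
interval covers ≥ 50 % of its bases (`OverlapRule(min_fraction=0.5,
mode="query")`; reciprocal overlap available), or, for variants, when it
contains ≥ 1 variant position. Each null profile yields a 2×2 table

&nbsp;&nbsp;&nbsp;&nbsp;OR = (a·d) / (b·c),&nbsp;&nbsp; a,b = real hits/misses,&nbsp; c,d = null hits/misses,

with an exact two-sided (minimum-likelihood) p-value evaluated in log
space, and the headline number is the odds ratio averaged over the finite
per-profile ORs (infinite ORs are counted, never silently averaged).

**Rank-sum association tests.** The knockout readout compares the
expression of exons lying < 1000 bp from RBP-supported peaks between a
CRISPR knockout and its control; the lncRNA "sponge" readout compares
per-bp peak density between lncRNAs above and below their median TPM. Both
use a self-contained Wilcoxon/Mann–Whitney test: exact enumeration of the
U distribution for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise.

**Element annotation.** Peaks are assigned a single label at their midpoint
with the fixed priority promoter-TSS > TTS > 5′UTR > exon(CDS) > 3′UTR >
non-coding-exon > intron > intergenic (±1000 bp TSS/TTS windows by
default), mirroring the behaviour of the standard peak annotators.

## Worked example

```
$ python examples/03_null_and_enrichment.py
null audit: widths ok=True, exclusion violations=0, out of gene=0

reference enrichment: mean OR=25.78 across 5 profiles, min p=4.26e-67
ClinVar      mean OR= 20.55  min p=3.47e-26
GWAS         mean OR=  1.47  min p=0.474
PhenVar      mean OR= 23.17  min p=8.26e-25
SomaticVar   mean OR= 26.25  min p=3.44e-23
```

The audit line confirms the chance model is sound (exact width match, zero
contamination by real peaks, all intervals genic). The reference odds ratio
of ~26 says real peaks overlap the reference binding profile far beyond
what identically shaped random genic intervals achieve; the variant rows
show the same test against planted variant cohorts, whose generator targets
(odds ratio 22 for the clinical/somatic cohorts, 1.45 for GWAS) are
recovered within sampling noise. The other example scripts
(`examples/01…04`) walk through descriptive statistics, annotation and
support, and the two expression associations, each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library:

```
occu simulate --preset small --seed 17 --out-dir sim/
occu run-all --sim-dir sim/ --out-dir results/ -k 5 --seed 17
occu support --query sim/peaks/NPOP_merged.bed --ref sim/reference.bed --min-frac 0.5
```

`run-all` executes every stage in a fixed order (descriptive → annotation →
null → enrichment → knockout association → lncRNA association), writes one
TSV per stage plus `summary.json` and `report.txt`, and is byte-for-byte
reproducible from its `config.json` and inputs.

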