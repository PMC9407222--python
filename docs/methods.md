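# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the numerical conventions used throughout.

## Coordinates and genotype semantics

VCF and GFF3 are 1-based inclusive on disk; every in-memory window, ROH
segment and BED output is 0-based half-open. A site at VCF position *p*
belongs to window [s, e) iff s ≤ p−1 < e. Multiallelic records are kept
unsplit; a genotype is heterozygous iff its two allele indices differ,
whatever the alleles — the statistics here are per-genotype, not
per-allele. A missing genotype (`./.`) is a first-class state: it never
counts as heterozygous, is excluded from load denominators, and (when a
callability mask is supplied) is subtracted from window denominators.
Impact categories, deleterious flags, gene ids and ancestral alleles are
consumed from configurable INFO keys (`IMPACT`, `DEL`, `GENE`, `AA`);
the package never predicts variant consequences itself.

## Heterozygosity

Defaults: 100-kb windows, 10-kb step, so an interior site is covered by
exactly 10 windows. The window denominator is the raw window length by
default; whether real analyses should normalize by callable sites depends
on the callability model of the upstream pipeline, so a BED mask mode is
provided that uses `|mask ∩ window| − n_missing` instead. With
non-overlapping tiling the window counts conserve the genome-wide
heterozygote total exactly, and the per-site rate equals the
callable-length-weighted mean of the window rates; both identities are
tested. Chromosomes can be excluded from "autosomal" summaries via the
run config (e.g. the X).

## Runs of homozygosity

The caller re-implements the PLINK `--homozyg` scheme rather than calling
PLINK, so the algorithm is testable against an exhaustive enumeration.
Defaults mirror common PLINK practice: scanning window of 50 consecutive
sites, a window is a hit with ≤1 heterozygous and ≤5 missing genotypes,
a site qualifies when ≥5% of its covering windows are hits, and maximal
runs of qualifying sites are emitted when they contain ≥100 SNPs, span
≥100 kb and have no inter-site gap >1 Mb. Two deliberate conventions:

* **Segment bounds are site-defined** (first/last SNP of the run), never
  window-defined — this matches PLINK semantics and makes the brute-force
  oracle unambiguous.
* **Length classes are half-open on the left**: short [0.1, 1) Mb, medium
  [1, 10) Mb, long ≥10 Mb, so a segment of exactly 1 Mb (10 Mb) is medium
  (long). Segments under 0.1 Mb are discarded and tallied.

Raising the hit threshold can only remove qualifying sites, so total ROH
length is monotone non-increasing in it (property-tested). A chromosome
with fewer sites than the scanning window is skipped with a warning, not
an error — that situation is routine on small scaffolds.

## Private-allele scan

For each gene the longest isoform is kept and its two flank windows
([start−f, start) and [end, end+f), default f = 1 kb) are clipped to
chromosome bounds; a fully clipped window is dropped and the gene is then
reported with zero counts and p = 1. Because the windows sit strictly
outside the transcript body they cannot overlap each other; a defensive
interval merge still runs in case degenerate inputs produce overlap.

A site is *private* to a focal species when ≥1 focal sample carries an
eligible allele that no sample of any other species (with a called
genotype) carries. Eligibility is polarity-aware: where an ancestral
allele is annotated, only derived alleles qualify (the reference allele
itself can be private if it is derived); elsewhere any non-reference
allele qualifies. Sites where every non-focal genotype is missing are
never private — absence of evidence is not evidence of absence.

"Variable within a species" means ≥1 sample of that species is
heterozygous or carries a non-reference allele; the cross-species
baseline is the mean of this count over the non-focal species. This
within-species reading was chosen over counting cross-species differences
because the baseline is meant to measure mutational/callability activity
of a window inside each lineage, not divergence between lineages. The
per-gene enrichment statistic is `n_private / max(mean_variable_other,
pseudocount)` with pseudocount 1 — the two quantities are only combined
for ranking/plotting, and the pseudocount prevents division by zero
without reordering genes with nonzero baselines.

**Null models.** The default P value is a one-sided exact binomial tail:
under a homogeneous placement of the focal species' private alleles, the
count in a gene's flanks is Binomial(L_flank, r̂) with r̂ the observed
genome-wide private rate. The alternative permutation null re-draws
flank-sized windows uniformly from the genome (window chosen with
probability proportional to the number of valid placements per
chromosome) and assigns `p = (1 + #{perm ≥ x}) / (n_perm + 1)`; one shared
null distribution is computed per distinct flank length, and a gene's two
flanks are approximated by a single window of their total length — under
a homogeneous null the split is immaterial. Defaults: 10,000 seeded
permutations. No multiple-testing correction is applied by default (the
reported threshold is a raw P < 0.01); Benjamini–Hochberg is a flag.

Exact one-sided tests on discrete counts are conservative and their
p-values cannot be marginally uniform. Calibration is therefore checked
with the standard probability-integral-transform device: the
`binomial_mode="randomized"` option returns `P(X > x) + U·P(X = x)`,
which is exactly Uniform(0,1) under the null, and the KS uniformity check
runs on those; significance calls always use the exact (conservative)
tail. A mid-p mode is also available. `alpha ≥ 1` disables the filter
entirely (exact tests report p = 1.0 for empty genes, which a strict
inequality would otherwise exclude).

An optional user-supplied BED of conserved intervals can restrict the
scanned windows; no conservation model is built in.

## High-impact variants and damaging load

`unique_high_impact` intersects the HIGH-impact annotation with the
private predicate above and reports both the variant list and the
deduplicated gene set (the two tallies differ and both are of interest).
`damaging_load` counts genotypes homozygous for a non-ancestral allele at
deleterious-flagged sites, with derived heterozygotes tallied separately;
sites lacking an ancestral allele are excluded and counted, never
guessed — the reference genome is an ingroup, so "reference = ancestral"
would systematically mispolarize.

## Synthetic-data generator

Sites are simulated independently — no linkage, recombination map,
mutation spectrum or demography. This is sufficient because none of the
implemented statistics model LD; it keeps every truth count exact and the
Poisson/binomial oracles closed-form. Consequences: simulated panels
cannot test LD-aware methods, ROH length distributions are implanted
rather than emergent from pedigree IBD, and site-frequency spectra are
unrealistic. Passing recovery tests therefore demonstrates correctness of
the *scan algorithms*, not robustness to real-data artifacts
(callability holes, allele-balance bias, misannotation).

Per species with rate *h*, Poisson(h·L) sites are placed uniformly; the
species' samples are 0/1 there and all other samples 1/1. This
"divergent homozygous-alt background" guarantees background polymorphism
is never private to any species (the alternate allele is shared
everywhere, and the reference allele is not eligible without an ancestral
annotation), so the private-site set is exactly the injected-singleton
set. Expected per-sample heterozygosity is exactly *h* outside implanted
tracts. Inside a planned tract the carrier's genotype is forced
homozygous, so tract boundaries are known to the site. Private alleles
are injected as derived singletons (ancestral = reference recorded in
`AA`): one random sample of the species carries the allele, homozygous
with probability 0.5, scaled by the per-sample `hom_damaging_bias`
multiplier when the allele is flagged deleterious (probability
`damaging_fraction`). Enrichment multiplies the private rate inside the
1-kb flanks of target genes for focal species; a `target_flank_rate`
override supports the zero-background, flank-only regime. Position
collisions between processes are resolved by keeping the first-drawn
site; at the configured rates this loses a vanishing fraction of sites
and the truth file recounts everything from the final genotypes anyway.

The simulated transcriptome places single-transcript genes uniformly with
≥2-kb gaps and ≥1-kb clearance from chromosome ends, so every flank
window is full-length and disjoint across genes.

All randomness flows from one `numpy` Generator seeded by the config;
identical seed + config yields byte-identical VCF, GFF3, TSV and truth
files (the VCF writer is a deterministic text emitter for this reason).

## Problem sizes used in tests and the acceptance script

Chosen so the whole suite runs in well under a minute of compute per
block while keeping every statistical check comfortably powered:
heterozygosity recovery on a 10-Mb genome at 3×10⁻⁴/10⁻³/2×10⁻³ per bp
(99% Poisson intervals); ROH recovery with 30 implanted tracts of
0.3/3/30 Mb across 10 inbred samples (plus 10 clean samples) on a 50-Mb
chromosome; null calibration with 2,000 genes at a 0.01/bp private rate
(≈20 expected sites per 2-kb flank pair); power at 10× enrichment on 20
of 500 genes, with recall/false-positive thresholds frozen from a
Monte-Carlo oracle (`tests/oracles/power_oracle.py`) run against the
closed-form site process; load bias over 10 replicate seeds with a 2×
homozygosity bias on one of four conspecifics.

## Known limitations

* The permutation null conditions on the observed private-site positions,
  not on regional mutation-rate or callability covariates; rate
  heterogeneity in real data will inflate both nulls similarly.
* `mean_variable_other` uses the within-species reading (see above);
  users wanting cross-species divergence counts must compute them
  separately.
* The ROH caller has no likelihood model; very short or SNP-sparse
  autozygous segments below the scanning-window resolution are invisible.
* Genome fractions use the full chromosome lengths, not callable lengths.
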