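# comparascan

Comparative genome scans for multi-species diploid panels — the analysis
layer a population geneticist needs after genotypes have been called and
annotated: genome-wide diversity, inbreeding signatures, lineage-specific
regulatory variation, and deleterious-variant load, all driven from a
multi-sample VCF, a species panel, a chromosome-length table and a
transcript annotation.

The package was built for comparative studies of closely related wild
species (its test regimes mirror wild canid panels: per-site
heterozygosity spanning ~0.3–2 het/kb, recently inbred individuals with
multi-megabase autozygous tracts, and focal lineages screened for private
regulatory alleles), but nothing in it is taxon-specific.

## What it computes

**Windowed and per-site heterozygosity.** For sample *i*, windows of size
*w* sliding by step *s* (defaults 100 kb / 10 kb) count genotypes with two
distinct allele indices; the rate is `n_het / callable length` reported per
kb. Missing genotypes never count as heterozygous; an optional BED
callability mask shrinks the denominator. Per-site heterozygosity is the
genome-wide analogue over a callable length *L*.

**Runs of homozygosity (ROH).** A PLINK-style `--homozyg` re-implementation:
a scanning window of 50 consecutive sites is a *hit* when it has ≤1
heterozygous and ≤5 missing genotypes; a site qualifies when ≥5% of the
windows covering it are hits; maximal runs of qualifying sites with ≥100
SNPs, span ≥100 kb and inter-site gaps ≤1 Mb become segments (all
parameters configurable). Segments are classified short [0.1, 1) Mb,
medium [1, 10) Mb, long ≥10 Mb, and summarized as counts, summed lengths,
genome fractions and the inbreeding coefficient
`F_ROH = total ROH length / genome length`.

**Private-allele enrichment in regulatory flanks.** For each gene's longest
isoform, the two 1-kb windows flanking the transcript start and end are a
proxy for proximal regulatory sequence. Within them the scan counts sites
carrying alleles private to a focal species (derived alleles when the
ancestral state is annotated) and the mean number of within-species
variable sites across the remaining species. Each gene gets a one-sided
P value for private-allele excess: with the default binomial null,

    x ~ Binomial(L_flank, r̂),   p = P(X ≥ x),

where `r̂` is the genome-wide focal private-allele rate; an empirical
permutation null (flank-sized windows re-drawn uniformly from the genome)
is available. Genes with `p < α` (default 0.01, raw) are reported, and a
gene set can be compared across species by its proportion of private
alleles among all variable sites in the set's windows.

**Unique high-impact variants and damaging load.** Variants annotated
HIGH impact (consumed from an INFO key, e.g. a VEP run upstream) and
private to the focal lineage are grouped by gene; per-sample genetic load
is the count of genotypes homozygous for a non-ancestral allele at sites
flagged deleterious. The reference allele is never assumed ancestral.

**Synthetic panels with known truth.** `comparascan simulate` generates
multi-species VCF/GFF3 panels with configured heterozygosity rates,
implanted autozygous tracts, private derived singletons (optionally
enriched near target genes), impact annotations and a damaging fraction —
plus a truth JSON recounted from the emitted genotypes, so every scan
above has an exact recovery test.

## Worked example

Simulate a three-species demo panel (a low-diversity focal lineage with
private-allele enrichment at 10 target genes, an inbred individual with a
3-Mb implanted tract, and a high-diversity outgroup), then run every stage:

```sh
comparascan simulate --config examples/simulate_demo.yaml --out demo_data
comparascan run-all  --config examples/run_demo.yaml      --out demo_out
```

`demo_out/summary.json` (seed 11) contains, among other things:

```
"per_site_het_per_kb": { "bush_dog_1": 0.524, "maned_wolf_2": 0.991,
                         "crab_eating_fox_1": 2.011, ... }
"roh": { "maned_wolf_1": { "per_class": { "medium":
         { "n_segments": 1, "summed_length": 3003665 } }, "froh": 0.3755 } }
"scan": { "bush_dog": { "significant_genes": ["gene00001", "gene00002",
          "gene00003", "gene00005", ..., "gene00059"] } }
"load": { "bush_dog_1": { "hom_derived": 222, "het_derived": 0 }, ... }
"high_impact": { "bush_dog": { "n_genes": 9, "n_variants": 98 } }
```

Reading these numbers: the recovered per-site heterozygosity matches each
species' configured rate (0.5 / 1.0 / 2.0 het/kb); the implanted 3-Mb
tract in `maned_wolf_1` is called as a single medium ROH within ~4 kb of
its true boundaries (F_ROH ≈ 0.375 of this 8-Mb toy genome); 9 of the 10
enrichment-target genes (plus one borderline background gene) pass the
P < 0.01 scan; and the sample simulated with a doubled
homozygous-damaging bias carries roughly twice the homozygous derived
damaging load of its conspecific (222 vs 116).

Every stage is also available as a standalone subcommand
(`het-windows`, `roh`, `scan-private`, `load`, `high-impact`) writing
TSV/BED/bedGraph tracks with a commented header naming version and seed.

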