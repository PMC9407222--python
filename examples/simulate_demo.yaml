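# Demo synthetic panel: three species in the regimes seen in wild canid
# panels (low / moderate / high diversity), one inbred sample with an
# implanted 3-Mb autozygous tract, and private-allele enrichment around
# 10 target genes for the focal lineage.
seed: 11
chromosomes:
  - {name: chr1, length: 5000000}
  - {name: chr2, length: 3000000}
species:
  - {id: bush_dog, n_samples: 2, het_rate: 0.0005}
  - {id: maned_wolf, n_samples: 2, het_rate: 0.001}
  - {id: crab_eating_fox, n_samples: 2, het_rate: 0.002}
focal: [bush_dog]
transcriptome: {n_genes: 200, min_length: 1000, max_length: 3000}
target_genes: 10
enrichment_factor: 10.0
private_background_rate: 0.0002
damaging_fraction: 0.3
hom_damaging_bias: {bush_dog_1: 2.0}
roh_plan:
  - {sample: maned_wolf_1, chrom: chr1, start: 1000000, end: 4000000}
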