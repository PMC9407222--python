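# Runs every stage on the demo panel produced by:
#   comparascan simulate --config examples/simulate_demo.yaml --out demo_data
seed: 11
vcf: ../demo_data/panel.vcf
gff: ../demo_data/transcripts.gff3
panel: ../demo_data/panel.tsv
layout: ../demo_data/chroms.tsv
focal: [bush_dog]
window_size: 100000
window_step: 10000
flank: 1000
alpha: 0.01
null: binomial
excluded_chromosomes: []
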