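# Desk-scale end-to-end experiment for `herdimpute run --config ...`.
# Omitted keys fall back to package defaults; this file spells out the
# main ones so they are easy to tweak.
sim:
  n_markers: 2500
  n_chromosomes: 2
  n_founders_per_breed: 30
  mosaic_switch_rate: 0.0005
  genotype_error_rate: 0.002
  seed: 0
hmm:
  switch_rate: 0.01
  emission_error: 0.002
  max_reference_haplotypes: 2000
strategies: [one-round-CR, two-round-CR, one-round-BR]
breed_reference: GEL
start_assay: SNP50
seed: 1
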