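name: negautoreg_delay
species:
  - {name: mRNA}
  - {name: protein}
  - {name: dimer}
reactions:
  # translation releases its product 1000 s after initiation; the mRNA
  # template is catalytic and is never consumed
  - name: translation
    modifiers: {mRNA: 1}
    products: {protein: 1}
    rate: 1.0
    rate_units: per_mRNA_per_second
    delay: 1000.0
  - name: mrna_decay
    reactants: {mRNA: 1}
    rate: 2.0
    rate_units: per_second
  - name: protein_decay
    reactants: {protein: 1}
    rate: 0.01
    rate_units: per_second
  - name: dimerization
    reactants: {protein: 2}
    products: {dimer: 1}
    rate: 1.0
    rate_units: per_uM_per_second
  - name: dimer_dissociation
    reactants: {dimer: 1}
    products: {protein: 2}
    rate: 1.0
    rate_units: per_second
genes:
  - name: gene
    position: 0.05
    transcription_rate: 1.0
    mrna: mRNA
    initial_copies: 2
    promoter:
      sites:
        - {tf: dimer, k_on: 100.0, k_off: 0.1, bound_factor: 0.1}
config:
  T: 200
  C: 40
  D: 20
  t_end: 24000
  seed: 1
  grid_dt: 1.0
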