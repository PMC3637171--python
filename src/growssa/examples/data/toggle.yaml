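name: toggle
# Mutual repression between two symmetric genes.  Rates follow the
# autoregulation parameter set symmetrized across the pair (the toggle's own
# rates are not fixed by the source system); the dimer production and
# dissociation rates are slowed to 0.01 (equilibrium unchanged) to keep the
# dimer exchange from dominating the event budget.  Non-reference values are
# flagged here on purpose.
species:
  - {name: mRNA_A}
  - {name: protein_A}
  - {name: dimer_A}
  - {name: mRNA_B}
  - {name: protein_B}
  - {name: dimer_B}
reactions:
  - name: translation_A
    modifiers: {mRNA_A: 1}
    products: {protein_A: 1}
    rate: 1.0
    rate_units: per_mRNA_per_second
  - name: translation_B
    modifiers: {mRNA_B: 1}
    products: {protein_B: 1}
    rate: 1.0
    rate_units: per_mRNA_per_second
  - name: mrna_decay_A
    reactants: {mRNA_A: 1}
    rate: 2.0
    rate_units: per_second
  - name: mrna_decay_B
    reactants: {mRNA_B: 1}
    rate: 2.0
    rate_units: per_second
  - name: protein_decay_A
    reactants: {protein_A: 1}
    rate: 0.01
    rate_units: per_second
  - name: protein_decay_B
    reactants: {protein_B: 1}
    rate: 0.01
    rate_units: per_second
  - name: dimerization_A
    reactants: {protein_A: 2}
    products: {dimer_A: 1}
    rate: 0.01
    rate_units: per_uM_per_second
  - name: dimerization_B
    reactants: {protein_B: 2}
    products: {dimer_B: 1}
    rate: 0.01
    rate_units: per_uM_per_second
  - name: dimer_dissociation_A
    reactants: {dimer_A: 1}
    products: {protein_A: 2}
    rate: 0.01
    rate_units: per_second
  - name: dimer_dissociation_B
    reactants: {dimer_B: 1}
    products: {protein_B: 2}
    rate: 0.01
    rate_units: per_second
genes:
  # gene A is repressed by the dimer of protein B and vice versa; equal
  # binding abilities on both sides
  - name: gene_A
    position: 0.5
    transcription_rate: 1.0
    mrna: mRNA_A
    promoter:
      sites:
        - {tf: dimer_B, k_on: 100.0, k_off: 0.1, bound_factor: 0.1}
  - name: gene_B
    position: 0.5
    transcription_rate: 1.0
    mrna: mRNA_B
    promoter:
      sites:
        - {tf: dimer_A, k_on: 100.0, k_off: 0.1, bound_factor: 0.1}
config:
  T: 50
  C: 40
  D: 20
  t_end: 11000
  seed: 1
  grid_dt: 1.0
  max_cells: 64
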