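name: flux_balanced
# Metabolic flux model: M1 is taken up from the medium, enzyme a converts
# M1 -> M2, enzyme b converts M2 -> M3, M1 and M3 are utilized first-order.
# Both enzyme genes sit at the middle of the chromosome, so their dosage
# profiles coincide and the M2 input and output fluxes balance on cycle
# average.
species:
  - {name: mRNA_a, initial_count: 10}
  - {name: enzyme_a, initial_count: 100}
  - {name: mRNA_b, initial_count: 10}
  - {name: enzyme_b, initial_count: 100}
  - {name: M1, initial_count: 50}
  - {name: M2, initial_count: 50}
  - {name: M3, initial_count: 50}
reactions:
  - name: translation_a
    modifiers: {mRNA_a: 1}
    products: {enzyme_a: 1}
    rate: 1.0
    rate_units: per_mRNA_per_second
  - name: translation_b
    modifiers: {mRNA_b: 1}
    products: {enzyme_b: 1}
    rate: 1.0
    rate_units: per_mRNA_per_second
  - name: m1_influx
    products: {M1: 1}
    rate: 100.0
    rate_units: uM_per_second
    volume_class: proportional
  - name: m1_utilization
    reactants: {M1: 1}
    rate: 1.0
    rate_units: per_second
  - name: m3_utilization
    reactants: {M3: 1}
    rate: 1.0
    rate_units: per_second
  - name: catalysis_a
    reactants: {M1: 1}
    products: {M2: 1}
    modifiers: {enzyme_a: 1}
    rate: 10.0
    rate_units: per_second
    rate_law: michaelis_menten
    km: 1.0
  - name: catalysis_b
    reactants: {M2: 1}
    products: {M3: 1}
    modifiers: {enzyme_b: 1}
    rate: 10.0
    rate_units: per_second
    rate_law: michaelis_menten
    km: 1.0
  - name: mrna_a_decay
    reactants: {mRNA_a: 1}
    rate: 1.0
    rate_units: per_second
  - name: mrna_b_decay
    reactants: {mRNA_b: 1}
    rate: 1.0
    rate_units: per_second
  - name: enzyme_a_decay
    reactants: {enzyme_a: 1}
    rate: 0.01
    rate_units: per_second
  - name: enzyme_b_decay
    reactants: {enzyme_b: 1}
    rate: 0.01
    rate_units: per_second
genes:
  - name: gene_a
    position: 0.5
    transcription_rate: 1.0
    mrna: mRNA_a
  - name: gene_b
    position: 0.5
    transcription_rate: 1.0
    mrna: mRNA_b
config:
  T: 50
  C: 40
  D: 20
  t_end: 12000
  seed: 1
  grid_dt: 1.0
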