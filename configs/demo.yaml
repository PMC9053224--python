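# End-to-end demo configuration: small enough to run in well under a minute
# on one CPU, while exercising every stage of the pipeline.
seed: 7

stages: [simulate, descriptives, cooccurrence, sem, prs, assoc]

simulate:
  n_participants: 400
  n_variants: 80
  n_blocks: 8
  block_rho: 0.5
  gwas_n: 50000
  exposure_probs:
    sertraline: 0.55
    escitalopram: 0.45
    venlafaxine: 0.45
    fluoxetine: 0.40
    citalopram: 0.35
    desvenlafaxine: 0.30
    duloxetine: 0.30
    mirtazapine: 0.30
    amitriptyline: 0.30
    paroxetine: 0.25
  class_loadings:
    sweating: {SNRI: 0.45}
  genetic_betas:
    weight_gain: [bmi, 0.3]
    insomnia: [insomnia, 0.25]
  sex_effects:
    nausea: 0.3
  emit_indication_flag: true
  indication_prob: 0.3

descriptives:
  stratify_sex: true

cooccurrence:
  min_pair_n: 30
  effects: [nausea, headache, sweating, weight_gain]

sem:
  side_effects: [nausea, sweating]
  nodes: 9
  starts: 2

prs:
  clump_r2: 0.1
  clump_kb: 10000
  pcs_k: 10

assoc:
  family: per_drug_10
  pairs:
    - {trait: bmi, side_effect: weight_gain}
    - {trait: insomnia, side_effect: insomnia}
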