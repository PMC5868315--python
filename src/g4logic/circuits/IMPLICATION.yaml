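format: g4logic-circuit/1
name: IMPLICATION
provenance: reconstructed
declared_function: [1, 0, 1, 1]
strands:
- name: DNA1
  domains: ['E/toehold:6', 'p:12', 'r:12']
- name: DNA2
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'p*/recognition_arm:12']
- name: DNA3
  domains: ['r*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA4
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'm*/recognition_arm:12']
- name: DNA5
  domains: ['n*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA6
  domains: ['g4/g4_segment:17', 'sL:8', 'sR:8', 'g4*/g4_segment:17']
  ra_site: 2
  caged_g4: [0, 0]
inputs:
- name: input1
  domains: ['p*:12', 'E*/toehold:6']
- name: input2
  domains: ['m:12', 'n:12']
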