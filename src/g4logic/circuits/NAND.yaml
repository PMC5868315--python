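format: g4logic-circuit/1
name: NAND
provenance: reconstructed
declared_function: [1, 1, 1, 0]
strands:
- name: DNA1
  domains: ['E/toehold:6', 'p:12', 'r:12', 'H/toehold:6']
- name: DNA2
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'a*/recognition_arm:12']
- name: DNA3
  domains: ['b*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA4
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'q/recognition_arm:12']
- name: DNA5
  domains: ['c/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA6
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'p*/recognition_arm:12']
- name: DNA7
  domains: ['r*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA8
  domains: ['g4/g4_segment:17', 'sL:8', 'sR:8', 'g4*/g4_segment:17']
  ra_site: 2
  caged_g4: [0, 0]
inputs:
- name: input1
  domains: ['a:12', 'b:12', 'c:12', 'q:12', 'p*:12', 'E*/toehold:6']
- name: input2
  domains: ['H*/toehold:6', 'r*:12', 'q*:12', 'c*:12', 'b*:12', 'a*:12']
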