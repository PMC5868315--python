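format: g4logic-circuit/1
name: INHIBIT
provenance: reconstructed
declared_function: [0, 1, 0, 0]
strands:
- name: DNA1
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'a*/recognition_arm:12']
- name: DNA2
  domains: ['b*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA3
  domains: ['g4/g4_segment:17', 'sL:8', 'sR:8', 'g4*/g4_segment:17']
  ra_site: 2
  caged_g4: [0, 0]
inputs:
- name: input1
  domains: ['a:12', 'b:12']
- name: input2
  domains: ['b*:12', 'a*:12']
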