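format: g4logic-circuit/1
name: XOR_AND
provenance: reference
declared_function: [0, 1, 1, 1]
strands:
- name: DNA1
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'a*/recognition_arm:12']
- name: DNA2
  domains: ['b*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA3
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'q/recognition_arm:12']
- name: DNA4
  domains: ['c/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA5
  domains: ['sL*/substrate_arm:8', 'cI/catalytic_core_I:8', 'E*/recognition_arm:12']
- name: DNA6
  domains: ['F*/recognition_arm:12', 'cII/catalytic_core_II:7', 'sR*/substrate_arm:8']
- name: DNA7
  domains: ['g4/g4_segment:17', 'sL:8', 'sR:8', 'g4*/g4_segment:17']
  ra_site: 2
  caged_g4: [0, 0]
inputs:
- name: input1
  domains: ['E:12', 'a:12', 'b:12', 'c:12', 'q:12']
- name: input2
  domains: ['q*:12', 'c*:12', 'b*:12', 'a*:12', 'F:12']
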