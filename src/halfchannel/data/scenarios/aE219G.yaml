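label: aE219G
source_selection: chain A and resid 119 and polar
sink_selection: chain C and resid 61 and polar
substitutions:
- chain: A
  res_seq: 219
  from_res: GLU
  to_res: GLY
regions:
- name: W1
  anchor_a: chain C and resid 61 and name CA
  anchor_b: chain A and resid 214 and name CA
  radius: 3.5
  center_rule: midpoint_of_anchor_centroids
- name: W2/W3
  anchor_a: chain A and resid 245 and name CA
  anchor_b: chain A and resid 214 and name CA
  radius: 3.5
  center_rule: midpoint_of_anchor_centroids
gate_residues:
- chain: A
  res_seq: 140
- chain: A
  res_seq: 119
- chain: A
  res_seq: 219
- chain: A
  res_seq: 245
canonical_chain:
- kind: residue
  label: aE219
  selection: chain A and resid 219 and polar
  regions: []
- kind: residue
  label: aD119
  selection: chain A and resid 119 and polar
  regions: []
- kind: residue
  label: aH245
  selection: chain A and resid 245 and polar
  regions: []
- kind: region
  label: W2/W3
  selection: null
  regions:
  - W2/W3
- kind: residue
  label: aN214
  selection: chain A and resid 214 and polar
  regions: []
- kind: region
  label: W1
  selection: null
  regions:
  - W1
- kind: residue
  label: cD61
  selection: chain C and resid 61 and polar
  regions: []
md_metadata:
  temperature_K: 310
  pressure_bar: 1
  ensemble: NPT
  engine: NAMD 2.14
  force_field: CHARMM36
  production_ns: 150
  frame_interval_ps: 2
  note: simulation parameters recorded as metadata only
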