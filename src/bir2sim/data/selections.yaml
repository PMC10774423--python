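# Named residue selections for the XIAP BIR2 domain (UniProt numbering,
# residues 163-234).  version 1.
version: 1
domain_range: [163, 234]
selections:
  hydrophobic_core: [170, 173, 177, 179, 184, 187, 189, 198, 207, 210, 216]
  helix_163_168: {range: [163, 168]}
  helix_181_186: {range: [181, 186]}
  loop_174_182: {range: [174, 182]}
  region_192_198: {range: [192, 198]}
  loop_205_215: {range: [205, 215]}
  beta_198_200: {range: [198, 200]}
  beta_206_208: {range: [206, 208]}
  zn_finger: [200, 203, 220, 227]
  rip2_binding_loops: {union: [loop_174_182, loop_205_215]}
  domain: {range: [163, 234]}
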