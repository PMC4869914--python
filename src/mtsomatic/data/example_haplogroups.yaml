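# Illustrative haplogroup definition set for the host-naming scheme.
# Each haplogroup lists its parent and the diagnostic variants that must
# all be present (in addition to the parent chain's) for assignment.
# Study-specific diagnostic tables are external inputs and are not bundled.
- name: A
  parent: null
  variants: ["1013:A>G"]
- name: A1
  parent: A
  variants: ["2216:C>T"]
- name: A1a
  parent: A1
  variants: ["4401:G>A"]
- name: A1c
  parent: A1
  variants: ["5321:T>C"]
  merged_with: ["A1e"]
- name: A1e
  parent: A1
  variants: ["5321:T>C"]
  merged_with: ["A1c"]
- name: B
  parent: null
  variants: ["8368:C>T"]
- name: B1
  parent: B
  variants: ["9911:T>C"]
- name: C
  parent: null
  variants: ["11053:G>A"]
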