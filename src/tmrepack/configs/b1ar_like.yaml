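# Turkey-beta1AR-like target specification (the method's validation target).
# Per-helix tether counts: 5, 7, 9, 3, 7, 7, 5 for TM1-TM7.
name: b1ar_like
helix_spans:
  - [40, 68]    # TM1  W40-S68
  - [75, 103]   # TM2  L75-V103
  - [110, 142]  # TM3  G110-A142
  - [155, 177]  # TM4  R155-I177
  - [205, 233]  # TM5  R205-E233
  - [286, 314]  # TM6  H286-V314
  - [322, 343]  # TM7  D322-Y343
tether_residues:
  - [40, 47, 54, 61, 68]
  - [75, 80, 84, 89, 94, 98, 103]
  - [110, 114, 118, 122, 126, 130, 134, 138, 142]
  - [155, 166, 177]
  - [205, 210, 214, 219, 224, 228, 233]
  - [286, 291, 295, 300, 305, 309, 314]
  - [322, 327, 332, 338, 343]
serine_residues: [211, 215]     # S5.42, S5.46
aspartate_residue: 121          # D3.32
aromatic_residues: [306, 307]   # F6.51, F6.52
receptor_anchors:
  # aspartate carboxylate to serine hydroxyls window: 9.5 +/- 1.5 A
  - receptor_atoms: [[121, OD1], [121, OD2]]
    receptor_atoms_b: [[211, OG], [215, OG]]
    target: 9.5
    half_width: 1.5
acceptance:
  hbond_asp_max: -0.2
  hbond_ser_max: -0.2
  aromatic_vdw_max: -0.3
loop_lengths: [6, 6, 12, 27, 52, 7]
ligand: S-cyanopindolol
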