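# Dopamine-D2-like target specification.
# Helix spans and per-helix tether counts (3, 10, 6, 5, 10, 11, 4; mean 7)
# follow the published D2 modeling setup; tether residue identities are
# evenly spread within each span (the conserved-residue list itself is a
# modeling input, only the counts are prescribed).
name: d2_like
helix_spans:
  - [34, 62]    # TM1
  - [67, 97]    # TM2
  - [102, 134]  # TM3
  - [149, 173]  # TM4
  - [185, 211]  # TM5
  - [368, 400]  # TM6
  - [405, 425]  # TM7
tether_residues:
  - [34, 48, 62]
  - [67, 70, 74, 77, 80, 84, 87, 90, 94, 97]
  - [102, 108, 115, 121, 128, 134]
  - [149, 155, 161, 167, 173]
  - [185, 188, 191, 194, 197, 199, 202, 205, 208, 211]
  - [368, 371, 374, 378, 381, 384, 387, 390, 394, 397, 400]
  - [405, 412, 418, 425]
serine_residues: [193, 197]     # S5.42, S5.46
aspartate_residue: 114          # D3.32
aromatic_residues: [389, 390]   # F6.51, F6.52
receptor_anchors:
  # aspartate carboxylate to serine hydroxyls window: 12 +/- 2 A
  - receptor_atoms: [[114, OD1], [114, OD2]]
    receptor_atoms_b: [[193, OG], [197, OG]]
    target: 12.0
    half_width: 2.0
acceptance:
  hbond_asp_max: -0.2
  hbond_ser_max: -0.2
  aromatic_vdw_max: -0.3
loop_lengths: [4, 4, 14, 11, 156, 4]
ligand: R-NPA
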