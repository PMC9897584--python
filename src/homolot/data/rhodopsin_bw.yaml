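# Ballesteros-Weinstein (BW) configuration for the vertebrate rod opsin
# reference frame (human/bovine rhodopsin numbering).
#
# Provenance: the x.50 anchor residues are the most conserved position of
# each transmembrane helix in class A GPCRs (N55 1.50, D83 2.50, R135 3.50,
# W161 4.50, P215 5.50, P267 6.50, P303 7.50); helix spans follow the rod
# opsin crystal-structure assignment.  The 30 cavity-facing pocket
# positions are derived from chemogenomic analyses of the class A
# ligand-binding cavity and are editable: they are configuration, not
# constants of the method.  The minimal 4-residue signalling pocket is
# left empty by default; the 3-of-4 conservation check only runs when a
# user supplies it.
reference_id: RHO_HUMAN
anchors:
  1: 55
  2: 83
  3: 135
  4: 161
  5: 215
  6: 267
  7: 303
helix_bounds:
  1: [34, 64]
  2: [71, 100]
  3: [106, 139]
  4: [150, 173]
  5: [200, 230]
  6: [246, 277]
  7: [285, 309]
pocket_positions:
  - "2.53"
  - "2.57"
  - "2.60"
  - "2.61"
  - "2.64"
  - "3.28"
  - "3.32"
  - "3.33"
  - "3.36"
  - "3.37"
  - "3.40"
  - "4.56"
  - "4.60"
  - "5.39"
  - "5.42"
  - "5.43"
  - "5.46"
  - "5.47"
  - "6.44"
  - "6.48"
  - "6.51"
  - "6.52"
  - "6.55"
  - "6.58"
  - "7.35"
  - "7.38"
  - "7.39"
  - "7.42"
  - "7.43"
  - "7.46"
# Retinal-binding rule: the Schiff-base lysine of rod opsin is K296 (BW
# 7.43); its counter-ion is E113 (BW 3.28).
schiff_position: "7.43"
counterion_position: "3.28"
minimal_pocket: []
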