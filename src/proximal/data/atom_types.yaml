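# KEGG-style atom type decision table.
#
# Rules are evaluated top to bottom; the first rule whose constraints all
# hold assigns its code.  Atoms matching no rule receive the flagged
# fallback "<Element>?" and are excluded from look-up table matching.
#
# Recognised constraint fields (all optional except code/elements):
#   elements           list of element symbols the rule applies to
#   aromatic           bool  - atom carries the aromatic flag
#   in_ring            bool  - atom is a ring member
#   min_h / max_h      int   - bounds on the (implicit) hydrogen count
#   heavy_degree       int   - exact number of heavy-atom neighbours
#   min_heavy_degree / max_heavy_degree
#   unsaturated        bool  - atom has a non-aromatic double or triple bond
#   double_to          list  - has a non-aromatic double/triple bond to one
#                              of these elements
#   double_to_aromatic bool  - has a non-aromatic double bond to an atom
#                              flagged aromatic (e.g. pyridone-type oxygen)
#   carboxyl_self      bool  - the atom itself bears >=2 oxygen neighbours,
#                              at least one via a double bond (carboxyl C)
#   carboxyl_neighbor  bool  - bonded to a carbon that bears >=2 oxygens,
#                              at least one via a double bond
#
# The table covers the subset of KEGG atom classes exercised by small
# drug-like molecules; extend it here (no code changes needed) to add more.
rules:
  # halogens collapse to the single KEGG halogen class
  - {code: X, elements: [F, Cl, Br, I]}

  # carbon
  - {code: C8x, elements: [C], aromatic: true, min_h: 1}      # aromatic CH
  - {code: C8y, elements: [C], aromatic: true}                # substituted aromatic C
  - {code: C6a, elements: [C], double_to: [O], carboxyl_self: true}  # carboxyl/ester C
  - {code: C5a, elements: [C], double_to: [O]}                # ketone/amide carbonyl C
  - {code: C2x, elements: [C], unsaturated: true, in_ring: true}   # sp2 C in ring
  - {code: C2y, elements: [C], unsaturated: true}             # sp2 C outside ring
  - {code: C1a, elements: [C], max_heavy_degree: 1}           # R-CH3
  - {code: C1b, elements: [C], heavy_degree: 2}               # R-CH2-R
  - {code: C1c, elements: [C], heavy_degree: 3}               # R3-CH
  - {code: C1d, elements: [C], heavy_degree: 4}               # R4-C

  # nitrogen
  - {code: N4x, elements: [N], aromatic: true, min_h: 1}      # aromatic NH
  - {code: N4y, elements: [N], aromatic: true}                # substituted aromatic N
  - {code: N2b, elements: [N], unsaturated: true}             # imine-class N (C=N)
  - {code: N1a, elements: [N], max_heavy_degree: 1}           # primary amine/amide N
  - {code: N1b, elements: [N], heavy_degree: 2}               # secondary amine/amide N
  - {code: N1c, elements: [N], heavy_degree: 3}               # tertiary N

  # oxygen
  - {code: O5x, elements: [O], double_to_aromatic: true}      # exocyclic O on aromatic ring
  - {code: O6a, elements: [O], carboxyl_neighbor: true}       # carboxyl/ester O
  - {code: O5a, elements: [O], double_to: [C]}                # carbonyl O
  - {code: O1d, elements: [O], double_to: [S, P]}             # S=O / P=O oxygen
  - {code: O2x, elements: [O], in_ring: true, heavy_degree: 2}  # ring O (epoxide, pyranose)
  - {code: O2a, elements: [O], heavy_degree: 2}               # ether O
  - {code: O1a, elements: [O], max_heavy_degree: 1}           # hydroxyl O

  # sulfur / phosphorus
  - {code: S4a, elements: [S], double_to: [O]}                # sulfonate/sulfate S
  - {code: S2x, elements: [S], aromatic: true}                # aromatic S
  - {code: S2a, elements: [S], heavy_degree: 2}               # thioether S
  - {code: S1a, elements: [S], max_heavy_degree: 1}           # thiol S
  - {code: P1b, elements: [P]}
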