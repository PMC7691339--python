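# Conserved-cysteine scaffold profiles.
#
# Each anchor is a required residue; gap_min/gap_max bound the spacer
# PRECEDING it (first anchor has no gap).  "extras" encodes a C-terminal
# extension rule: at least min_extra further copies of the residue after the
# final anchor, then a required trailing residue.
#
# Users may copy this file, edit it, and pass it via --patterns.

classic_obp:
  anchors:
    - {residue: C}
    - {residue: C, gap_min: 23, gap_max: 44}
    - {residue: C, gap_min: 3}
    - {residue: C, gap_min: 36, gap_max: 43}
    - {residue: C, gap_min: 8, gap_max: 12}
    - {residue: C, gap_min: 8}

# Derived from classic_obp by deleting anchors C2 and C5 and merging the
# flanking gaps (sum of bounds, +1 per absorbed anchor position).
minusc_obp:
  anchors:
    - {residue: C}
    - {residue: C, gap_min: 27, gap_max: 48}
    - {residue: C, gap_min: 36, gap_max: 43}
    - {residue: C, gap_min: 17, gap_max: 21}

# The plus-C rule is classic_obp plus this extension.
plusc_obp:
  anchors:
    - {residue: C}
    - {residue: C, gap_min: 23, gap_max: 44}
    - {residue: C, gap_min: 3}
    - {residue: C, gap_min: 36, gap_max: 43}
    - {residue: C, gap_min: 8, gap_max: 12}
    - {residue: C, gap_min: 8}
  extras: {residue: C, min_extra: 7, trailing_residue: P}

csp:
  anchors:
    - {residue: C}
    - {residue: C, gap_min: 6}
    - {residue: C, gap_min: 18}
    - {residue: C, gap_min: 2}
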