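# Example residue grouping for the grouped dynamical-memory report
# (condact report --groups ... / RunConfig.groups).
#
# Members may be plain residue numbers, inclusive "start-end" ranges, or
# segment-qualified ranges "SEG:start-end" that target one chain.  The
# histone-tail boundaries below are conventional choices (N-terminal
# tails up to the first core helix) for a nucleosome whose histone
# chains are named H3/H4/H2A/H2B and numbered from 1 — EDIT THEM to
# match your topology's chain names and numbering.
tails:
  - "H3:1-38"    # H3 N-tail (up to the alphaN helix)
  - "H4:1-24"    # H4 N-tail
  - "H2A:1-15"   # H2A N-tail
  - "H2B:1-34"   # H2B N-tail
core:
  - "H3:39-135"
  - "H4:25-102"
  - "H2A:16-129" # includes the H2A C-terminal tail
  - "H2B:35-125"
H3:
  - "H3:1-135"
H4:
  - "H4:1-102"
H2A:
  - "H2A:1-129"
H2B:
  - "H2B:1-125"
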