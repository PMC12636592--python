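#!/bin/sh
# Full pipeline from the shell: simulate a seeded synthetic experiment,
# stitch it, evaluate the alignment and call reads.  All artifacts (tile
# TIFFs, constraint/colony/cell TSVs, manifests) land in ./demo_out.
set -e

issq simulate --out demo_out --seed 3 --grid 3x3 --cycles 4
issq stitch --out demo_out --method mae --integerize round --merge mean
issq evaluate --out demo_out
issq call-reads --out demo_out --k 2

# Or everything at once (equivalent artifacts, byte-identical tables for
# the same seed):
#   issq run --out demo_out --seed 3 --grid 3x3 --cycles 4
head -3 demo_out/cells.tsv
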