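"""Sequence-derived construct properties.

Computes the average molecular weight and nearest-neighbor extinction
coefficient at 260 nm for the telomere repeat constructs, the numbers used
to normalize every downstream concentration-dependent measurement.
"""

from quadflex.datasets import CONSTRUCT_SEQUENCES
from quadflex.io import oligo_eps260, oligo_mw

print(f"{'construct':10s} {'nt':>4s} {'MW (kDa)':>9s} {'eps260 (1/M/cm)':>16s}")
for name in ("2JSL", "Tel48", "Tel72", "Tel96"):
    seq = CONSTRUCT_SEQUENCES[name]
    print(f"{name:10s} {len(seq):4d} {oligo_mw(seq):9.1f} "
          f"{oligo_eps260(seq):16.0f}")

print("\nMW is the linear free-acid 5'-OH average mass; eps260 converts "
      "absorbance\nto strand concentration for CD normalization and "
      "sample preparation.")
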