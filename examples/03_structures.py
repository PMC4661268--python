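"""Reaction coordinates from 4-chain bundle structures.

Builds toy tetrameric bundles, extracts the two diagonal marker C-alpha
distances (zeta1, zeta2), and generates intermediate structures along the
closed-to-open pathway by rigid-body radial interpolation.
"""
from porepmf import extract_reaction_coordinates, interpolate_structures, make_toy_bundle

closed = make_toy_bundle(9.6, 9.6)    # crystal-like closed bundle
open_ = make_toy_bundle(12.5, 12.5)   # wide-open bundle

rc = extract_reaction_coordinates(closed)
pairs = ["-".join(map(str, pair)) for pair in rc.pairing]
print(f"closed bundle : zeta1 = {rc.zeta1:.3f} A, zeta2 = {rc.zeta2:.3f} A, "
      f"diagonals {pairs[0]} and {pairs[1]}")

targets = [(10.0, 10.0), (11.05, 11.05), (9.5, 12.0)]
for target, structure in zip(targets, interpolate_structures(closed, open_, targets)):
    rc = extract_reaction_coordinates(structure)
    print(f"target {target} -> extracted ({rc.zeta1:.4f}, {rc.zeta2:.4f}) A")

print("\nEach interpolated structure hits its requested (zeta1, zeta2) to ~1e-3 A;")
print("chains move as rigid bodies, so intra-chain geometry is untouched. These")
print("structures seed the per-window simulations of a real umbrella campaign.")
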