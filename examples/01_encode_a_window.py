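"""Encode one candidate phosphosite window into its descriptor vector.

The window KAGVSPHED (a serine in the middle of nine residues) becomes a
593-position vector: entropy measures, an accessibility channel, class
bits, hydrophobicity means, identity bits, CTD, and sequence-order terms.
"""

from phosforest.features import (
    FeatureSchema,
    ctd_encode,
    encode,
    overlapping_properties,
)

window = "KAGVSPHED"
schema = FeatureSchema.for_window(9)
vec = encode(window, schema)

print(f"window {window!r} -> {len(vec.values)} features")
for family, start, stop in schema.blocks:
    print(f"  {family:<5} positions {start:>3}-{stop:>3}")

h, re_, ig = vec.values[:3]
print(f"\nShannon entropy H = {h:.4f} bits (diversity of the window)")
print(f"relative entropy RE = {re_:.4f} (distance from the uniform 1/9)")
print(f"information gain IG = H - RE = {ig:.4f}")

bits = "".join(str(int(b)) for b in overlapping_properties("H"))
print(f"\nhistidine's 10 overlapping-class bits: {bits}")
print("  (polar, positive, charged, hydrophobic, aromatic)")
print(f"MVKELRTA under the hydrophobicity 3-group code: {ctd_encode('MVKELRTA')}")
print("  (1 = polar, 2 = neutral, 3 = hydrophobic residue)")
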