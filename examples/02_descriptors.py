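"""Compute the 31 physiochemical descriptors for a peptide.

The pocket B and F windows score the hydropathy of the residues facing
the HLA-A*02:01 anchor pockets (peptide positions 2 and 9); hydrophobic
anchors (L/V/I/M) push them up.
"""

from pepgan import compute_descriptors, descriptor_frame, pocket_windows, robust_scale
from pepgan.descriptors import DESCRIPTOR_NAMES

seq = "AAGIGILTV"  # MART-1 epitope: A at position 2, V at position 9
vec = compute_descriptors(seq)
for name, value in zip(DESCRIPTOR_NAMES, vec):
    print(f"{name:24s} {value:12.4g}")

b, f = pocket_windows(seq)
print(f"\npocket B (pos 2 = {seq[1]}): {b:+.1f}   pocket F (pos 9 = {seq[8]}): {f:+.1f}")
print("Position 9 carries valine, a canonical hydrophobic F-pocket anchor,")
print("so the F window is strongly positive on the hydropathy scale.")

scaled = robust_scale(descriptor_frame([seq, "FLIDLAFLI", "CLICMDMVV", "GGGGGGGGG"]))
print("\nafter robust scaling every feature column has median 0:")
print(scaled.values.round(2).head(2).to_string())
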