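"""Single-cell copy numbers to cytoplasmic molar concentrations.

C = N / (V_cyto * N_A), with the nucleus taking 25% of the cell volume and
1 um^3 = 1e-15 L.  Typical animal cells span 1000-25000 um^3.
"""

from mirneq import CellSpec, copies_to_molar, molar_to_copies

for copies, volume, label in (
    (1, 25_000.0, "1 mRNA copy, large cell"),
    (1000, 1000.0, "abundant mRNA, small cell"),
    (10_000, 1000.0, "highly expressed miRNA, small cell"),
):
    conc = copies_to_molar(CellSpec(copies, volume))
    print(f"{label:38s} {copies:>6} copies / {volume:>7.0f} um^3  ->  {conc:.3e} M")

print()
copies = molar_to_copies(1e-6, 1000.0)
print(f"1 uM in a 1000 um^3 cell (25% nucleus) corresponds to {copies:,.0f} copies")
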