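"""Single-cut fragmentation and virtual-analogue construction.

Cutting compound 3 at its biphenyl bond and welding the trifluoromethyl
substituent onto the freed core constructs compound 4 — a novel
core/substituent combination taken from structurally distinct compounds.
"""

from sarmatrix import enumerate_cuts, reassemble, standardize_structure
from sarmatrix.datasets import MMP1_SMILES

pairs = enumerate_cuts(MMP1_SMILES["3"])
print(f"compound 3 has {len(pairs)} admissible single cuts:")
for p in pairs:
    print(f"  core {p.core_heavy_atoms:>2} atoms | substituent {p.substituent}")

(biphenyl_cut,) = [p for p in pairs if p.substituent == "*c1ccccc1"]
virtual = reassemble(biphenyl_cut.core, "[*]C(F)(F)F")
print("\nwelding the phenyl-cut core to [*]C(F)(F)F gives:")
print(" ", virtual)
print("identical to compound 4:", virtual == standardize_structure(MMP1_SMILES["4"]))
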