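"""Convert measured activities to the p-scale and size an activity cliff.

The MMP-1 validation series ships with the package: compound 3 (biphenyl)
and compound 4 (para-CF3) differ by one substituent but by almost two log
units of IC50 — an activity cliff confirmed by experiment.
"""

from sarmatrix import to_p_potency
from sarmatrix.datasets import MMP1_IC50_UM

p3 = to_p_potency(MMP1_IC50_UM["3"][0], "µM")
p4 = to_p_potency(MMP1_IC50_UM["4"][0], "µM")

print(f"compound 3: IC50 11.5 uM -> pIC50 {p3:.3f}")
print(f"compound 4: IC50 0.18 uM -> pIC50 {p4:.3f}")
print(f"potency gap: {p4 - p3:.3f} log units = {10 ** (p4 - p3):.1f}-fold")
# The ~64-fold gap from a single phenyl->CF3 swap is the cliff this
# package is designed to predict before the potent analogue is made.
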