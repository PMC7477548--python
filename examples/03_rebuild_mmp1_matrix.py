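"""Rebuild the MMP-1 SAR matrix with compound 4 held out.

Holding out the potent analogue recreates the discovery situation: the
remaining compounds (3, 5, 6 — the inactive diastereomers are qualified
'>' measurements and are excluded) organize into one matrix whose rows are
the para- and meta-attached lactam cores, and the missing (para-core, CF3)
combination reappears as a virtual cell that welds to exactly compound 4.
"""

from sarmatrix import (
    build_matrices,
    build_series_index,
    fit,
    load_compounds,
    predict_cell,
    reassemble,
    standardize_structure,
)
from sarmatrix.datasets import MMP1_SMILES, mmp1_activity_records

compounds = load_compounds(mmp1_activity_records(exclude=("4",)))
(matrix,) = build_matrices(build_series_index(compounds))

print(f"matrix {matrix.matrix_id}: {len(matrix.rows)} rows x {len(matrix.columns)} columns")
for r, c, cell in matrix.observed_cells():
    print(f"  observed  compound {cell.compound_id}: p = {cell.p_potency:.2f}  [{c}]")

target = standardize_structure(MMP1_SMILES["4"])
model = fit(matrix)
for r, c in matrix.virtual_cells():
    smiles = reassemble(r, c)
    marker = "  <-- compound 4" if smiles == target else ""
    pred = predict_cell(model, r, c)
    pred_txt = f"pred p = {pred:.2f}" if pred is not None else "no prediction"
    print(f"  virtual   [{c}] {pred_txt}{marker}")
# With only these four observations the local model has little signal;
# predicting the cell's potency needs the wider inhibitor corpus, where
# other series establish the large CF3 contribution.
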