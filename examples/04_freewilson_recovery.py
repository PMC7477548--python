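"""Exact recovery of withheld potencies by the local Free-Wilson model.

On a noise-free additive matrix with 25% of cells withheld, the model
reproduces every withheld potency to numerical precision — the structural
guarantee behind virtual-analogue prediction.
"""

from sarmatrix import SimConfig, fit, make_matrix, predict_cell

config = SimConfig(
    n_scaffolds=5, n_substituents=6, noise_sd=0.0, missing_frac=0.25,
    n_cliffs=0, seed=17,
)
matrix, truth = make_matrix(config)
model = fit(matrix)

print(f"{len(matrix.rows)}x{len(matrix.columns)} matrix, "
      f"{matrix.n_observed} observed, {len(matrix.virtual_cells())} withheld")
worst = 0.0
for r, c in matrix.virtual_cells():
    pred = predict_cell(model, r, c)
    err = abs(pred - truth.truth[(r, c)])
    worst = max(worst, err)
    print(f"  {r},{c}: truth {truth.truth[(r, c)]:.4f}  predicted {pred:.4f}  |err| {err:.2e}")
print(f"worst absolute error: {worst:.2e}  (additive ground truth is recovered exactly)")
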