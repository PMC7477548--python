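# sarmatrix

SAR matrices, local Free-Wilson potency models, and activity-cliff
candidate ranking for analogue series.

## The problem

In lead optimization, most useful potency gains hide in *SAR
discontinuity*: regions where a small chemical change (one substituent
swap) produces a large potency jump — an **activity cliff**. Ordinary QSAR
methods assume smooth structure–activity surfaces and cannot predict
cliffs. The SAR-matrix approach attacks the problem combinatorially:

1. **Fragment** every active compound by systematically cleaving each
   acyclic single bond (size-restricted single cuts), giving core /
   substituent pairs.
2. **Organize** structurally related analogue series into matrices: cores
   that share a second-stage core (*hypercore*) become rows, their
   substituents become columns. Grid positions without an existing
   compound are **virtual analogues** — real, makeable structures obtained
   by welding a row's core onto a column's substituent.
3. **Predict** virtual-cell potencies with a local additive (Free-Wilson)
   model fitted to each matrix's observed cells:

   p(i, j) = μ + αᵢ + βⱼ,  Σαᵢ = Σβⱼ = 0 (per connected component),

   estimated by least squares on the observed-cell bipartite graph.
4. **Rank** candidate cliffs: pairs of a weakly potent observed compound
   and a virtual analogue in the same row or column predicted to be at
   least `delta_min` log units more potent (default 1.0 — one order of
   magnitude).

The package is aimed at computational and medicinal chemists who have a
compound–activity table (Ki or IC50) and want a deterministic, fully
scriptable screen for "which unmade analogue is most likely to form a
cliff with what we already have".

## Worked example

The package ships the six-compound MMP-1 N-hydroxy-lactam validation
series (IC50-annotated, structures name-derived). Holding out the potent
para-CF3 analogue (compound 4) and rebuilding:

```python
from sarmatrix import build_matrices, build_series_index, load_compounds, reassemble
from sarmatrix.datasets import mmp1_activity_records

compounds = load_compounds(mmp1_activity_records(exclude=("4",)))
(matrix,) = build_matrices(build_series_index(compounds))
for r, c in matrix.virtual_cells():
    print(c, reassemble(r, c))
```

Running `python examples/03_rebuild_mmp1_matrix.py` prints:

```
matrix a1879faae3f3: 2 rows x 3 columns
  observed  compound 3: p = 4.94  [*c1ccccc1]
  observed  compound 5: p = 5.81  [[*][H]]
  observed  compound 6: p = 4.95  [*C(F)(F)F]
  observed  compound 5: p = 5.81  [[*][H]]
  virtual   [*C(F)(F)F] pred p = 4.95  <-- compound 4
  virtual   [*c1ccccc1] pred p = 4.94
```

The two rows are the para- and meta-attached lactam cores (they share the
lactam hypercore); the held-out compound reappears as the (para-core, CF3)
virtual cell, and welding that cell's fragments reproduces compound 4's
structure exactly. Measured potencies (`examples/01_potency_scales.py`)
put the confirmed cliff at **63.9-fold** (pIC50 6.745 vs 4.939). With only
four local observations the model predicts p 4.95 for the cell — potency
predictions of this constellation need the wider inhibitor corpus, where
other series establish the CF3 contribution; the point of the desk-scale
fixture is the reconstruction of the cliff *candidate*, not its magnitude.

`examples/05_cliff_screen_pipeline.py` runs the whole pipeline on a
synthetic combinatorial library with one injected 2-log cliff and prints
the ranked candidate list; the injected combination is recovered as the
top candidate (predicted p 8.95 vs observed 6.58, delta 2.37).

## Command line

```bash
sarmatrix run --input compounds.csv --out outdir/     # full pipeline
sarmatrix simulate --out sim/ --seed 5                # synthetic library
```

Input CSV columns: `compound_id, smiles, value, unit, type, relation`.
Outputs: compound table, fragment index, matrices (JSON/CSV),
discontinuity report, Free-Wilson models, predictions, ranked cliff
candidates, and a run summary with config and input checksums. Identical
inputs, config and seed give byte-identical outputs.

## Layout

- `src/sarmatrix/chem_io.py` — records, p-scale conversion, standardization, aggregation
- `src/sarmatrix/fragmentation.py` — single-cut enumeration, welding, H-capping
- `src/sarmatrix/sarm_builder.py` — series index, hypercore grouping, matrices
- `src/sarmatrix/discontinuity.py` — neighbor-pair gap scoring
- `src/sarmatrix/freewilson.py` — per-component additive least squares
- `src/sarmatrix/cliff_predictor.py` — candidate enumeration, gating, ranking, reports
- `src/sarmatrix/synthetic_data.py` — additive matrices, libraries, cliff injection
- `src/sarmatrix/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
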