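# Methods

## Scope and data model

The package operates on compound–activity tables: one measurement per row
with a SMILES, a positive activity value (Ki or IC50) in nM/µM/M, and a
relation qualifier. All modeling happens on the p-scale, p = −log10 of the
molar value, so that potency differences are additive and "one order of
magnitude" is one unit. Ki- and IC50-derived potencies are never mixed in
one analysis: a pKi and a pIC50 are not comparable, and the series index
refuses mixed sets.

Curation defaults (all configurable):

- Qualified measurements (`<`, `>`, `<=`, `>=`) are excluded. They carry a
  bound, not a value, and a censored bound entering a least-squares fit as
  if exact would bias every effect sharing its row or column.
- Replicates of one standardized structure aggregate by the **median** on
  the p-scale — robust to the occasional order-of-magnitude outlier that
  unit-transcription errors produce in public data.
- Standardization keeps the largest organic fragment (salt stripping) and
  preserves stereochemistry. Stereoisomers are distinct compounds: the
  validation series contains diastereomer pairs whose activities differ by
  more than two orders of magnitude, so collapsing stereo would merge a
  potent compound with an inactive one.

## Fragmentation

"Single cut" means cleaving one acyclic single bond between two heavy
atoms; ring bonds and bonds to hydrogen are never cut. Each cut gives a
core (larger fragment) and substituent (smaller), both carrying one `[*]`
attachment point. Ties at equal heavy-atom count go to the ring-containing
fragment as core; if that does not decide, the lexicographically smaller
canonical string becomes the substituent — an arbitrary but deterministic
rule.

Size restrictions keep cuts analogue-like: substituent ≤ 13 heavy atoms
and ≤ 33% of the parent's heavy atoms, and the core must contain a ring.
These are the common matched-molecular-pair working values; they are
surfaced in `SizeRules` and in the run config because no single setting
suits every corpus.

Stereocenters adjacent to a cut cannot carry their parent's assignment
unambiguously once a neighbor becomes an attachment point; fragment stereo
is therefore taken as RDKit produces it, and the round-trip guarantee
(weld(core, substituent) = parent) is stated and tested at the
constitution level. In practice centers away from the cut survive intact —
welding compound 3's core to CF3 reproduces compound 4 with full
stereochemistry.

Welding uses RDKit `molzip` on map-matched attachment points. The special
substituent label `[*][H]` denotes the hydrogen-capped parent: single cuts
cannot produce an H substituent, so the unsubstituted parent of a series
is matched explicitly (`hydrogen_parent_match`) and occupies an `H`
column. This is on by default; the validation series' compound 5 occupies
exactly such a cell.

## Matrix construction

Every core is fragmented a second time with the same rules. The piece
*not* carrying the first-stage attachment point is the **hypercore**; the
removed piece (which carries it) plays the substituent role for the size
rules. Cores yielding an identical canonical hypercore become rows of one
matrix; columns are the union of their first-stage substituents. This
keying deliberately places positional isomers — para- and meta-attached
aryl cores strip to the same hypercore — as distinct rows of one matrix,
which is what exposes cross-series core/substituent combinations.

A matrix is kept when it has ≥ 2 rows, ≥ 2 columns, ≥ 3 observed cells and
≥ 2 distinct potency values; below that a local additive fit is degenerate.
Matrix ids are content hashes of (hypercore, rows, columns), so ids are
stable across runs and machines.

One compound may appear in several matrices (one per qualifying
decomposition). It may also appear **twice within one matrix** through the
H column: capping the para- and the meta-attached core with hydrogen gives
the same unsubstituted parent, which then truthfully occupies the H cell
of both rows. Both placements are kept — they are chemically correct,
carry identical potency, and connect the two rows in the observed
bipartite graph (without that link the validation fixture's held-out cell
would have no prediction at all).

## Discontinuity scoring

Two observed cells sharing a row or a column differ by one structural
change. The matrix score is the maximum (and mean) absolute potency gap
over such neighbor pairs; a matrix is flagged when the maximum reaches the
conventional 100-fold cliff criterion (2.0 p-units, configurable). Scores
use observed cells only; predictions never feed back into selection, so
region selection and potency prediction stay independent. Matrices whose
observations share no axis (diagonal-only) score zero. By default the
pipeline reports the flags but still models every matrix; `predict_only_flagged`
restricts modeling to flagged matrices.

## Local Free-Wilson models

Per matrix, p(i, j) = μ + αᵢ + βⱼ is fitted by ordinary least squares to
observed cells, separately on each connected component of the bipartite
row–column graph induced by those cells, with Σα = Σβ = 0 per component
for identifiability. The solver uses the full indicator design and the
minimum-norm least-squares solution, then re-centers to the zero-sum
parameterization; fitted values are invariant to that step. No
regularization is applied by default: matrices are small and dense, and
reproducibility of the classical estimator is worth more here than
variance reduction.

A connected component with r rows, c columns and n observations always
satisfies n ≥ r + c − 1 = number of free parameters, so components are
never under-determined; n = r + c − 1 (a spanning tree) gives a
zero-residual *saturated* fit whose predictions are unchecked
interpolations. Diagnostics report n_obs, parameters, residual degrees of
freedom, RMSE and R² per component and flag saturation. Predictions exist
only within a component; a virtual cell whose row and column lie in
different components gets an explicit "no prediction" (None), never a
number.

On complete grids the estimator reduces to the closed form
row mean + column mean − grand mean; this identity (to 1e-9) and exact
recovery of withheld cells on noise-free additive matrices (to 1e-6) are
enforced in the test suite against independently computed oracles.

## Cliff candidates

For every predicted virtual cell passing the quality gate, every observed
cell in the same row or column with predicted − observed ≥ `delta_min`
yields a candidate. `delta_min` defaults to 1.0 p-unit — one order of
magnitude, the working definition of a cliff worth synthesizing toward.
Candidates sort by delta descending with deterministic tie-breaking
(smaller component RMSE, larger component n_obs, lexicographic ids).

The quality gate replaces case-by-case inspection of compound
environments: a prediction is used when its component has ≥ 4 observations
and residual degrees of freedom, or — with an explicit warning flag — when
the component is saturated but fits its observations exactly (RMSE 0). The
saturated-exact branch keeps small, internally consistent neighborhoods
usable (the validation fixture is one) while marking that their
predictions are unvalidated. Reverse candidates (virtual predicted much
*weaker* than a potent neighbor) are emitted only under a flag; the
default use case is finding more potent analogues.

## Synthetic data

`make_matrix` draws α ~ N(0, 0.5²), β ~ N(0, 0.75²) around μ = 6.5 with
observation noise sd 0.2 — a mid-potency analogue campaign with
substituent effects somewhat stronger than scaffold effects and typical
assay replicate spread. A configured fraction of cells (default 20%) is
withheld as virtual, resampling the layout (bounded retries) until the
observed graph is connected so every withheld cell is predictable.
`make_library` materializes the same surface as molecules: scaffold
templates (by default the para-, meta- and ortho-attached
N-hydroxy-lactam cores of the validation series) welded to a small
substituent pool, potencies emitted as Ki in nM. Generated SMILES are
already canonical, so libraries pass standardization unchanged, and
re-fragmenting a library reconstructs the generating matrix.

**Cliff injection.** An injected cliff raises a chosen virtual cell's
ground truth by `cliff_magnitude` (default 2.0) *via its substituent's
column effect*: the truth of every cell in that column rises, including
the recorded potencies of its observed cells. This is the mechanism by
which real cliffs of this kind are predictable at all — the strong
substituent's contribution is learned from the series where it has been
made and transferred to the series where it has not. The injected cell's
truth minus its pre-injection additive value equals the magnitude exactly.
A second mode (`mode="cell"`) raises only the chosen cell's own truth,
modeling an epistatic, single-compound cliff; such a cliff leaves no trace
in observed data and is *by construction* invisible to additive models —
the package keeps this mode so that limitation is explicit and testable
rather than implicit.

What passing synthetic tests shows — and does not. The generator emulates
additive SAR with Gaussian noise, missingness and substituent-driven
cliffs. It does not emulate censored measurements, batch effects,
non-additive (interaction) SAR beyond the per-cell mode, or the curation
noise of public databases; recovery rates measured on it are upper bounds
for real corpora.

## Determinism and provenance

Every stochastic path takes a seed; identical (inputs, config, seed) give
byte-identical artifacts, which the suite asserts at file level. Run
outputs embed the exact config used and SHA-256 checksums of inputs.
Problem sizes used by the shipped checks (100 molecules for round trips,
50 grids for the closed form, 20 replicates for cliff recovery, 6×8
matrices) keep a full verification run in the order of seconds while
leaving each estimate's sampling error far from the asserted margins.

## Known limitations

- Single-cut decompositions only; analogues differing at two or more
  sites never share a matrix.
- The discontinuity metric is the unweighted neighbor-pair gap;
  similarity-weighted landscape indices are out of scope.
- No uncertainty quantification beyond per-component RMSE/DoF flags; a
  saturated-exact prediction carries no error estimate at all.
- Virtual analogues are proposed on potency alone — no synthesizability,
  selectivity or ADMET filtering.
- Matrices are modeled independently; information is never pooled across
  hypercores, so a substituent's effect must be re-learned in every
  matrix.
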