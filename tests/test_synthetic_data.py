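import dataclasses

import pytest
from rdkit import Chem

from sarmatrix.chem_io import load_compounds, standardize_structure
from sarmatrix.fragmentation import canonical_fragment
from sarmatrix.sarm_builder import build_matrices, build_series_index
from sarmatrix.synthetic_data import (
    DEFAULT_SCAFFOLDS,
    SimConfig,
    SyntheticDataError,
    inject_cliffs,
    make_library,
    make_matrix,
    random_molecules,
)


class TestMakeMatrix:
    def test_noise_free_complete_matrix_equals_truth(self):
        config = SimConfig(noise_sd=0.0, missing_frac=0.0, n_cliffs=0, seed=1)
        matrix, truth = make_matrix(config)
        for r, c, cell in matrix.observed_cells():
            assert cell.p_potency == pytest.approx(truth.truth[(r, c)])
        assert matrix.virtual_cells() == []

    def test_seed_determinism_bit_identical(self):
        config = SimConfig(seed=42)
        m1, t1 = make_matrix(config)
        m2, t2 = make_matrix(config)
        assert m1 == m2
        assert t1 == t2

    def test_observed_graph_connected(self):
        import networkx as nx

        matrix, _ = make_matrix(SimConfig(seed=5, missing_frac=0.3, n_cliffs=0))
        graph = nx.Graph()
        graph.add_nodes_from(("row", r) for r in matrix.rows)
        graph.add_nodes_from(("col", c) for c in matrix.columns)
        for r, c, _ in matrix.observed_cells():
            graph.add_edge(("row", r), ("col", c))
        assert nx.is_connected(graph)

    def test_infeasible_layout_raises(self):
        config = SimConfig(
            n_scaffolds=2, n_substituents=2, missing_frac=0.75, n_cliffs=0, seed=0
        )
        with pytest.raises(SyntheticDataError, match="connected"):
            make_matrix(config)


class TestInjectCliffs:
    def _base(self, seed=0):
        return make_matrix(
            SimConfig(seed=seed, n_cliffs=0, missing_frac=0.25, noise_sd=0.1)
        )

    def test_zero_cliffs_is_identity(self):
        matrix, truth = self._base()
        m2, t2 = inject_cliffs(matrix, truth, 0, 2.0, seed=9)
        assert m2 == matrix and t2 == truth

    def test_injected_truth_exceeds_additive_by_exact_magnitude(self):
        matrix, truth = self._base()
        _, t2 = inject_cliffs(matrix, truth, 2, 2.0, seed=9)
        assert len(t2.injected) == 2
        for cell in t2.injected:
            assert t2.truth[cell] - t2.additive[cell] == pytest.approx(2.0)

    def test_substituent_mode_lifts_observed_column(self):
        matrix, truth = self._base()
        m2, t2 = inject_cliffs(matrix, truth, 1, 2.0, seed=9)
        ((_, col),) = t2.injected
        for r, c, cell in m2.observed_cells():
            orig = matrix.cells[(r, c)].p_potency
            expected = orig + 2.0 if c == col else orig
            assert cell.p_potency == pytest.approx(expected)

    def test_cell_mode_is_invisible_in_observed_data(self):
        matrix, truth = self._base()
        m2, t2 = inject_cliffs(matrix, truth, 1, 2.0, seed=9, mode="cell")
        assert m2 == matrix  # observed data untouched
        (cell,) = t2.injected
        assert t2.truth[cell] - t2.additive[cell] == pytest.approx(2.0)

    def test_injected_cells_disjoint_and_reproducible(self):
        matrix, truth = self._base(seed=3)
        _, a = inject_cliffs(matrix, truth, 3, 2.0, seed=11)
        _, b = inject_cliffs(matrix, truth, 3, 2.0, seed=11)
        assert a.injected == b.injected
        assert len(set(a.injected)) == 3

    def test_too_many_cliffs_rejected(self):
        matrix, truth = self._base()
        n_virtual = len(matrix.virtual_cells())
        with pytest.raises(SyntheticDataError):
            inject_cliffs(matrix, truth, n_virtual + 1, 2.0, seed=0)


class TestMakeLibrary:
    def test_full_grid_yields_distinct_valid_structures(self):
        config = SimConfig(
            n_scaffolds=2, n_substituents=3, missing_frac=0.0, n_cliffs=0, seed=2
        )
        records, truth = make_library(config)
        assert len(records) == 6
        smiles = {r.smiles for r in records}
        assert len(smiles) == 6
        for smi in smiles:
            assert Chem.MolFromSmiles(smi) is not None

    def test_records_are_already_standardized(self):
        records, _ = make_library(SimConfig(n_scaffolds=2, n_substituents=4, seed=3,
                                            missing_frac=0.0, n_cliffs=0))
        for rec in records:
            assert standardize_structure(rec.smiles) == rec.smiles

    def test_seed_determinism(self):
        config = SimConfig(n_scaffolds=3, n_substituents=5, seed=8)
        r1, t1 = make_library(config)
        r2, t2 = make_library(config)
        assert r1 == r2 and t1 == t2

    def test_invalid_template_names_offender(self):
        with pytest.raises(SyntheticDataError, match="CCX"):
            make_library(SimConfig(n_scaffolds=1, n_substituents=2), ["CCX"])

    def test_fragmentation_reconstructs_generating_matrix(self):
        """Rows/columns of the rebuilt matrix match the templates and pool."""
        config = SimConfig(
            n_scaffolds=3, n_substituents=5, missing_frac=0.1, noise_sd=0.0,
            n_cliffs=0, seed=4,
        )
        records, truth = make_library(config)
        compounds = load_compounds(records)
        matrices = build_matrices(build_series_index(compounds))
        expected_rows = {
            canonical_fragment(Chem.MolFromSmiles(t)) for t in truth.scaffolds
        }
        expected_cols = {
            canonical_fragment(Chem.MolFromSmiles(s)) for s in truth.substituents
        }
        match = [
            m
            for m in matrices
            if set(m.rows) == expected_rows and expected_cols <= set(m.columns)
        ]
        assert len(match) == 1

    def test_withheld_cells_reappear_virtual(self):
        config = SimConfig(
            n_scaffolds=3, n_substituents=5, missing_frac=0.15, noise_sd=0.0,
            n_cliffs=0, seed=6,
        )
        records, truth = make_library(config)
        compounds = load_compounds(records)
        matrices = build_matrices(build_series_index(compounds))
        virtual = {
            (r, c) for m in matrices for r, c in m.virtual_cells()
        }
        for sc, su in truth.withheld:
            key = (
                canonical_fragment(Chem.MolFromSmiles(sc)),
                canonical_fragment(Chem.MolFromSmiles(su)),
            )
            assert key in virtual


class TestRandomMolecules:
    def test_distinct_valid_and_deterministic(self):
        mols = random_molecules(50, seed=1)
        assert len(mols) == len(set(mols)) == 50
        assert mols == random_molecules(50, seed=1)
        for smi in mols:
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            assert all(a.GetAtomicNum() > 0 for a in mol.GetAtoms())
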