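import pytest

from sarmatrix.chem_io import ActivityRecord, load_compounds, standardize_structure
from sarmatrix.fragmentation import (
    H_SUBSTITUENT,
    canonical_fragment,
    fragment_from_smiles,
    reassemble,
)
from sarmatrix.sarm_builder import (
    BuilderError,
    MatrixMinima,
    build_matrices,
    build_series_index,
    enumerate_virtual_cells,
    hypercore_cuts,
    matrices_to_csv,
    matrices_to_json,
)

LACTAM_PARA = "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccc([*])cc2)C1=O"
LACTAM_META = "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2cccc([*])c2)C1=O"


def _records(entries):
    return [
        ActivityRecord(cid, smi, value, "nM", "Ki", "=")
        for cid, smi, value in entries
    ]


def _library(scaffolds, subs, potencies_nm, skip=()):
    entries = []
    k = 0
    for i, sc in enumerate(scaffolds):
        for j, su in enumerate(subs):
            if (i, j) in skip:
                continue
            entries.append((f"L{k}", reassemble(sc, su), potencies_nm[i][j]))
            k += 1
    return load_compounds(_records(entries))


class TestSeriesIndex:
    def test_shared_core_collects_substituents(self):
        comps = load_compounds(
            _records([("tol", "Cc1ccccc1", 100), ("etb", "CCc1ccccc1", 200)])
        )
        index = build_series_index(comps)
        subs = {sub for sub, _, _ in index.series("*c1ccccc1")}
        assert {"*C", "*CC"} <= subs

    def test_single_compound_has_no_multi_substituent_core(self):
        comps = load_compounds(_records([("tol", "Cc1ccccc1", 100)]))
        index = build_series_index(comps)
        assert all(len(index.series(core)) == 1 for core in index.cores)

    def test_fixture_para_core_carries_phenyl_and_cf3(self, mmp1_records):
        comps = load_compounds(mmp1_records)
        index = build_series_index(comps)
        para_cores = [
            core
            for core in index.cores
            if {"*C(F)(F)F", "*c1ccccc1"}
            <= {sub for sub, _, _ in index.series(core)}
        ]
        assert len(para_cores) == 1

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(BuilderError):
            build_series_index([])
        mixed = load_compounds(
            [
                ActivityRecord("a", "Cc1ccccc1", 100, "nM", "Ki", "="),
                ActivityRecord("b", "CCc1ccccc1", 100, "nM", "IC50", "="),
            ]
        )
        with pytest.raises(BuilderError, match="mixed potency types"):
            build_series_index(mixed)


class TestHypercoreCuts:
    def test_para_and_meta_cores_share_lactam_hypercore(self):
        para = canonical_fragment(fragment_from_smiles(LACTAM_PARA))
        meta = canonical_fragment(fragment_from_smiles(LACTAM_META))
        shared = set(hypercore_cuts(para)) & set(hypercore_cuts(meta))
        assert any("C1=O" in h or "C(=O)" in h for h in shared)
        assert len(shared) == 1


class TestBuildMatrices:
    def test_complete_grid(self):
        comps = _library(
            [LACTAM_PARA, LACTAM_META],
            ["[*]C", "[*]CC"],
            [[100, 300], [1000, 40]],
        )
        matrices = build_matrices(build_series_index(comps))
        (matrix,) = [m for m in matrices if len(m.rows) == 2 and m.n_observed == 4]
        assert enumerate_virtual_cells(matrix) == []

    def test_one_missing_compound_becomes_virtual(self):
        comps = _library(
            [LACTAM_PARA, LACTAM_META],
            ["[*]C", "[*]CC"],
            [[100, 300], [1000, 40]],
            skip={(1, 1)},
        )
        matrices = build_matrices(build_series_index(comps))
        (matrix,) = [m for m in matrices if len(m.rows) == 2 and len(m.columns) == 2]
        assert matrix.n_observed == 3
        assert len(enumerate_virtual_cells(matrix)) == 1

    def test_fixture_reconstructs_heldout_compound_cell(
        self, mmp1_compounds_holdout4, mmp1_smiles
    ):
        """Holding out compound 4, its grid cell reappears as a virtual analogue."""
        index = build_series_index(mmp1_compounds_holdout4)
        matrices = build_matrices(index)
        assert len(matrices) == 1
        matrix = matrices[0]
        assert len(matrix.rows) == 2  # para- and meta-attached cores
        assert H_SUBSTITUENT in matrix.columns
        assert "*C(F)(F)F" in matrix.columns and "*c1ccccc1" in matrix.columns
        target = standardize_structure(mmp1_smiles["4"])
        welded = {
            (r, c): reassemble(r, c) for r, c in enumerate_virtual_cells(matrix)
        }
        assert target in welded.values()

    def test_observed_cells_roundtrip_to_their_compounds(self, mmp1_compounds_holdout4):
        index = build_series_index(mmp1_compounds_holdout4)
        (matrix,) = build_matrices(index)
        by_id = {c.compound_id: c for c in mmp1_compounds_holdout4}
        for r, c, cell in matrix.observed_cells():
            assert reassemble(r, c) == by_id[cell.compound_id].canonical_smiles

    def test_minima_discard_thin_matrices(self):
        comps = _library(
            [LACTAM_PARA, LACTAM_META],
            ["[*]C", "[*]CC"],
            [[100, 300], [1000, 40]],
        )
        index = build_series_index(comps)
        strict = build_matrices(index, minima=MatrixMinima(min_observed=5))
        assert all(m.n_observed >= 5 for m in strict)

    def test_h_match_toggle(self, mmp1_compounds_holdout4):
        index = build_series_index(mmp1_compounds_holdout4)
        without_h = build_matrices(index, h_match=False)
        # compound 5 only enters via the H column; without it the grid is too sparse
        assert all(H_SUBSTITUENT not in m.columns for m in without_h)

    def test_serialization(self, tmp_path, mmp1_compounds_holdout4):
        import json

        import pandas as pd

        matrices = build_matrices(build_series_index(mmp1_compounds_holdout4))
        matrices_to_json(matrices, tmp_path / "m.json")
        matrices_to_csv(matrices, tmp_path / "m.csv")
        payload = json.loads((tmp_path / "m.json").read_text())
        assert payload[0]["matrix_id"] == matrices[0].matrix_id
        df = pd.read_csv(tmp_path / "m.csv")
        assert len(df) == len(matrices[0].rows) * len(matrices[0].columns)

    def test_matrix_ids_stable_across_runs(self, mmp1_compounds_holdout4):
        ids1 = [m.matrix_id for m in build_matrices(build_series_index(mmp1_compounds_holdout4))]
        ids2 = [m.matrix_id for m in build_matrices(build_series_index(mmp1_compounds_holdout4))]
        assert ids1 == ids2
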