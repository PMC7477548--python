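import pytest

from sarmatrix.chem_io import load_compounds
from sarmatrix.datasets import MMP1_SMILES, mmp1_activity_records
from sarmatrix.sarm_builder import OBSERVED, VIRTUAL, Cell, SARMatrix


def grid_matrix(values: dict, rows, cols, matrix_id="m") -> SARMatrix:
    """Build a SARMatrix from {(row, col): potency-or-None} (None = virtual)."""
    cells = {}
    for r in rows:
        for c in cols:
            p = values.get((r, c))
            if p is None:
                cells[(r, c)] = Cell(VIRTUAL)
            else:
                cells[(r, c)] = Cell(OBSERVED, compound_id=f"{r}-{c}", p_potency=float(p))
    return SARMatrix(matrix_id, "hypercore", list(rows), list(cols), cells)


@pytest.fixture
def mmp1_records():
    return mmp1_activity_records()


@pytest.fixture
def mmp1_compounds_holdout4():
    """The validation series as curated compounds, with compound 4 held out."""
    return load_compounds(mmp1_activity_records(exclude=("4",)))


@pytest.fixture
def mmp1_smiles():
    return MMP1_SMILES


@pytest.fixture
def three_obs_2x2():
    """2x2 with observed 6.0/7.0/8.0 and one virtual cell at (r2, c2)."""
    return grid_matrix(
        {("r1", "c1"): 6.0, ("r1", "c2"): 7.0, ("r2", "c1"): 8.0},
        ["r1", "r2"],
        ["c1", "c2"],
    )
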