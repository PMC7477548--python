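"""Organization of core/substituent decompositions into SAR matrices.

A SAR matrix groups structurally related analogue series: rows are cores
that share an identical second-stage core (the *hypercore*, obtained by
fragmenting each core once more with the same cut rules), columns are the
union of the substituents seen on those cores. Grid positions where a
compound exists are *observed* cells; the remaining combinations are
*virtual* analogues — real, synthesizable structures obtained by welding a
row's core onto a column's substituent, just not yet made.

Keying rows by the hypercore places positional isomers (e.g. para- versus
meta-substituted aryl cores) as distinct rows of one matrix, which is what
exposes novel core/substituent combinations across series.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .chem_io import Compound
from .fragmentation import (
    H_SUBSTITUENT,
    SizeRules,
    _heavy_atoms,
    _has_ring,
    _cuttable_bonds,
    canonical_fragment,
    enumerate_cuts,
    fragment_from_smiles,
    hydrogen_parent_match,
)

OBSERVED = "observed"
VIRTUAL = "virtual"

_STAGE1_MARK = 99  # isotope label marking the first-stage attachment point


class BuilderError(ValueError):
    """Raised for unusable inputs to index or matrix construction."""


@dataclass
class SeriesIndex:
    """Index of all (core, substituent) decompositions of a compound set."""

    entries: dict  # core -> {substituent -> (compound_id, p_potency)}
    compounds: dict  # canonical_smiles -> Compound

    def series(self, core: str) -> list[tuple[str, str, float]]:
        """All (substituent, compound_id, p_potency) entries for one core."""
        return [
            (sub, cid, p) for sub, (cid, p) in sorted(self.entries.get(core, {}).items())
        ]

    @property
    def cores(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class Cell:
    """One grid position of a SAR matrix."""

    status: str
    compound_id: Optional[str] = None
    p_potency: Optional[float] = None
    predicted_p: Optional[float] = None


@dataclass(frozen=True)
class MatrixMinima:
    """Minimum content for a matrix to be usable for local modeling."""

    min_rows: int = 2
    min_columns: int = 2
    min_observed: int = 3
    min_distinct_potencies: int = 2


@dataclass
class SARMatrix:
    """A core × substituent grid of observed and virtual cells."""

    matrix_id: str
    hypercore: str
    rows: list
    columns: list
    cells: dict  # (row, col) -> Cell

    def observed_cells(self) -> list[tuple[str, str, Cell]]:
        return [
            (r, c, self.cells[(r, c)])
            for r in self.rows
            for c in self.columns
            if self.cells[(r, c)].status == OBSERVED
        ]

    def virtual_cells(self) -> list[tuple[str, str]]:
        return [
            (r, c)
            for r in self.rows
            for c in self.columns
            if self.cells[(r, c)].status == VIRTUAL
        ]

    @property
    def n_observed(self) -> int:
        return len(self.observed_cells())


def build_series_index(
    compounds: Sequence[Compound], rules: SizeRules | None = None
) -> SeriesIndex:
    """Fragment every compound and index decompositions by core.

    All compounds must share one potency type; mixing pKi- and pIC50-derived
    compounds in one matrix would compare incomparable scales.
    """
    if not compounds:
        raise BuilderError("empty compound set")
    ptypes = {c.potency_type for c in compounds}
    if len(ptypes) > 1:
        raise BuilderError(
            f"mixed potency types {sorted(ptypes)}: split the compound set "
            "by potency type before building matrices"
        )
    rules = rules or SizeRules()
    entries: dict = {}
    by_smiles: dict = {}
    for comp in compounds:
        by_smiles[comp.canonical_smiles] = comp
        for pair in enumerate_cuts(comp, rules):
            entries.setdefault(pair.core, {})[pair.substituent] = (
                comp.compound_id,
                comp.p_potency,
            )
    return SeriesIndex(entries=entries, compounds=by_smiles)


def hypercore_cuts(core: str, rules: SizeRules | None = None) -> list[str]:
    """Second-stage cuts of a core: canonical hypercores it can be keyed by.

    The core (one attachment point) is cut once more at each acyclic single
    bond; the piece *not* carrying the first-stage attachment point is the
    hypercore candidate. The same size restrictions apply, with the removed
    piece playing the substituent role.
    """
    rules = rules or SizeRules()
    mol = fragment_from_smiles(core)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(_STAGE1_MARK)
    core_heavy = _heavy_atoms(mol)

    hypercores: set[str] = set()
    for bond_idx in _cuttable_bonds(mol):
        frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:  # pragma: no cover
            continue

        def has_stage1(m: Chem.Mol) -> bool:
            return any(
                a.GetAtomicNum() == 0 and a.GetIsotope() == _STAGE1_MARK
                for a in m.GetAtoms()
            )

        hyper = next((p for p in pieces if not has_stage1(p)), None)
        removed = next((p for p in pieces if has_stage1(p)), None)
        if hyper is None or removed is None:
            continue
        n_removed = _heavy_atoms(removed)
        if n_removed > rules.max_sub_heavy_atoms:
            continue
        if n_removed > rules.max_sub_fraction * core_heavy:
            continue
        if rules.core_must_contain_ring and not _has_ring(hyper):
            continue
        hypercores.add(canonical_fragment(hyper))
    return sorted(hypercores)


def _matrix_id(hypercore: str, rows: Sequence[str], columns: Sequence[str]) -> str:
    digest = hashlib.sha1(
        "|".join([hypercore, *sorted(rows), *sorted(columns)]).encode()
    ).hexdigest()
    return digest[:12]


def build_matrices(
    index: SeriesIndex,
    rules: SizeRules | None = None,
    minima: MatrixMinima | None = None,
    h_match: bool = True,
) -> list[SARMatrix]:
    """Group cores by shared hypercore into SAR matrices.

    Cores whose second-stage fragmentation yields an identical canonical
    hypercore become rows of one matrix; columns are the union of their
    first-stage substituents (plus an ``[*][H]`` column for rows whose
    hydrogen-capped parent exists in the compound set, when ``h_match`` is
    on). Matrices failing the content minima are discarded. Output order and
    matrix ids are deterministic.
    """
    if not index.entries:
        raise BuilderError("empty series index")
    rules = rules or SizeRules()
    minima = minima or MatrixMinima()

    groups: dict[str, set[str]] = {}
    for core in index.cores:
        for hyper in hypercore_cuts(core, rules):
            groups.setdefault(hyper, set()).add(core)

    compounds = list(index.compounds.values())
    matrices: list[SARMatrix] = []
    for hyper in sorted(groups):
        rows = sorted(groups[hyper])
        if len(rows) < minima.min_rows:
            continue
        columns = sorted({sub for row in rows for sub, _, _ in index.series(row)})

        h_parents: dict[str, Compound] = {}
        if h_match:
            for row in rows:
                parent = hydrogen_parent_match(row, compounds)
                if parent is not None:
                    h_parents[row] = parent
            if h_parents and H_SUBSTITUENT not in columns:
                columns = sorted(columns + [H_SUBSTITUENT])
        if len(columns) < minima.min_columns:
            continue

        cells: dict = {}
        for row in rows:
            observed_subs = dict(index.entries.get(row, {}))
            for col in columns:
                if col == H_SUBSTITUENT and row in h_parents:
                    parent = h_parents[row]
                    cells[(row, col)] = Cell(OBSERVED, parent.compound_id, parent.p_potency)
                elif col in observed_subs:
                    cid, p = observed_subs[col]
                    cells[(row, col)] = Cell(OBSERVED, cid, p)
                else:
                    cells[(row, col)] = Cell(VIRTUAL)

        matrix = SARMatrix(
            matrix_id=_matrix_id(hyper, rows, columns),
            hypercore=hyper,
            rows=rows,
            columns=columns,
            cells=cells,
        )
        observed = matrix.observed_cells()
        if len(observed) < minima.min_observed:
            continue
        distinct = {round(c.p_potency, 9) for _, _, c in observed}
        if len(distinct) < minima.min_distinct_potencies:
            continue
        matrices.append(matrix)
    return matrices


def enumerate_virtual_cells(matrix: SARMatrix) -> list[tuple[str, str]]:
    """All (row, column) positions with no existing compound, in grid order."""
    return matrix.virtual_cells()


# ---------------------------------------------------------------------------
# serialization


def matrix_to_dict(matrix: SARMatrix) -> dict:
    return {
        "matrix_id": matrix.matrix_id,
        "hypercore": matrix.hypercore,
        "rows": list(matrix.rows),
        "columns": list(matrix.columns),
        "cells": [
            {
                "row": r,
                "column": c,
                "status": cell.status,
                "compound_id": cell.compound_id,
                "p_potency": cell.p_potency,
                "predicted_p": cell.predicted_p,
            }
            for (r, c), cell in sorted(matrix.cells.items())
        ],
    }


def matrices_to_json(matrices: Iterable[SARMatrix], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([matrix_to_dict(m) for m in matrices], indent=2, sort_keys=True)
    )


def matrices_to_csv(matrices: Iterable[SARMatrix], path: str | Path) -> None:
    """Flat one-line-per-cell view for inspection."""
    rows = []
    for m in matrices:
        for cell_rec in matrix_to_dict(m)["cells"]:
            rows.append({"matrix_id": m.matrix_id, "hypercore": m.hypercore, **cell_rec})
    columns = [
        "matrix_id", "hypercore", "row", "column", "status",
        "compound_id", "p_potency", "predicted_p",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
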