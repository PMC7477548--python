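"""Single-cut matched-molecular-pair fragmentation and fragment welding.

Compounds are decomposed by systematically cleaving each acyclic single
bond between two heavy atoms — the established single-cut convention for
matched molecular pairs. Each cut yields a *core* (the larger fragment,
normally carrying the scaffold) and a *substituent* (the smaller), both
written as SMILES with one ``[*]`` attachment point. Size restrictions keep
the substituent small relative to the parent so that rows and columns of a
SAR matrix correspond to chemically meaningful analogue relationships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chem_io import Compound, standardize_structure

#: Column label used for the unsubstituted (hydrogen-capped) parent.
H_SUBSTITUENT = "[*][H]"


class FragmentError(ValueError):
    """Raised for invalid fragments (wrong attachment-point count, bad SMILES)."""


@dataclass(frozen=True)
class SizeRules:
    """Size restrictions applied to candidate cuts.

    A cut is kept only if the substituent has at most ``max_sub_heavy_atoms``
    heavy atoms and at most ``max_sub_fraction`` of the parent's heavy atoms,
    and (optionally) the core contains at least one ring.
    """

    max_sub_heavy_atoms: int = 13
    max_sub_fraction: float = 0.33
    core_must_contain_ring: bool = True


@dataclass(frozen=True)
class CorePair:
    """One single-cut decomposition of a parent compound."""

    parent_id: str
    core: str
    substituent: str
    core_heavy_atoms: int
    sub_heavy_atoms: int


def _heavy_atoms(mol: Chem.Mol) -> int:
    """Heavy-atom count excluding attachment-point dummies."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _has_ring(mol: Chem.Mol) -> bool:
    return mol.GetRingInfo().NumRings() > 0


def _n_dummies(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def canonical_fragment(mol: Chem.Mol) -> str:
    """Canonical SMILES of a fragment with bare ``[*]`` attachment points."""
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def fragment_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a fragment SMILES, requiring exactly one attachment point."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentError(f"unparseable fragment SMILES {smiles!r}")
    n = _n_dummies(mol)
    if n != 1:
        raise FragmentError(
            f"fragment {smiles!r} has {n} attachment points, expected exactly 1"
        )
    return mol


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of acyclic single bonds between two heavy non-dummy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _split_on_bond(mol: Chem.Mol, bond_idx: int) -> tuple[Chem.Mol, Chem.Mol]:
    frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - single acyclic cut always splits in two
        raise FragmentError("single cut did not produce two fragments")
    return pieces[0], pieces[1]


def _assign_core_sub(a: Chem.Mol, b: Chem.Mol) -> tuple[Chem.Mol, Chem.Mol]:
    """Decide which fragment is the core (larger; ties broken deterministically)."""
    ha, hb = _heavy_atoms(a), _heavy_atoms(b)
    if ha != hb:
        return (a, b) if ha > hb else (b, a)
    ra, rb = _has_ring(a), _has_ring(b)
    if ra != rb:
        return (a, b) if ra else (b, a)
    # lexicographically smaller canonical string is the substituent
    sa, sb = canonical_fragment(a), canonical_fragment(b)
    return (a, b) if sa >= sb else (b, a)


def enumerate_cuts(
    compound: Compound | str, rules: SizeRules | None = None
) -> list[CorePair]:
    """Enumerate all size-admissible single-cut core/substituent pairs.

    Accepts a :class:`~sarmatrix.chem_io.Compound` or a SMILES string.
    Returns a deterministic, duplicate-free list sorted by canonical
    fragment strings. A molecule with no cuttable bond yields ``[]``.
    """
    rules = rules or SizeRules()
    if isinstance(compound, Compound):
        smiles, parent_id = compound.canonical_smiles, compound.compound_id
    else:
        smiles, parent_id = standardize_structure(compound), ""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentError(f"unparseable SMILES {smiles!r}")
    parent_heavy = _heavy_atoms(mol)

    pairs: set[CorePair] = set()
    for bond_idx in _cuttable_bonds(mol):
        a, b = _split_on_bond(mol, bond_idx)
        core, sub = _assign_core_sub(a, b)
        n_core, n_sub = _heavy_atoms(core), _heavy_atoms(sub)
        if n_sub > rules.max_sub_heavy_atoms:
            continue
        if n_sub > rules.max_sub_fraction * parent_heavy:
            continue
        if rules.core_must_contain_ring and not _has_ring(core):
            continue
        pairs.add(
            CorePair(
                parent_id=parent_id,
                core=canonical_fragment(core),
                substituent=canonical_fragment(sub),
                core_heavy_atoms=n_core,
                sub_heavy_atoms=n_sub,
            )
        )
    return sorted(pairs, key=lambda p: (p.core, p.substituent))


def reassemble(core: str, substituent: str) -> str:
    """Weld two one-attachment-point fragments into a standardized molecule.

    The attachment points are joined by a single bond; ``[*][H]`` as the
    substituent caps the core with hydrogen. Inverse of
    :func:`enumerate_cuts` at the constitution level.
    """
    if substituent == H_SUBSTITUENT:
        return cap_with_hydrogen(core)
    core_mol = fragment_from_smiles(core)
    sub_mol = fragment_from_smiles(substituent)
    for mol in (core_mol, sub_mol):
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(1)
    welded = Chem.molzip(core_mol, sub_mol)
    Chem.SanitizeMol(welded)
    return standardize_structure(Chem.MolToSmiles(welded))


def cap_with_hydrogen(core: str) -> str:
    """Replace a fragment's attachment point with hydrogen."""
    mol = fragment_from_smiles(core)
    editable = Chem.RWMol(mol)
    for atom in editable.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    capped = editable.GetMol()
    Chem.SanitizeMol(capped)
    capped = Chem.RemoveHs(capped)
    return standardize_structure(Chem.MolToSmiles(capped))


def hydrogen_parent_match(
    core: str, compounds: Iterable[Compound]
) -> Optional[Compound]:
    """Find the compound equal to the core capped with hydrogen, if any.

    Lets the unsubstituted parent of an analogue series occupy the ``H``
    column of a SAR matrix (single cuts can never produce an H substituent
    directly).
    """
    capped = cap_with_hydrogen(core)
    for comp in compounds:
        if comp.canonical_smiles == capped:
            return comp
    return None


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereo descriptors removed (constitution only)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentError(f"unparseable SMILES {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)
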