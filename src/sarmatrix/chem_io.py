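"""Reading, standardization, and aggregation of compound-activity records.

Activity values (Ki or IC50) arrive in concentration units (nM, µM, M) and
are converted to the negative-log molar scale (pKi / pIC50) so that potency
differences are additive and an "order of magnitude" is one unit.
Replicate measurements of the same standardized structure are aggregated
(median by default); qualified measurements (relation ``<`` or ``>``) are
excluded unless explicitly requested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean, median
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Conversion factors to mol/L.
UNIT_FACTORS = {
    "nM": 1e-9,
    "uM": 1e-6,
    "µM": 1e-6,
    "M": 1.0,
}

ACTIVITY_TYPES = ("Ki", "IC50")
RELATIONS = ("=", "<", ">", "<=", ">=")

#: Map from measured activity type to the p-scale potency label.
POTENCY_TYPES = {"Ki": "pKi", "IC50": "pIC50"}


class ChemIOError(ValueError):
    """Raised for invalid activity records or unusable inputs."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity measurement for one compound."""

    compound_id: str
    smiles: str
    value: float
    unit: str
    activity_type: str
    relation: str = "="

    def __post_init__(self) -> None:
        if not (self.value > 0) or not math.isfinite(self.value):
            raise ChemIOError(
                f"record {self.compound_id!r}: activity value must be a "
                f"positive finite number, got {self.value!r}"
            )
        if self.unit not in UNIT_FACTORS:
            raise ChemIOError(
                f"record {self.compound_id!r}: unknown unit {self.unit!r} "
                f"(expected one of {sorted(set(UNIT_FACTORS))})"
            )
        if self.activity_type not in ACTIVITY_TYPES:
            raise ChemIOError(
                f"record {self.compound_id!r}: unknown activity type "
                f"{self.activity_type!r} (expected one of {ACTIVITY_TYPES})"
            )
        if self.relation not in RELATIONS:
            raise ChemIOError(
                f"record {self.compound_id!r}: unknown relation "
                f"{self.relation!r} (expected one of {RELATIONS})"
            )

    @property
    def is_exact(self) -> bool:
        return self.relation == "="


@dataclass(frozen=True)
class Compound:
    """A standardized structure with an aggregated p-scale potency."""

    compound_id: str
    canonical_smiles: str
    p_potency: float
    potency_type: str
    n_measurements: int = 1


def to_p_potency(value: float, unit: str) -> float:
    """Convert a concentration-type activity value to -log10(molar).

    Examples
    --------
    >>> to_p_potency(1000, "nM")
    6.0
    """
    if unit not in UNIT_FACTORS:
        raise ChemIOError(
            f"unknown unit {unit!r} (expected one of {sorted(set(UNIT_FACTORS))})"
        )
    if not (value > 0) or not math.isfinite(value):
        raise ChemIOError(f"activity value must be positive and finite, got {value!r}")
    return -math.log10(value * UNIT_FACTORS[unit])


def standardize_structure(smiles: str, record_id: str | None = None) -> str:
    """Canonicalize a SMILES, keeping the largest organic fragment.

    Stereo descriptors are preserved. Idempotent: applying the function to
    its own output returns the same string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" (record {record_id!r})" if record_id else ""
        raise ChemIOError(f"unparseable SMILES {smiles!r}{where}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        # salt / solvate stripping: keep the fragment with most heavy atoms,
        # preferring carbon-containing (organic) fragments
        def key(f: Chem.Mol) -> tuple:
            has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
            return (has_c, f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))

        mol = max(frags, key=key)
    return Chem.MolToSmiles(mol)


def load_compounds(
    records: Sequence[ActivityRecord],
    aggregation: str = "median",
    include_nonexact: bool = False,
) -> list[Compound]:
    """Standardize, filter, and aggregate activity records into compounds.

    Records with a qualified relation (``<``, ``>``, ...) are dropped unless
    ``include_nonexact`` is set. Replicates of the same standardized
    structure and activity type are aggregated on the p-scale. Structures
    measured with different activity types yield separate compounds and are
    never merged (a pKi and a pIC50 are not comparable).
    """
    if not records:
        raise ChemIOError("no activity records supplied")
    if aggregation not in ("median", "mean"):
        raise ChemIOError(f"unknown aggregation {aggregation!r}")
    agg = median if aggregation == "median" else mean

    groups: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rec in records:
        if not rec.is_exact and not include_nonexact:
            continue
        smi = standardize_structure(rec.smiles, rec.compound_id)
        groups.setdefault((smi, rec.activity_type), []).append(
            (rec.compound_id, to_p_potency(rec.value, rec.unit))
        )
    if not groups:
        raise ChemIOError(
            "no usable records: all measurements were excluded "
            "(qualified relations are dropped by default)"
        )

    compounds = []
    for (smi, atype), entries in sorted(groups.items()):
        ids = sorted({cid for cid, _ in entries})
        pvals = [p for _, p in entries]
        compounds.append(
            Compound(
                compound_id=ids[0],
                canonical_smiles=smi,
                p_potency=float(agg(pvals)),
                potency_type=POTENCY_TYPES[atype],
                n_measurements=len(pvals),
            )
        )
    return compounds


# ---------------------------------------------------------------------------
# tabular I/O

CSV_COLUMNS = ["compound_id", "smiles", "value", "unit", "type", "relation"]


def read_activity_csv(path: str | Path, sep: str | None = None) -> list[ActivityRecord]:
    """Read activity records from a delimited text file.

    The header must contain ``compound_id, smiles, value, unit, type`` and
    optionally ``relation`` (defaulting to ``=``). The delimiter is sniffed
    unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ChemIOError(f"{path}: missing required columns {missing}")
    if "relation" not in df.columns:
        df["relation"] = "="
    df["relation"] = df["relation"].fillna("=")
    return [
        ActivityRecord(
            compound_id=str(row.compound_id),
            smiles=str(row.smiles),
            value=float(row.value),
            unit=str(row.unit).strip(),
            activity_type=str(row.type).strip(),
            relation=str(row.relation).strip(),
        )
        for row in df.itertuples(index=False)
    ]


def write_compound_table(
    compounds: Iterable[Compound], path: str | Path, manifest_path: str | Path | None = None
) -> None:
    """Write the canonical compound table (CSV) and an optional JSON manifest."""
    rows = [
        {
            "compound_id": c.compound_id,
            "canonical_smiles": c.canonical_smiles,
            "p_potency": c.p_potency,
            "potency_type": c.potency_type,
            "n_measurements": c.n_measurements,
        }
        for c in compounds
    ]
    pd.DataFrame(rows, columns=list(rows[0]) if rows else None).to_csv(path, index=False)
    if manifest_path is not None:
        manifest = {
            "n_compounds": len(rows),
            "potency_types": sorted({r["potency_type"] for r in rows}),
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
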