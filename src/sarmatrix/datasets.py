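"""Built-in validation data: the MMP-1 N-hydroxy-lactam inhibitor series.

Six synthesized compounds with measured MMP-1 IC50 values form a compact,
fully specified test bed for the whole pipeline. Structures were
transcribed from their IUPAC names; CIP assignments were verified with
RDKit. Compounds 3 and 4 are the (R,S) diastereomers (propanamide CH,
lactam quaternary carbon); 3' and 4' are the inactive (R,R) diastereomers,
reported only as IC50 > 100 µM (qualified records, excluded from modeling
by default).

The series encodes a textbook activity-cliff constellation: 3 (biphenyl,
11.5 µM) vs 4 (para-CF3, 0.18 µM) — a ~60-fold potency gap from a single
substituent swap — with 5 (unsubstituted phenyl) and 6 (meta-CF3) as
positional/steric controls. Holding compound 4 out reconstructs the
discovery situation: its grid cell reappears as a virtual analogue whose
welded structure is exactly compound 4.
"""

from __future__ import annotations

from .chem_io import ActivityRecord

#: Name-derived structures, (R,S) unless noted.
MMP1_SMILES = {
    "3": "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccc(-c3ccccc3)cc2)C1=O",
    "3'": "ONC(=O)[C@@H](C)N1CC[C@](C)(c2ccc(-c3ccccc3)cc2)C1=O",
    "4": "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccc(C(F)(F)F)cc2)C1=O",
    "4'": "ONC(=O)[C@@H](C)N1CC[C@](C)(c2ccc(C(F)(F)F)cc2)C1=O",
    "5": "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccccc2)C1=O",
    "6": "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2cccc(C(F)(F)F)c2)C1=O",
}

#: Measured MMP-1 IC50 values in µM; (value, relation).
MMP1_IC50_UM = {
    "3": (11.5, "="),
    "4": (0.18, "="),
    "5": (1.54, "="),
    "6": (11.1, "="),
    "3'": (100.0, ">"),
    "4'": (100.0, ">"),
}


def mmp1_activity_records(exclude: tuple[str, ...] = ()) -> list[ActivityRecord]:
    """Activity records for the MMP-1 validation series.

    ``exclude`` drops compounds by id — e.g. ``exclude=("4",)`` recreates
    the pre-synthesis situation in which compound 4 is still virtual.
    """
    records = []
    for cid, smiles in MMP1_SMILES.items():
        if cid in exclude:
            continue
        value, relation = MMP1_IC50_UM[cid]
        records.append(
            ActivityRecord(
                compound_id=cid,
                smiles=smiles,
                value=value,
                unit="µM",
                activity_type="IC50",
                relation=relation,
            )
        )
    return records
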