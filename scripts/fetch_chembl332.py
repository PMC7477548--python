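#!/usr/bin/env python
"""Optional helper: download Ki activities for ChEMBL target CHEMBL332 (MMP-1).

Writes data/chembl332_ki.csv in the dialect read by sarmatrix.chem_io. The
core package and its tests never require this download; the file only
enables the optional full-data integration test and analyses on the real
inhibitor corpus. Requires network access and the `chembl_webresource_client`
package OR plain HTTPS access to the ChEMBL REST API (used here via urllib).

Equivalent query: activities with target_chembl_id=CHEMBL332,
standard_type=Ki, standard_units=nM, with canonical SMILES joined from the
molecule endpoint.
"""

from __future__ import annotations

import csv
import json
import sys
import urllib.parse
import urllib.request
from pathlib import Path

BASE = "https://www.ebi.ac.uk/chembl/api/data/activity.json"


def fetch(limit: int = 1000) -> list[dict]:
    rows = []
    offset = 0
    while True:
        query = urllib.parse.urlencode(
            {
                "target_chembl_id": "CHEMBL332",
                "standard_type": "Ki",
                "limit": limit,
                "offset": offset,
            }
        )
        with urllib.request.urlopen(f"{BASE}?{query}", timeout=60) as resp:
            payload = json.load(resp)
        for act in payload["activities"]:
            smiles = act.get("canonical_smiles")
            value = act.get("standard_value")
            units = act.get("standard_units")
            if not smiles or value is None or units != "nM":
                continue
            rows.append(
                {
                    "compound_id": act["molecule_chembl_id"],
                    "smiles": smiles,
                    "value": value,
                    "unit": "nM",
                    "type": "Ki",
                    "relation": act.get("standard_relation") or "=",
                }
            )
        if payload["page_meta"]["next"] is None:
            break
        offset += limit
    return rows


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "data" / "chembl332_ki.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    rows = fetch()
    if not rows:
        sys.exit("no activities retrieved")
    with open(out, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["compound_id", "smiles", "value", "unit", "type", "relation"]
        )
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {len(rows)} records to {out}")


if __name__ == "__main__":
    main()
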