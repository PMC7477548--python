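"""Enumeration and ranking of predicted activity-cliff candidates.

An activity-cliff candidate pairs a weakly potent *observed* compound with
a *virtual* analogue in the same matrix row or column whose Free-Wilson
prediction is higher by at least ``delta_min`` p-units (default 1.0, i.e.
one order of magnitude). Sharing a row or column means the two structures
differ by a single substituent or core swap — the matched-pair relationship
that makes the potency gap a cliff rather than a scaffold hop.

A quality gate replaces manual inspection of compound environments:
predictions are accepted from components with enough observations and
residual degrees of freedom, or from saturated components only when the
fit is exact (zero residual), with a warning flag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .fragmentation import reassemble
from .freewilson import FreeWilsonModel, predict_cell
from .sarm_builder import SARMatrix

SAME_ROW = "same_row"
SAME_COL = "same_col"

#: One order of magnitude on the p-scale.
DEFAULT_DELTA_MIN = 1.0


@dataclass(frozen=True)
class QualityGate:
    """Acceptance rule for using a component's predictions."""

    min_component_obs: int = 4
    accept_saturated_exact: bool = True
    exact_rmse_tol: float = 1e-9

    def passes(self, comp) -> tuple[bool, bool]:
        """(accepted, warning): warning marks saturated-but-exact acceptance."""
        if comp is None or not comp.fittable:
            return False, False
        if comp.n_obs >= self.min_component_obs and not comp.saturated:
            return True, False
        if (
            self.accept_saturated_exact
            and comp.saturated
            and comp.rmse <= self.exact_rmse_tol
        ):
            return True, True
        return False, False


@dataclass(frozen=True)
class CliffCandidate:
    """An (observed, virtual) cell pair with a predicted potency gap."""

    matrix_id: str
    observed_row: str
    observed_col: str
    observed_compound_id: str
    observed_p: float
    virtual_row: str
    virtual_col: str
    predicted_p: float
    relation: str  # same_row or same_col
    delta: float
    virtual_smiles: Optional[str]
    component_rmse: float
    component_n_obs: int
    saturated_warning: bool


def _virtual_structure(row: str, col: str) -> Optional[str]:
    """Weld the virtual cell's fragments; None for non-chemical labels."""
    try:
        return reassemble(row, col)
    except Exception:
        return None


def find_cliffs(
    matrices: Sequence[SARMatrix],
    models: dict | Sequence[FreeWilsonModel],
    delta_min: float = DEFAULT_DELTA_MIN,
    quality_gate: QualityGate | None = None,
    include_reverse: bool = False,
) -> list[CliffCandidate]:
    """Rank candidate cliffs formed by observed compounds and virtual analogues.

    For every virtual cell whose prediction passes the quality gate, every
    observed cell in the same row or column with ``predicted - observed >=
    delta_min`` yields a candidate. ``include_reverse`` additionally emits
    pairs where the virtual analogue is predicted *weaker* by the same
    margin (off by default; the use case is finding more potent analogues).

    Candidates are sorted by delta descending; ties break by smaller
    component RMSE, larger component n_obs, then lexicographic matrix id
    and cell labels.
    """
    gate = quality_gate or QualityGate()
    if not isinstance(models, dict):
        models = {m.matrix_id: m for m in models}

    candidates: list[CliffCandidate] = []
    for matrix in matrices:
        model = models[matrix.matrix_id]
        observed = matrix.observed_cells()
        for vrow, vcol in matrix.virtual_cells():
            comp = model.component_for(vrow, vcol)
            accepted, warning = gate.passes(comp)
            if not accepted:
                continue
            pred = predict_cell(model, vrow, vcol)
            if pred is None:  # pragma: no cover - gate already requires fittable
                continue
            vsmiles = _virtual_structure(vrow, vcol)
            for orow, ocol, cell in observed:
                if (orow == vrow) == (ocol == vcol):  # must share exactly one axis
                    continue
                delta = pred - cell.p_potency
                emit = delta >= delta_min or (include_reverse and -delta >= delta_min)
                if not emit:
                    continue
                candidates.append(
                    CliffCandidate(
                        matrix_id=matrix.matrix_id,
                        observed_row=orow,
                        observed_col=ocol,
                        observed_compound_id=cell.compound_id,
                        observed_p=cell.p_potency,
                        virtual_row=vrow,
                        virtual_col=vcol,
                        predicted_p=pred,
                        relation=SAME_ROW if orow == vrow else SAME_COL,
                        delta=delta,
                        virtual_smiles=vsmiles,
                        component_rmse=comp.rmse,
                        component_n_obs=comp.n_obs,
                        saturated_warning=warning,
                    )
                )
    candidates.sort(
        key=lambda c: (
            -c.delta,
            c.component_rmse,
            -c.component_n_obs,
            c.matrix_id,
            c.virtual_row,
            c.virtual_col,
            c.observed_row,
            c.observed_col,
        )
    )
    return candidates


CSV_COLUMNS = [
    "matrix_id", "relation", "delta",
    "observed_compound_id", "observed_p", "observed_row", "observed_col",
    "virtual_row", "virtual_col", "predicted_p", "virtual_smiles",
    "component_rmse", "component_n_obs", "saturated_warning",
]


def write_report(
    candidates: Sequence[CliffCandidate],
    out_dir: str | Path,
    config: dict | None = None,
    input_checksums: dict | None = None,
) -> tuple[Path, Path]:
    """Write cliff candidates as CSV and JSON (with run provenance).

    The JSON sidecar embeds the configuration used and input checksums so a
    report is traceable to its exact inputs. Ordering is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "cliffs.csv"
    json_path = out_dir / "cliffs.json"

    rows = [asdict(c) for c in candidates]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(csv_path, index=False)

    payload = {
        "n_candidates": len(candidates),
        "config": config or {},
        "input_checksums": input_checksums or {},
        "candidates": rows,
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return csv_path, json_path


def checksum_file(path: str | Path) -> str:
    """SHA-256 of a file, for run provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
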