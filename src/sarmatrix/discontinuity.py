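"""SAR discontinuity scoring within SAR matrices.

Two observed cells sharing a row or a column differ by a single structural
change (one substituent swap or one core swap) — a matched molecular pair.
Large potency gaps across such neighbor pairs mark regions of SAR
discontinuity, the environments in which activity-cliff prediction is
meaningful. The conventional activity-cliff criterion of a 100-fold potency
difference (2.0 p-units) is the default flag threshold.

Scores use observed cells only; model predictions never feed back into
discontinuity, keeping region selection independent of prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sarm_builder import SARMatrix

#: 100-fold potency difference, the conventional activity-cliff criterion.
DEFAULT_THRESHOLD = 2.0


@dataclass(frozen=True)
class DiscontinuityReport:
    matrix_id: str
    max_neighbor_gap: float
    mean_neighbor_gap: float
    n_neighbor_pairs: int
    flagged: bool


def neighbor_pairs(matrix: SARMatrix) -> list[tuple[float, float]]:
    """Potency pairs of observed cells sharing a row or a column."""
    observed = matrix.observed_cells()
    pairs = []
    for i, (r1, c1, cell1) in enumerate(observed):
        for r2, c2, cell2 in observed[i + 1 :]:
            if (r1 == r2) != (c1 == c2):  # share exactly one axis
                pairs.append((cell1.p_potency, cell2.p_potency))
    return pairs


def score_matrix(
    matrix: SARMatrix, threshold: float = DEFAULT_THRESHOLD
) -> DiscontinuityReport:
    """Score one matrix by its neighbor-pair potency gaps.

    A matrix whose observed cells form no neighbor pair (e.g. diagonal-only
    observations) scores zero and is never flagged.
    """
    if matrix.n_observed < 2:
        raise ValueError(
            f"matrix {matrix.matrix_id}: discontinuity needs >= 2 observed cells"
        )
    gaps = [abs(p1 - p2) for p1, p2 in neighbor_pairs(matrix)]
    if not gaps:
        return DiscontinuityReport(matrix.matrix_id, 0.0, 0.0, 0, False)
    max_gap = max(gaps)
    return DiscontinuityReport(
        matrix_id=matrix.matrix_id,
        max_neighbor_gap=max_gap,
        mean_neighbor_gap=sum(gaps) / len(gaps),
        n_neighbor_pairs=len(gaps),
        flagged=max_gap >= threshold,
    )


def score_matrices(
    matrices: Sequence[SARMatrix], threshold: float = DEFAULT_THRESHOLD
) -> list[DiscontinuityReport]:
    return [score_matrix(m, threshold) for m in matrices]


def reports_to_csv(reports: Iterable[DiscontinuityReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "matrix_id": r.matrix_id,
                "n_neighbor_pairs": r.n_neighbor_pairs,
                "max_neighbor_gap": r.max_neighbor_gap,
                "mean_neighbor_gap": r.mean_neighbor_gap,
                "flagged": r.flagged,
            }
            for r in reports
        ],
        columns=[
            "matrix_id", "n_neighbor_pairs", "max_neighbor_gap",
            "mean_neighbor_gap", "flagged",
        ],
    ).to_csv(path, index=False)
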