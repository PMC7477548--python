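"""Local Free-Wilson (additive contribution) models per SAR matrix.

The model attributes independent potency contributions to cores (rows) and
substituents (columns):

    p(i, j) = mu + alpha_i + beta_j

fitted by ordinary least squares to the observed cells of one matrix. A
prediction for a virtual cell (i, j) only borrows information along row i
and column j, so it is defined only where the observed cells connect row i
to column j: fitting is done separately on each connected component of the
bipartite row-column graph induced by observed cells. Within a component
the zero-sum constraints sum(alpha) = sum(beta) = 0 identify the
parameters; the least-squares fit itself is unique because the component is
connected.

A connected component with r rows, c columns and n observed cells always
has n >= r + c - 1 = number of free parameters, so every component is
fittable; n = r + c - 1 (a tree) gives a saturated, zero-residual fit whose
predictions are unchecked interpolations — flagged so downstream consumers
can gate on it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sarm_builder import SARMatrix


@dataclass
class ComponentFit:
    """Fitted additive model for one connected component of a matrix."""

    component_id: int
    rows: list
    columns: list
    mu: float
    alpha: dict  # row -> contribution, zero-sum
    beta: dict  # column -> contribution, zero-sum
    n_obs: int
    n_params: int
    rmse: float
    r2: float
    fittable: bool = True

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params

    @property
    def saturated(self) -> bool:
        return self.fittable and self.dof == 0


@dataclass
class FreeWilsonModel:
    """Per-matrix additive model: one ComponentFit per connected component."""

    matrix_id: str
    components: list  # list[ComponentFit]
    row_component: dict  # row -> component_id
    col_component: dict  # column -> component_id

    @property
    def n_obs(self) -> int:
        return sum(c.n_obs for c in self.components)

    @property
    def rmse(self) -> float:
        """Pooled RMSE over all fitted observed cells."""
        n = sum(c.n_obs for c in self.components if c.fittable)
        if n == 0:
            return float("nan")
        sse = sum(c.rmse**2 * c.n_obs for c in self.components if c.fittable)
        return math.sqrt(sse / n)

    def component_for(self, row: str, col: str) -> Optional[ComponentFit]:
        """The component containing both row and col, if they share one."""
        rid = self.row_component.get(row)
        cid = self.col_component.get(col)
        if rid is None or cid is None or rid != cid:
            return None
        return self.components[rid]


def _fit_component(
    comp_id: int, obs: list[tuple[str, str, float]]
) -> ComponentFit:
    """Least-squares additive fit with zero-sum identification.

    Solved with the full (rank-deficient) indicator design via the
    minimum-norm pseudoinverse solution, then re-centered so that row and
    column effects sum to zero; the fitted values are invariant to that
    reparameterization.
    """
    rows = sorted({r for r, _, _ in obs})
    cols = sorted({c for _, c, _ in obs})
    n_obs = len(obs)
    n_params = 1 + (len(rows) - 1) + (len(cols) - 1)

    if n_obs < n_params:
        # unreachable for connected components; kept as a guard
        return ComponentFit(
            comp_id, rows, cols, float("nan"), {}, {}, n_obs, n_params,
            float("nan"), float("nan"), fittable=False,
        )

    row_ix = {r: i for i, r in enumerate(rows)}
    col_ix = {c: i for i, c in enumerate(cols)}
    design = np.zeros((n_obs, 1 + len(rows) + len(cols)))
    y = np.zeros(n_obs)
    for k, (r, c, p) in enumerate(obs):
        design[k, 0] = 1.0
        design[k, 1 + row_ix[r]] = 1.0
        design[k, 1 + len(rows) + col_ix[c]] = 1.0
        y[k] = p
    theta, *_ = np.linalg.lstsq(design, y, rcond=None)

    mu = theta[0]
    alpha = theta[1 : 1 + len(rows)]
    beta = theta[1 + len(rows) :]
    # re-center to the zero-sum parameterization (fitted values unchanged)
    mu = float(mu + alpha.mean() + beta.mean())
    alpha = alpha - alpha.mean()
    beta = beta - beta.mean()

    fitted = design[:, 1 : 1 + len(rows)] @ alpha + design[:, 1 + len(rows) :] @ beta + mu
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-18 else 0.0

    return ComponentFit(
        comp_id, rows, cols, mu,
        {r: float(a) for r, a in zip(rows, alpha)},
        {c: float(b) for c, b in zip(cols, beta)},
        n_obs, n_params, rmse, r2,
    )


def fit(matrix: SARMatrix) -> FreeWilsonModel:
    """Fit the local Free-Wilson model to a matrix's observed cells."""
    observed = [(r, c, cell.p_potency) for r, c, cell in matrix.observed_cells()]
    if not observed:
        raise ValueError(f"matrix {matrix.matrix_id}: no observed cells to fit")

    graph = nx.Graph()
    for r, c, _ in observed:
        graph.add_edge(("row", r), ("col", c))
    components = []
    row_component: dict = {}
    col_component: dict = {}
    # deterministic component order: by smallest member label
    comps = sorted(nx.connected_components(graph), key=lambda s: sorted(s)[0])
    for comp_id, nodes in enumerate(comps):
        comp_obs = [
            (r, c, p) for r, c, p in observed if ("row", r) in nodes
        ]
        fit_result = _fit_component(comp_id, comp_obs)
        components.append(fit_result)
        for kind, name in nodes:
            if kind == "row":
                row_component[name] = comp_id
            else:
                col_component[name] = comp_id

    return FreeWilsonModel(
        matrix_id=matrix.matrix_id,
        components=components,
        row_component=row_component,
        col_component=col_component,
    )


def predict_cell(model: FreeWilsonModel, row: str, col: str) -> Optional[float]:
    """Predicted potency mu + alpha_row + beta_col, or None.

    None means "no prediction": the row and column are not connected through
    observed cells (or the component was unfittable), so the additive model
    has no information linking them.
    """
    comp = model.component_for(row, col)
    if comp is None or not comp.fittable:
        return None
    return comp.mu + comp.alpha[row] + comp.beta[col]


def predict_virtual_cells(matrix: SARMatrix, model: FreeWilsonModel) -> int:
    """Fill ``predicted_p`` of every predictable virtual cell in place.

    Returns the number of cells that received a prediction.
    """
    n = 0
    for r, c in matrix.virtual_cells():
        pred = predict_cell(model, r, c)
        if pred is not None:
            matrix.cells[(r, c)].predicted_p = pred
            n += 1
    return n


def diagnostics(model: FreeWilsonModel) -> dict:
    """Per-component fit summary with saturation flags."""
    return {
        "matrix_id": model.matrix_id,
        "n_components": len(model.components),
        "n_obs": model.n_obs,
        "pooled_rmse": model.rmse,
        "components": [
            {
                "component_id": c.component_id,
                "n_rows": len(c.rows),
                "n_columns": len(c.columns),
                "n_obs": c.n_obs,
                "n_params": c.n_params,
                "dof": c.dof if c.fittable else None,
                "rmse": c.rmse,
                "r2": c.r2,
                "fittable": c.fittable,
                "saturated": c.saturated,
            }
            for c in model.components
        ],
    }


def models_to_json(models: Iterable[FreeWilsonModel], path: str | Path) -> None:
    payload = []
    for model in models:
        entry = diagnostics(model)
        entry["components_parameters"] = [
            {
                "component_id": c.component_id,
                "mu": c.mu,
                "alpha": c.alpha,
                "beta": c.beta,
            }
            for c in model.components
            if c.fittable
        ]
        payload.append(entry)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def predictions_to_csv(
    matrices: Sequence[SARMatrix], models: dict, path: str | Path
) -> None:
    """One line per predicted virtual cell: matrix, cell, prediction, flags."""
    rows = []
    for matrix in matrices:
        model = models[matrix.matrix_id]
        for r, c in matrix.virtual_cells():
            cell = matrix.cells[(r, c)]
            if cell.predicted_p is None:
                continue
            comp = model.component_for(r, c)
            rows.append(
                {
                    "matrix_id": matrix.matrix_id,
                    "row": r,
                    "column": c,
                    "predicted_p": cell.predicted_p,
                    "component_id": comp.component_id,
                    "component_n_obs": comp.n_obs,
                    "saturated": comp.saturated,
                }
            )
    columns = [
        "matrix_id", "row", "column", "predicted_p",
        "component_id", "component_n_obs", "saturated",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
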