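"""Ground-truth-bearing synthetic inputs for every pipeline stage.

Two generators share one configuration:

* :func:`make_matrix` draws an abstract additive potency surface
  p(i, j) = mu + alpha_i + beta_j (+ noise), withholds a fraction of cells
  as virtual, and returns the matrix together with its full ground truth —
  the setting in which Free-Wilson recovery can be verified exactly.
* :func:`make_library` materializes the same additive model as real
  molecules: scaffold templates (by default the para-, meta- and
  ortho-attached N-hydroxy-lactam cores of the MMP-1 inhibitor series that
  motivates this package) welded to a substituent pool, with potencies
  emitted as Ki values in nM so the records exercise unit conversion,
  standardization, fragmentation and matrix reconstruction end to end.

Activity cliffs are injected by raising the potency contribution of a
chosen virtual cell's substituent (column) by ``cliff_magnitude``: observed
analogues bearing that substituent carry the signal, so an additive model
can legitimately predict the withheld cell as a cliff partner — the same
mechanism by which a real strongly activity-enhancing substituent reveals
itself across series. A literal per-cell mode (``mode="cell"``) raises only
the virtual cell's own ground truth; such an epistatic cliff is invisible
to any model fitted on observed cells and is provided to make that
limitation testable.

All randomness flows from ``SimConfig.seed``; identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .chem_io import ActivityRecord
from .fragmentation import reassemble, fragment_from_smiles
from .sarm_builder import OBSERVED, VIRTUAL, Cell, SARMatrix, _matrix_id

from rdkit import Chem


class SyntheticDataError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for synthetic matrices and libraries.

    Defaults describe a mid-size analogue campaign on the p-scale:
    micromolar-centred potencies (mu 6.5), core and substituent effects of
    a few tenths to one log unit (sd 0.5 / 0.75), assay noise of 0.2 log
    units (typical replicate spread of biochemical assays), one fifth of
    the grid unexplored, and single injected 100-fold cliffs.
    """

    n_scaffolds: int = 6
    n_substituents: int = 8
    mu: float = 6.5
    sd_alpha: float = 0.5
    sd_beta: float = 0.75
    noise_sd: float = 0.2
    missing_frac: float = 0.2
    n_cliffs: int = 1
    cliff_magnitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be >= 0")
        if not (0 <= self.missing_frac < 1):
            raise SyntheticDataError("missing_frac must be in [0, 1)")
        if self.n_cliffs < 0:
            raise SyntheticDataError("n_cliffs must be >= 0")


@dataclass
class GroundTruth:
    """Generative state of a synthetic matrix.

    ``additive`` is the pre-injection additive surface; ``truth`` the
    noiseless potency after cliff injection. Observed cell values are
    ``truth + noise``.
    """

    mu: float
    alpha: dict
    beta: dict
    additive: dict  # (row, col) -> float
    truth: dict  # (row, col) -> float
    injected: list  # [(row, col), ...]


def _connected(rows: Sequence[str], cols: Sequence[str], observed: set) -> bool:
    """True if the observed cells connect all rows and columns in one component."""
    graph = nx.Graph()
    graph.add_nodes_from(("row", r) for r in rows)
    graph.add_nodes_from(("col", c) for c in cols)
    for r, c in observed:
        graph.add_edge(("row", r), ("col", c))
    return nx.is_connected(graph)


def _draw_layout(
    rng: np.random.Generator,
    rows: list,
    cols: list,
    missing_frac: float,
    max_retries: int = 200,
) -> set:
    """Choose virtual cells, resampling until the observed graph is connected."""
    cells = [(r, c) for r in rows for c in cols]
    n_virtual = int(round(missing_frac * len(cells)))
    if n_virtual == 0:
        return set()
    for _ in range(max_retries):
        picks = rng.choice(len(cells), size=n_virtual, replace=False)
        virtual = {cells[i] for i in picks}
        observed = set(cells) - virtual
        if _connected(rows, cols, observed):
            return virtual
    raise SyntheticDataError(
        f"could not draw a connected observed layout with missing_frac="
        f"{missing_frac} in {max_retries} attempts"
    )


def make_matrix(config: SimConfig) -> tuple[SARMatrix, GroundTruth]:
    """Generate an abstract additive SAR matrix with full ground truth."""
    rng = np.random.default_rng(config.seed)
    rows = [f"R{i:02d}" for i in range(config.n_scaffolds)]
    cols = [f"C{j:02d}" for j in range(config.n_substituents)]
    alpha = rng.normal(0.0, config.sd_alpha, len(rows))
    beta = rng.normal(0.0, config.sd_beta, len(cols))
    noise = rng.normal(0.0, config.noise_sd, (len(rows), len(cols)))
    virtual = _draw_layout(rng, rows, cols, config.missing_frac)

    additive = {
        (r, c): config.mu + alpha[i] + beta[j]
        for i, r in enumerate(rows)
        for j, c in enumerate(cols)
    }
    cells = {}
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            if (r, c) in virtual:
                cells[(r, c)] = Cell(VIRTUAL)
            else:
                cells[(r, c)] = Cell(
                    OBSERVED,
                    compound_id=f"SIM-{r}-{c}",
                    p_potency=float(additive[(r, c)] + noise[i, j]),
                )
    matrix = SARMatrix(
        matrix_id=_matrix_id("synthetic", rows, cols),
        hypercore="synthetic",
        rows=rows,
        columns=cols,
        cells=cells,
    )
    truth = GroundTruth(
        mu=config.mu,
        alpha={r: float(a) for r, a in zip(rows, alpha)},
        beta={c: float(b) for c, b in zip(cols, beta)},
        additive={k: float(v) for k, v in additive.items()},
        truth={k: float(v) for k, v in additive.items()},
        injected=[],
    )
    if config.n_cliffs > 0:
        matrix, truth = inject_cliffs(
            matrix, truth, config.n_cliffs, config.cliff_magnitude, config.seed + 1
        )
    return matrix, truth


def inject_cliffs(
    matrix: SARMatrix,
    truth: GroundTruth,
    n_cliffs: int,
    cliff_magnitude: float,
    seed: int,
    mode: str = "substituent",
) -> tuple[SARMatrix, GroundTruth]:
    """Raise chosen virtual cells' ground truths by ``cliff_magnitude``.

    ``mode="substituent"`` (default) attributes the raise to the cell's
    substituent: the column effect increases, lifting the truth of every
    cell in that column and the recorded potency of its observed cells, so
    the cliff is learnable from data. Injected columns are distinct and
    must have observed support; the designated cell's row must also contain
    an observed cell, guaranteeing a weak partner for the cliff pair.

    ``mode="cell"`` raises only the designated cell's truth (an epistatic
    deviation from additivity that no additive model can see).

    Inputs are not mutated; returns updated copies. The injected cells'
    ``truth - additive`` equals ``cliff_magnitude`` exactly in both modes.
    """
    if mode not in ("substituent", "cell"):
        raise SyntheticDataError(f"unknown injection mode {mode!r}")
    matrix = copy.deepcopy(matrix)
    truth = copy.deepcopy(truth)
    virtual = matrix.virtual_cells()
    if n_cliffs > len(virtual):
        raise SyntheticDataError(
            f"cannot inject {n_cliffs} cliffs: only {len(virtual)} virtual cells"
        )
    if n_cliffs == 0:
        return matrix, truth

    rng = np.random.default_rng(seed)
    observed = {(r, c) for r, c, _ in matrix.observed_cells()}
    obs_rows = {r for r, _ in observed}
    obs_cols = {c for _, c in observed}

    if mode == "substituent":
        eligible = [
            (r, c) for r, c in virtual if r in obs_rows and c in obs_cols
        ]
        # one injected column per cliff so magnitudes stay exact
        chosen: list = []
        used_cols: set = set()
        order = rng.permutation(len(eligible))
        for k in order:
            r, c = eligible[k]
            if c not in used_cols:
                chosen.append((r, c))
                used_cols.add(c)
            if len(chosen) == n_cliffs:
                break
        if len(chosen) < n_cliffs:
            raise SyntheticDataError(
                f"cannot place {n_cliffs} cliffs in distinct supported columns "
                f"(only {len(chosen)} eligible)"
            )
        for _, col in chosen:
            truth.beta[col] = truth.beta.get(col, 0.0) + cliff_magnitude
            for row in matrix.rows:
                truth.truth[(row, col)] += cliff_magnitude
                cell = matrix.cells[(row, col)]
                if cell.status == OBSERVED:
                    cell.p_potency += cliff_magnitude
    else:
        picks = rng.choice(len(virtual), size=n_cliffs, replace=False)
        chosen = [virtual[i] for i in sorted(picks)]
        for cell_key in chosen:
            truth.truth[cell_key] += cliff_magnitude

    truth.injected = sorted(chosen)
    return matrix, truth


# ---------------------------------------------------------------------------
# chemical libraries

#: Aryl-attached N-hydroxy-lactam cores (para / meta / ortho attachment),
#: the scaffold family of the MMP-1 inhibitor series behind this package.
DEFAULT_SCAFFOLDS = [
    "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccc([*])cc2)C1=O",
    "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2cccc([*])c2)C1=O",
    "ONC(=O)[C@@H](C)N1CC[C@@](C)(c2ccccc2[*])C1=O",
]

DEFAULT_SUBSTITUENTS = [
    "[*]C",
    "[*]CC",
    "[*]C(C)C",
    "[*]C(F)(F)F",
    "[*]Cl",
    "[*]F",
    "[*]OC",
    "[*]C#N",
    "[*]c1ccccc1",
    "[*]N",
]


@dataclass
class LibraryGroundTruth:
    """Generative state of a synthetic combinatorial library."""

    scaffolds: list
    substituents: list
    mu: float
    alpha: dict  # scaffold -> effect
    beta: dict  # substituent -> effect (post-injection)
    truth_p: dict  # (scaffold, substituent) -> noiseless p-potency
    observed_p: dict  # (scaffold, substituent) -> noisy p used for records
    withheld: list  # [(scaffold, substituent), ...] virtual ground truth
    injected: list  # [(scaffold, substituent), ...]


def make_library(
    config: SimConfig,
    scaffold_templates: Optional[Sequence[str]] = None,
    substituent_pool: Optional[Sequence[str]] = None,
) -> tuple[list[ActivityRecord], LibraryGroundTruth]:
    """Generate a combinatorial analogue library as activity records.

    Compounds are scaffold × substituent welds with additive ground-truth
    potencies emitted as Ki values in nM. ``missing_frac`` combinations are
    withheld (they become the virtual cells after reconstruction) and
    ``n_cliffs`` withheld combinations get substituent-effect cliffs.
    """
    scaffolds = list(scaffold_templates or DEFAULT_SCAFFOLDS[: config.n_scaffolds])
    substituents = list(substituent_pool or DEFAULT_SUBSTITUENTS[: config.n_substituents])
    if scaffold_templates is None and config.n_scaffolds > len(DEFAULT_SCAFFOLDS):
        scaffolds = DEFAULT_SCAFFOLDS  # default family has three attachment isomers
    for template in scaffolds:
        try:
            fragment_from_smiles(template)
        except Exception as exc:
            raise SyntheticDataError(f"invalid scaffold template {template!r}: {exc}")
    for sub in substituents:
        try:
            fragment_from_smiles(sub)
        except Exception as exc:
            raise SyntheticDataError(f"invalid substituent {sub!r}: {exc}")

    rng = np.random.default_rng(config.seed)
    alpha = rng.normal(0.0, config.sd_alpha, len(scaffolds))
    beta = rng.normal(0.0, config.sd_beta, len(substituents))
    noise = rng.normal(0.0, config.noise_sd, (len(scaffolds), len(substituents)))
    withheld = _draw_layout(rng, scaffolds, substituents, config.missing_frac)

    beta_map = {s: float(b) for s, b in zip(substituents, beta)}
    injected: list = []
    if config.n_cliffs > 0:
        observed_cells = {
            (sc, su)
            for sc in scaffolds
            for su in substituents
            if (sc, su) not in withheld
        }
        obs_cols = {su for _, su in observed_cells}
        eligible = sorted(
            (sc, su) for sc, su in withheld if su in obs_cols
        )
        if not eligible or config.n_cliffs > len({su for _, su in eligible}):
            raise SyntheticDataError(
                "not enough withheld combinations with observed substituent "
                "support to inject the requested cliffs"
            )
        used_cols: set = set()
        for k in rng.permutation(len(eligible)):
            sc, su = eligible[k]
            if su not in used_cols:
                injected.append((sc, su))
                used_cols.add(su)
            if len(injected) == config.n_cliffs:
                break
        for _, su in injected:
            beta_map[su] += config.cliff_magnitude

    truth_p: dict = {}
    observed_p: dict = {}
    records: list[ActivityRecord] = []
    counter = 0
    for i, sc in enumerate(scaffolds):
        for j, su in enumerate(substituents):
            p = config.mu + float(alpha[i]) + beta_map[su]
            truth_p[(sc, su)] = p
            if (sc, su) in withheld:
                continue
            counter += 1
            p_obs = p + float(noise[i, j])
            observed_p[(sc, su)] = p_obs
            ki_nm = 10 ** (9.0 - p_obs)
            records.append(
                ActivityRecord(
                    compound_id=f"SYN-{counter:04d}",
                    smiles=reassemble(sc, su),
                    value=ki_nm,
                    unit="nM",
                    activity_type="Ki",
                    relation="=",
                )
            )
    ground_truth = LibraryGroundTruth(
        scaffolds=scaffolds,
        substituents=substituents,
        mu=config.mu,
        alpha={s: float(a) for s, a in zip(scaffolds, alpha)},
        beta=beta_map,
        truth_p=truth_p,
        observed_p=observed_p,
        withheld=sorted(withheld),
        injected=sorted(injected),
    )
    return records, ground_truth


def write_ground_truth(truth: LibraryGroundTruth, path: str | Path) -> None:
    """Sidecar JSON with the library's generative state."""
    payload = {
        "scaffolds": truth.scaffolds,
        "substituents": truth.substituents,
        "mu": truth.mu,
        "alpha": truth.alpha,
        "beta": truth.beta,
        "truth_p": [
            {"scaffold": sc, "substituent": su, "p": p}
            for (sc, su), p in sorted(truth.truth_p.items())
        ],
        "withheld": [list(t) for t in truth.withheld],
        "injected": [list(t) for t in truth.injected],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# random molecule generation (fragment-grammar welding)

_RM_SCAFFOLDS = [
    "[*]c1ccccc1",
    "[*]c1ccncc1",
    "[*]c1cccs1",
    "[*]c1ccc2ccccc2c1",
    "[*]C1CCCCC1",
    "[*]C1CCOC1",
    "[*]C1CCNC1",
    "[*]c1cnco1",
]

_RM_LINKERS = [
    "[*]C[*]",
    "[*]CC[*]",
    "[*]CCC[*]",
    "[*]C(C)[*]",
    "[*]C(=O)N[*]",
    "[*]NC(=O)[*]",
    "[*]C(=O)[*]",
    "[*]O[*]",
    "[*]CO[*]",
    "[*]S[*]",
    "[*]N(C)[*]",
    "[*]c1ccc([*])cc1",
]

_RM_TERMINALS = [
    "[*]C",
    "[*]CC",
    "[*]C(C)C",
    "[*]C(C)(C)C",
    "[*]C(F)(F)F",
    "[*]Cl",
    "[*]F",
    "[*]Br",
    "[*]OC",
    "[*]O",
    "[*]N",
    "[*]C#N",
    "[*]C(=O)OC",
    "[*]c1ccccc1",
    "[*][C@@H](C)O",
]


def _weld_first_dummies(a_smiles: str, b_smiles: str) -> str:
    """Weld the first attachment point of each fragment; others survive."""
    a = Chem.MolFromSmiles(a_smiles)
    b = Chem.MolFromSmiles(b_smiles)
    for mol in (a, b):
        done = False
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0 and not done:
                atom.SetAtomMapNum(1)
                done = True
    welded = Chem.molzip(a, b)
    Chem.SanitizeMol(welded)
    return Chem.MolToSmiles(welded)


def random_molecules(n: int, seed: int) -> list[str]:
    """Deterministically generate ``n`` distinct drug-like small molecules.

    Molecules are built by welding a ring scaffold, optionally a linker,
    and a terminal group from small fragment grammars — every product is a
    valid, standardized structure with at least one ring and several
    cuttable acyclic bonds, exercising fragmentation round trips.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        scaffold = _RM_SCAFFOLDS[rng.integers(len(_RM_SCAFFOLDS))]
        if rng.random() < 0.7:
            linker = _RM_LINKERS[rng.integers(len(_RM_LINKERS))]
            partial = _weld_first_dummies(scaffold, linker)
        else:
            partial = scaffold
        terminal = _RM_TERMINALS[rng.integers(len(_RM_TERMINALS))]
        smiles = _weld_first_dummies(partial, terminal)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
            continue  # pragma: no cover - grammar always closes all dummies
        smiles = Chem.MolToSmiles(mol)
        if smiles not in seen:
            seen.add(smiles)
            out.append(smiles)
    if len(out) < n:
        raise SyntheticDataError(f"could only generate {len(out)} of {n} molecules")
    return out
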