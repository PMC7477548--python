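"""Whole-pipeline orchestration, configuration and run provenance.

``run_pipeline`` executes load → fragment → build → score → fit → cliffs,
writes every stage artifact to the output directory, and returns a summary
of per-stage counts. Runs are deterministic functions of (inputs, config,
seed): the summary embeds the configuration used and a SHA-256 checksum of
the input so any report is traceable to its exact inputs. A failing stage
aborts with the stage name and cause; partial outputs are retained next to
a ``FAILED`` marker.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import chem_io, cliff_predictor, discontinuity, freewilson, sarm_builder
from .cliff_predictor import QualityGate, checksum_file, find_cliffs, write_report
from .fragmentation import SizeRules
from .sarm_builder import MatrixMinima
from .synthetic_data import SimConfig


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (YAML-serializable)."""

    input_path: Optional[str] = None
    output_dir: str = "sarmatrix_out"
    aggregation: str = "median"
    include_nonexact: bool = False
    size_rules: SizeRules = field(default_factory=SizeRules)
    minima: MatrixMinima = field(default_factory=MatrixMinima)
    h_match: bool = True
    discontinuity_threshold: float = discontinuity.DEFAULT_THRESHOLD
    predict_only_flagged: bool = False
    delta_min: float = cliff_predictor.DEFAULT_DELTA_MIN
    quality_gate: QualityGate = field(default_factory=QualityGate)
    include_reverse: bool = False
    seed: int = 0
    sim: Optional[SimConfig] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub_cls in (
            ("size_rules", SizeRules),
            ("minima", MatrixMinima),
            ("quality_gate", QualityGate),
            ("sim", SimConfig),
        ):
            if isinstance(data.get(key), dict):
                data[key] = sub_cls(**data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any error with its stage name."""

    class _Ctx:
        def __init__(self, stage_name: str):
            self.name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(self.name, exc) from exc
            return False

    return _Ctx(name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full SAR-matrix workflow and write all artifacts.

    Returns the run summary (also written to ``summary.json``): per-stage
    counts, the configuration used, and input provenance.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        summary = _run_stages(config, out)
    except PipelineError as err:
        failed_marker.write_text(f"stage: {err.stage}\ncause: {err.cause}\n")
        raise
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config.to_yaml(out / "config_used.yaml")
    return summary


def _run_stages(config: RunConfig, out: Path) -> dict:
    counts: dict = {}
    checksums: dict = {}

    with _stage("load"):
        if config.input_path is None:
            raise ValueError("no input_path configured")
        records = chem_io.read_activity_csv(config.input_path)
        checksums[str(config.input_path)] = checksum_file(config.input_path)
        compounds = chem_io.load_compounds(
            records,
            aggregation=config.aggregation,
            include_nonexact=config.include_nonexact,
        )
        chem_io.write_compound_table(
            compounds, out / "compounds.csv", out / "compounds_manifest.json"
        )
        counts["records"] = len(records)
        counts["compounds"] = len(compounds)

    with _stage("fragment"):
        index = sarm_builder.build_series_index(compounds, config.size_rules)
        n_cuts = sum(len(subs) for subs in index.entries.values())
        _write_fragments_csv(index, out / "fragments.csv")
        counts["cores"] = len(index.entries)
        counts["cuts"] = n_cuts

    with _stage("build"):
        matrices = sarm_builder.build_matrices(
            index, config.size_rules, config.minima, h_match=config.h_match
        )
        sarm_builder.matrices_to_json(matrices, out / "matrices.json")
        sarm_builder.matrices_to_csv(matrices, out / "matrix_cells.csv")
        counts["matrices"] = len(matrices)
        counts["virtual_cells"] = sum(len(m.virtual_cells()) for m in matrices)

    with _stage("score"):
        reports = discontinuity.score_matrices(matrices, config.discontinuity_threshold)
        discontinuity.reports_to_csv(reports, out / "discontinuity.csv")
        flagged_ids = {r.matrix_id for r in reports if r.flagged}
        counts["flagged_matrices"] = len(flagged_ids)

    with _stage("fit"):
        to_model = (
            [m for m in matrices if m.matrix_id in flagged_ids]
            if config.predict_only_flagged
            else matrices
        )
        models = {m.matrix_id: freewilson.fit(m) for m in to_model}
        n_pred = sum(
            freewilson.predict_virtual_cells(m, models[m.matrix_id]) for m in to_model
        )
        freewilson.models_to_json(models.values(), out / "freewilson.json")
        freewilson.predictions_to_csv(to_model, models, out / "predictions.csv")
        counts["modeled_matrices"] = len(to_model)
        counts["predictions"] = n_pred

    with _stage("cliffs"):
        candidates = find_cliffs(
            to_model,
            models,
            delta_min=config.delta_min,
            quality_gate=config.quality_gate,
            include_reverse=config.include_reverse,
        )
        write_report(candidates, out, config=config.to_dict(), input_checksums=checksums)
        counts["candidates"] = len(candidates)
        # one predicted cell can pair with several observed neighbors
        counts["candidate_virtual_cells"] = len(
            {(c.matrix_id, c.virtual_row, c.virtual_col) for c in candidates}
        )

    return {
        "counts": counts,
        "config": config.to_dict(),
        "input_checksums": checksums,
        "output_dir": str(out),
    }


def _write_fragments_csv(index, path: Path) -> None:
    import pandas as pd

    rows = [
        {"core": core, "substituent": sub, "compound_id": cid, "p_potency": p}
        for core in index.cores
        for sub, cid, p in index.series(core)
    ]
    pd.DataFrame(
        rows, columns=["core", "substituent", "compound_id", "p_potency"]
    ).to_csv(path, index=False)
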