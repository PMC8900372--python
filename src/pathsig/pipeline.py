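"""End-to-end orchestration and reproducibility metadata.

``run_pipeline`` reads the three inputs, runs scoring, and writes the
interaction table, the cluster-pair summary, and a run manifest.  The
manifest snapshots the configuration, input file hashes, seed, and package
version — enough to reproduce the run byte-for-byte (timestamps aside).
Outputs are written atomically at the end; a validation failure removes any
partial output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .data_model import (
    ExpressionMatrix,
    RunConfig,
    TrajectoryAssignment,
    read_assignment,
    read_expression,
)
from .errors import PathsigError
from .estimator import InteractionScorer
from .lr_database import LRDatabase, load_lr_pairs

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ValidationReport:
    """Cross-reference report between expression, assignment, and database."""

    n_cells_expression: int = 0
    n_cells_assigned: int = 0
    n_cells_unassigned: int = 0
    unknown_assignment_cells: list[str] = field(default_factory=list)
    n_db_pairs: int = 0
    n_db_genes_matched: int = 0
    unmatched_db_genes: list[str] = field(default_factory=list)
    edges_per_time_label: dict[str, list[str]] = field(default_factory=dict)
    cells_per_edge: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def validate_inputs(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
) -> ValidationReport:
    """Cross-check the three inputs without failing; callers decide fatality."""
    report = ValidationReport()
    report.n_cells_expression = expr.n_cells
    have = set(expr.cell_ids)
    assigned = {a.cell_id for a in assignments}
    report.n_cells_assigned = len(assigned & have)
    report.n_cells_unassigned = len(have - assigned)
    report.unknown_assignment_cells = sorted(assigned - have)
    if report.unknown_assignment_cells:
        report.problems.append(
            f"{len(report.unknown_assignment_cells)} assigned cells missing "
            "from the expression matrix"
        )
    if report.n_cells_unassigned:
        report.warnings.append(
            f"{report.n_cells_unassigned} expression cells have no assignment "
            "and will be dropped"
        )

    index = expr.gene_index()
    matched = {g for g in db.genes if g.strip().upper() in index}
    report.n_db_pairs = len(db)
    report.n_db_genes_matched = len(matched)
    report.unmatched_db_genes = sorted(db.genes - matched)
    if not matched:
        report.problems.append("no database gene is measured in the expression matrix")

    per_edge: dict[str, int] = {}
    per_label: dict[str, set[str]] = {}
    for a in assignments:
        per_edge[a.edge] = per_edge.get(a.edge, 0) + 1
        per_label.setdefault(a.sampling_time, set()).add(a.edge)
    report.cells_per_edge = per_edge
    report.edges_per_time_label = {k: sorted(v) for k, v in per_label.items()}
    for edge, n in sorted(per_edge.items()):
        if n <= 2:
            report.warnings.append(f"edge {edge!r} has only {n} cell(s)")
    for label, edges in report.edges_per_time_label.items():
        if len(edges) < 2:
            report.warnings.append(
                f"time label {label!r} has a single edge; no paracrine pair there"
            )
    return report


def write_manifest(
    out_dir: Path,
    config: RunConfig,
    input_paths: dict[str, Path],
    outputs: dict[str, Path],
) -> Path:
    manifest = {
        "tool": "pathsig",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in input_paths.items()
        },
        "outputs": {name: str(p) for name, p in outputs.items()},
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tmp.replace(path)
    return path


def run_pipeline(
    expr_path: str | Path,
    meta_path: str | Path,
    lr_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """simulate-independent scoring entry point: read, validate, score, write.

    Writes ``interactions.tsv``, ``summary.tsv``, and ``manifest.json`` under
    ``out_dir`` and returns their paths.  Raises (and removes partial
    outputs) if validation finds a fatal inconsistency.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = read_expression(expr_path)
    assignments = read_assignment(meta_path)
    db = load_lr_pairs(lr_path)

    report = validate_inputs(expr, assignments, db)
    for w in report.warnings:
        logger.warning("%s", w)
    if not report.ok:
        raise PathsigError("; ".join(report.problems))

    scorer = InteractionScorer(
        window_size=config.window_size,
        n_bins=config.n_bins,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        include_autocrine=config.include_autocrine,
        use_alignment=config.use_alignment,
        global_fdr=config.global_fdr,
        permute_within_pair=config.permute_within_pair,
        spline_df=config.spline_df,
        min_expressed_fraction=config.min_expressed_fraction,
        random_state=config.seed,
    )
    outputs = {
        "interactions": out / "interactions.tsv",
        "summary": out / "summary.tsv",
    }
    try:
        scorer.fit(expr, assignments, db)
        scorer.results_.to_csv(outputs["interactions"], sep="\t", index=False)
        scorer.summary_.to_csv(outputs["summary"], sep="\t", index=False)
    except Exception:
        for p in outputs.values():
            Path(p).unlink(missing_ok=True)
        raise
    outputs["manifest"] = write_manifest(
        out,
        config,
        {
            "expression": Path(expr_path),
            "assignment": Path(meta_path),
            "lr_database": Path(lr_path),
        },
        outputs,
    )
    return outputs


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Re-run a recorded run; same config + inputs give identical outputs."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig(**manifest["config"])
    inputs = manifest["inputs"]
    return run_pipeline(
        inputs["expression"]["path"],
        inputs["assignment"]["path"],
        inputs["lr_database"]["path"],
        out_dir,
        config,
    )
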