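"""Core domain types and file readers/writers.

The package works with three inputs:

* a genes x cells expression matrix of nonnegative, already-normalized
  values (dense CSV/TSV, or MatrixMarket MTX with gene/barcode sidecars);
* a per-cell trajectory assignment: the edge (branch/cluster) the cell sits
  on, its pseudotime position in [0, 1] along that edge, and the sampling
  time label of the experiment the cell came from;
* a run configuration bundling the scoring parameters.

Trajectory assignments can be supplied natively (4-column TSV) or converted
from a dynverse-style "milestone_progression" table; the converted form is
identical downstream, so all later stages see a single representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = ["cell_id", "edge", "pseudotime", "sampling_time"]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of nonnegative expression values.

    Values are assumed to be normalized upstream (e.g., by a standard
    single-cell pipeline); no transformation is applied here.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_names) != n_genes:
            raise FormatError(
                f"{len(self.gene_names)} gene names for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValidationError("gene names are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("expression contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        """Case-insensitive symbol -> row map.

        Symbols are trimmed and upper-cased before matching; when two rows
        collapse to the same key the first occurrence wins (a warning is
        logged).  Ligand-receptor databases mix human/mouse casing, so exact
        matching would silently drop most pairs for mouse data.
        """
        index: dict[str, int] = {}
        for i, name in enumerate(self.gene_names):
            key = name.strip().upper()
            if key in index:
                logger.warning(
                    "duplicate gene symbol %r (case-insensitive); keeping first",
                    name,
                )
                continue
            index[key] = i
        return index

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        cols = [pos[c] for c in cell_ids]
        return ExpressionMatrix(self.values[:, cols], self.gene_names, list(cell_ids))


@dataclass(frozen=True)
class TrajectoryAssignment:
    """One cell's position on the trajectory.

    ``edge`` is the branch (cluster) label; ``pseudotime`` is the cell's
    position in [0, 1] along that edge; ``sampling_time`` is the experimental
    collection label (e.g., "day11") used to restrict which branches may be
    tested against each other.
    """

    cell_id: str
    edge: str
    pseudotime: float
    sampling_time: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pseudotime <= 1.0):
            raise ValidationError(
                f"pseudotime {self.pseudotime} for cell {self.cell_id!r} "
                "outside [0, 1]"
            )


def validate_assignments(
    assignments: Iterable[TrajectoryAssignment],
) -> list[TrajectoryAssignment]:
    """Check uniqueness of cell ids; return the assignments as a list."""
    out = list(assignments)
    seen: set[str] = set()
    for a in out:
        if a.cell_id in seen:
            raise ValidationError(f"duplicate cell id {a.cell_id!r} in assignment")
        seen.add(a.cell_id)
    return out


def assignments_to_frame(assignments: Sequence[TrajectoryAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in assignments],
            "edge": [a.edge for a in assignments],
            "pseudotime": [a.pseudotime for a in assignments],
            "sampling_time": [a.sampling_time for a in assignments],
        }
    )


def frame_to_assignments(frame: pd.DataFrame) -> list[TrajectoryAssignment]:
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"assignment table missing columns: {missing}")
    return validate_assignments(
        TrajectoryAssignment(
            cell_id=str(r.cell_id),
            edge=str(r.edge),
            pseudotime=float(r.pseudotime),
            sampling_time=str(r.sampling_time),
        )
        for r in frame.itertuples(index=False)
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or MatrixMarket MTX.

    CSV/TSV layout: first row = cell ids, first column = gene symbols.
    MTX layout: genes x cells sparse matrix with sidecar ``genes.tsv`` and
    ``barcodes.tsv`` files (one name per line, first column used); sidecar
    locations default to the MTX's directory but can be overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {"csv": "csv", "tsv": "csv", "txt": "csv", "mtx": "mtx"}.get(
            suffix.lstrip("."), "csv"
        )
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"missing MTX sidecar file: {p}")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(cells_path, sep="\t", header=None).iloc[:, 0].astype(str)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes "
                f"x {len(cells)} barcodes"
            )
        return ExpressionMatrix(np.asarray(mat, dtype=float), list(genes), list(cells))
    if format == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if frame.empty and frame.columns.empty:
            raise FormatError(f"empty expression file: {path}")
        try:
            values = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression entries in {path}: {exc}")
        return ExpressionMatrix(
            values, [str(g) for g in frame.index], [str(c) for c in frame.columns]
        )
    raise FormatError(f"unknown expression format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(expr.values, index=expr.gene_names, columns=expr.cell_ids)
    frame.to_csv(path)


def read_assignment(path: str | Path) -> list[TrajectoryAssignment]:
    """Read the native 4-column assignment TSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t")
    return frame_to_assignments(frame)


def write_assignment(
    assignments: Sequence[TrajectoryAssignment], path: str | Path
) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def from_milestone_progression(
    table: pd.DataFrame,
    sampling_times: Mapping[str, str],
) -> list[TrajectoryAssignment]:
    """Convert a dynverse-style milestone-progression table.

    Accepts either columns (``cell_id``, ``edge``, ``progression``) or the raw
    dynverse form (``cell_id``, ``from``, ``to``, ``percentage``), in which
    case the edge label is formed as ``"from→to"``.  The progression value, a
    number in [0, 1] giving the cell's location along the edge, becomes the
    pseudotime verbatim.
    """
    table = table.copy()
    if {"from", "to", "percentage"}.issubset(table.columns):
        table["edge"] = table["from"].astype(str) + "→" + table["to"].astype(str)
        table["progression"] = table["percentage"]
    if not {"cell_id", "edge", "progression"}.issubset(table.columns):
        raise FormatError(
            "milestone table needs (cell_id, edge, progression) or "
            "(cell_id, from, to, percentage) columns"
        )
    out = []
    for r in table.itertuples(index=False):
        cell = str(r.cell_id)
        prog = float(r.progression)
        if not (0.0 <= prog <= 1.0):
            raise ValidationError(
                f"progression {prog} for cell {cell!r} outside [0, 1]"
            )
        if cell not in sampling_times:
            raise ValidationError(f"no sampling time provided for cell {cell!r}")
        out.append(
            TrajectoryAssignment(
                cell_id=cell,
                edge=str(r.edge),
                pseudotime=prog,
                sampling_time=str(sampling_times[cell]),
            )
        )
    return validate_assignments(out)


def read_milestone_progression(
    path: str | Path, sampling_times: Mapping[str, str]
) -> list[TrajectoryAssignment]:
    frame = pd.read_csv(path, sep="\t")
    return from_milestone_progression(frame, sampling_times)


def match_cells(
    expr: ExpressionMatrix, assignments: Sequence[TrajectoryAssignment]
) -> tuple[ExpressionMatrix, list[TrajectoryAssignment]]:
    """Reconcile an expression matrix with a trajectory assignment.

    Cells present in the expression matrix but absent from the assignment
    belong to no edge; they are dropped with a warning.  Assigned cells
    missing from the matrix are an error (the assignment refers to data we
    do not have).
    """
    have = set(expr.cell_ids)
    unknown = [a.cell_id for a in assignments if a.cell_id not in have]
    if unknown:
        raise ValidationError(
            f"assignment references cells absent from expression: {unknown[:5]}"
        )
    assigned = {a.cell_id for a in assignments}
    dropped = [c for c in expr.cell_ids if c not in assigned]
    if dropped:
        logger.warning(
            "dropping %d cells with no trajectory assignment", len(dropped)
        )
    order = [a.cell_id for a in assignments]
    return expr.subset_cells(order), list(assignments)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of a scoring run.

    window_size
        Sliding-window length L in bins (even; default 20 — sizes 5/10/20/30
        were assessed upstream and 20 performed best).
    n_bins
        Number of equal-size pseudotime bins per edge (default 101).
    n_permutations
        Permutation rounds N for the null (default 100000, giving a minimum
        attainable p-value of 1/N = 0.00001).
    alpha
        Benjamini-Hochberg FDR level (default 0.05).
    """

    window_size: int = 20
    n_bins: int = 101
    n_permutations: int = 100000
    alpha: float = 0.05
    seed: int | None = None
    include_autocrine: bool = False
    use_alignment: bool = False
    global_fdr: bool = False
    permute_within_pair: bool = False
    spline_df: int = 8
    min_expressed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.window_size % 2 != 0:
            raise ValidationError("window_size must be a positive even integer")
        if self.n_bins <= 0:
            raise ValidationError("n_bins must be positive")
        if self.window_size > self.n_bins:
            raise ValidationError("window_size must not exceed n_bins")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0.0 <= self.min_expressed_fraction <= 1.0):
            raise ValidationError("min_expressed_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
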