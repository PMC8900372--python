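"""Ligand-receptor interaction database.

A database is a deduplicated set of (ligand, receptor) gene-symbol pairs,
such as the Ramilowski et al. human resource (708 ligands, 691 receptors,
2557 interactions).  ``scripts/fetch_lr_database.py`` documents how to obtain
that table; any two-column CSV/TSV with ``ligand`` and ``receptor`` columns
is accepted, so alternative resources can be swapped in.

A gene may appear as both a ligand and a receptor — no exclusivity is
enforced (true of the Ramilowski annotations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRDatabase:
    """An ordered, deduplicated collection of ligand-receptor pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate ligand-receptor pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LRDatabase":
        """Build from an iterable of (ligand, receptor), dropping duplicates
        while preserving first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for lig, rec in pairs:
            seen.setdefault((str(lig).strip(), str(rec).strip()), None)
        return cls(tuple(seen))

    @property
    def ligands(self) -> set[str]:
        return {lig for lig, _ in self.pairs}

    @property
    def receptors(self) -> set[str]:
        return {rec for _, rec in self.pairs}

    @property
    def genes(self) -> set[str]:
        return self.ligands | self.receptors

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def load_lr_pairs(path: str | Path) -> LRDatabase:
    """Load a ligand-receptor database from a CSV/TSV file.

    Column names are matched case-insensitively; ``ligand``/``receptor`` are
    required.  Duplicate rows are collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in frame.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise FormatError(
            f"{path} must have 'ligand' and 'receptor' columns; "
            f"found {list(frame.columns)}"
        )
    if frame.empty:
        raise ValidationError(f"ligand-receptor file {path} has no rows")
    db = LRDatabase.from_pairs(
        zip(frame[cols["ligand"]].astype(str), frame[cols["receptor"]].astype(str))
    )
    logger.info(
        "loaded %d ligand-receptor pairs (%d ligands, %d receptors) from %s",
        len(db), len(db.ligands), len(db.receptors), path,
    )
    return db


def write_lr_pairs(db: LRDatabase, path: str | Path) -> None:
    pd.DataFrame(list(db.pairs), columns=["ligand", "receptor"]).to_csv(
        path, index=False
    )


def restrict_to_measured(
    db: LRDatabase,
    expr: ExpressionMatrix,
    min_expressed_fraction: float = 0.0,
) -> LRDatabase:
    """Keep only pairs whose ligand and receptor are both measured.

    Gene symbols are matched case-insensitively after trimming.  With
    ``min_expressed_fraction`` > 0, a gene must additionally be nonzero in at
    least that fraction of cells; the default applies no expression filter —
    permutation testing already neutralizes never-expressed genes, whose
    observed and null scores are both ~0.
    """
    index = expr.gene_index()

    def measured(symbol: str) -> bool:
        row = index.get(symbol.strip().upper())
        if row is None:
            return False
        if min_expressed_fraction > 0.0:
            frac = float(np.mean(expr.values[row] > 0))
            if frac < min_expressed_fraction:
                return False
        return True

    kept = [(lig, rec) for lig, rec in db.pairs if measured(lig) and measured(rec)]
    if not kept:
        logger.warning("no ligand-receptor pair is measured in the expression matrix")
    return LRDatabase.from_pairs(kept)
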