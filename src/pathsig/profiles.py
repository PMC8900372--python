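"""Sliding-window expression profiles along trajectory edges.

Each edge is divided into ``n_bins`` (default 101) equal-size pseudotime
bins.  Overlapping windows slide across the bins one bin at a time (adjacent
windows share L-1 bins).  Because cells pile up near branching nodes, the
first window has length L/2 and grows by one bin per step until it reaches
the full length L; thereafter every window has length L.  A gene's profile
is its mean expression over the cells falling in each window — the x and y
vectors later compared by dot product.

Windows are indexed by their end bin, which runs from L/2-1 to n_bins-1,
giving M = n_bins - L/2 + 1 windows (92 for the defaults).  This is the
minimal layout consistent with the first-window length, the ramp, and the
one-bin slide; a ``full_length_only`` flag drops the ramp for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ExpressionMatrix, TrajectoryAssignment
from .errors import ValidationError


@dataclass(frozen=True)
class WindowLayout:
    """The window grid shared by every edge of a run."""

    n_bins: int
    window_size: int
    starts: np.ndarray  # shape (M,), inclusive start bin of each window
    ends: np.ndarray  # shape (M,), inclusive end bin of each window

    @property
    def n_windows(self) -> int:
        return len(self.ends)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts + 1


def build_window_layout(
    n_bins: int = 101, window_size: int = 20, full_length_only: bool = False
) -> WindowLayout:
    """Enumerate the sliding windows for one edge.

    With the default ramp, window ends run from L/2-1 to n_bins-1 and starts
    are clipped at bin 0, so lengths ramp L/2, L/2+1, ..., L and then stay L.
    """
    L = int(window_size)
    if L <= 0 or L % 2 != 0:
        raise ValidationError("window_size must be a positive even integer")
    if L > n_bins:
        raise ValidationError(f"window_size {L} exceeds n_bins {n_bins}")
    first_end = L - 1 if full_length_only else L // 2 - 1
    ends = np.arange(first_end, n_bins)
    starts = np.maximum(0, ends - L + 1)
    return WindowLayout(n_bins=int(n_bins), window_size=L, starts=starts, ends=ends)


def assign_bins(pseudotimes: Sequence[float] | np.ndarray, n_bins: int) -> np.ndarray:
    """Map pseudotimes in [0, 1] to bin indices in [0, n_bins-1].

    Bins are the half-open intervals [k/n_bins, (k+1)/n_bins); t = 1 falls in
    the last bin.
    """
    t = np.asarray(pseudotimes, dtype=float)
    if t.size and (np.min(t) < 0.0 or np.max(t) > 1.0):
        raise ValidationError("pseudotimes outside [0, 1]")
    return np.minimum(np.floor(t * n_bins).astype(int), n_bins - 1)


@dataclass
class EdgeProfileSet:
    """Window-mean expression for all genes on one edge."""

    edge: str
    profile: np.ndarray  # genes x M
    n_cells_per_window: np.ndarray  # length M

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.profile)):
            raise ValidationError(f"non-finite profile entries on edge {self.edge!r}")


def _window_imputation_map(window_counts: np.ndarray) -> np.ndarray:
    """Index of the window each window should take its value from.

    Non-empty windows map to themselves.  An empty window borrows from the
    nearest non-empty window; on a distance tie the earlier window wins.
    Leading empties are therefore back-filled from the first non-empty
    window.  At least one window must be non-empty.
    """
    nonempty = np.flatnonzero(window_counts > 0)
    if nonempty.size == 0:
        raise ValidationError("edge has no cells in any window")
    m = len(window_counts)
    idx = np.arange(m)
    pos = np.searchsorted(nonempty, idx)
    left = nonempty[np.clip(pos - 1, 0, nonempty.size - 1)]
    right = nonempty[np.clip(pos, 0, nonempty.size - 1)]
    # ties (equal distance) resolve to the earlier (left) window
    use_right = (np.abs(right - idx) < np.abs(idx - left)) | (pos == 0)
    src = np.where(use_right, right, left)
    src[window_counts > 0] = idx[window_counts > 0]
    return src


def profile_from_bins(
    values: np.ndarray, bins: np.ndarray, layout: WindowLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Window-mean profile for a genes x cells block with known bin indices.

    Returns (profile genes x M, cells-per-window).  This is the hot path of
    the permutation loop: per-bin sums/counts are accumulated once, window
    sums come from prefix sums, and empty windows are filled from the
    nearest non-empty window (one shared index map — emptiness depends only
    on the bins, not on the gene).
    """
    n_genes = values.shape[0]
    if values.shape[1] != bins.shape[0]:
        raise ValidationError("values and bins disagree on cell count")
    if values.shape[1] == 0:
        raise ValidationError("edge has zero cells")
    bin_counts = np.bincount(bins, minlength=layout.n_bins)
    bin_sums = np.zeros((layout.n_bins, n_genes))
    np.add.at(bin_sums, bins, values.T)

    ccounts = np.concatenate([[0], np.cumsum(bin_counts)])
    csums = np.vstack([np.zeros((1, n_genes)), np.cumsum(bin_sums, axis=0)])
    wcounts = ccounts[layout.ends + 1] - ccounts[layout.starts]
    wsums = csums[layout.ends + 1] - csums[layout.starts]

    src = _window_imputation_map(wcounts)
    safe = np.maximum(wcounts, 1).astype(float)
    means = (wsums / safe[:, None])[src]
    return means.T, wcounts


def sliding_window_profile(
    expr: ExpressionMatrix,
    cells_on_edge: Sequence[TrajectoryAssignment],
    layout: WindowLayout,
) -> EdgeProfileSet:
    """Build the window-mean profile of one edge from its assigned cells."""
    cells = list(cells_on_edge)
    if not cells:
        raise ValidationError("edge has zero cells")
    edges = {a.edge for a in cells}
    if len(edges) != 1:
        raise ValidationError(f"cells belong to multiple edges: {sorted(edges)}")
    sub = expr.subset_cells([a.cell_id for a in cells])
    bins = assign_bins([a.pseudotime for a in cells], layout.n_bins)
    profile, wcounts = profile_from_bins(sub.values, bins, layout)
    return EdgeProfileSet(edge=cells[0].edge, profile=profile, n_cells_per_window=wcounts)


def write_profiles(
    profile_set: EdgeProfileSet, gene_names: Sequence[str], path
) -> None:
    """Dump one edge's gene x window profile as TSV (for visualization)."""
    import pandas as pd

    frame = pd.DataFrame(
        profile_set.profile,
        index=list(gene_names),
        columns=[f"w{j}" for j in range(profile_set.profile.shape[1])],
    )
    frame.to_csv(path, sep="\t")
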