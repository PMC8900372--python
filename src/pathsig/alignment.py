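"""Optional alignment between the two edges of a cluster pair.

Pseudotime runs from 0 to 1 on every edge, but a unit of pseudotime need not
correspond to the same span of real time on both edges.  To compare dynamics
on a common clock, each edge's window profiles are smoothed with a
least-squares cubic B-spline, z-scored per gene, stacked into a multivariate
curve over the union of database ligand and receptor genes, and the two
curves are matched by dynamic time warping (DTW).  The resulting warp path —
one per cluster pair — is then reused for every ligand-receptor pair of that
pair: the dot product is taken along the path and rescaled to M terms so
aligned and unaligned scores are directly comparable.

DTW here uses the symmetric step pattern (→, ↓, ↘) with squared Euclidean
local cost, no band constraint, and a deterministic diagonal-first
tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_lsq_spline

from .errors import ValidationError


@dataclass(frozen=True)
class WarpPath:
    """A monotone DTW path between two sequences.

    Steps run from (0, 0) to (M_A - 1, M_B - 1); each step increments the
    sender index, the receiver index, or both, by one.
    """

    steps: tuple[tuple[int, int], ...]
    total_cost: float

    def __post_init__(self) -> None:
        if not self.steps or self.steps[0] != (0, 0):
            raise ValidationError("warp path must start at (0, 0)")
        for (i0, j0), (i1, j1) in zip(self.steps, self.steps[1:]):
            di, dj = i1 - i0, j1 - j0
            if di not in (0, 1) or dj not in (0, 1) or (di, dj) == (0, 0):
                raise ValidationError("warp path steps must advance i, j, or both by 1")

    def __len__(self) -> int:
        return len(self.steps)


def smooth_profiles(profiles: np.ndarray, df: int = 8) -> np.ndarray:
    """Least-squares cubic B-spline fit of each row, evaluated in place.

    ``df`` is the number of spline coefficients (>= 4; df - 4 interior knots
    placed uniformly).  Rows shorter than ``df`` points use a reduced basis.
    Constant and linear rows are reproduced exactly (they lie in the cubic
    span); rough rows are shrunk toward the least-squares projection.
    """
    prof = np.atleast_2d(np.asarray(profiles, dtype=float))
    m = prof.shape[1]
    if m < 4:
        raise ValidationError("need at least 4 window positions to smooth")
    if df < 4:
        raise ValidationError("spline df must be >= 4")
    df = min(df, m)
    x = np.arange(m, dtype=float)
    interior = np.linspace(x[0], x[-1], df - 4 + 2)[1:-1]
    knots = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    spline = make_lsq_spline(x, prof.T, knots, k=3)
    out = spline(x).T
    return out if np.asarray(profiles).ndim == 2 else out[0]


def smooth_profile(profile: np.ndarray, df: int = 8) -> np.ndarray:
    """Smooth a single window profile (vector in, vector out)."""
    return smooth_profiles(np.asarray(profile, dtype=float)[None, :], df)[0]


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Per-row z-score; constant rows map to zero rather than NaN."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (matrix - mean) / sd


def dtw_align(curve_a: np.ndarray, curve_b: np.ndarray) -> WarpPath:
    """DTW between two (possibly multivariate) curves.

    Inputs are (M,) vectors or (d, M) matrices sharing d.  The path
    minimizes the summed squared Euclidean local cost under the boundary,
    monotonicity, and unit-step constraints; ties prefer the diagonal step.
    The dynamic program sweeps anti-diagonals so the inner work is
    vectorized.
    """
    A = np.atleast_2d(np.asarray(curve_a, dtype=float))
    B = np.atleast_2d(np.asarray(curve_b, dtype=float))
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValidationError("curves must be finite")
    if A.shape[0] != B.shape[0]:
        raise ValidationError("curves must share the feature dimension")
    m, n = A.shape[1], B.shape[1]
    if m < 2 or n < 2:
        raise ValidationError("curves must have length >= 2")

    diff = A.T[:, None, :] - B.T[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)

    D = np.full((m, n), np.inf)
    move = np.zeros((m, n), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    D[0, 0] = cost[0, 0]
    big = np.inf
    for d in range(1, m + n - 1):
        i = np.arange(max(0, d - n + 1), min(m - 1, d) + 1)
        j = d - i
        diag = np.where((i > 0) & (j > 0), D[np.maximum(i - 1, 0), np.maximum(j - 1, 0)], big)
        up = np.where(i > 0, D[np.maximum(i - 1, 0), j], big)
        left = np.where(j > 0, D[i, np.maximum(j - 1, 0)], big)
        best = np.minimum(diag, np.minimum(up, left))
        mv = np.where(diag <= best, 0, np.where(up <= left, 1, 2)).astype(np.int8)
        D[i, j] = cost[i, j] + best
        move[i, j] = mv

    steps = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
        steps.append((i, j))
    steps.reverse()
    return WarpPath(steps=tuple(steps), total_cost=float(D[m - 1, n - 1]))


def aligned_interaction_score(x: np.ndarray, y: np.ndarray, path: WarpPath) -> float:
    """Dot product along a warp path, rescaled to M = len(x) terms.

    The path mean of x_i * y_j is multiplied by M so that with the identity
    (diagonal) path on equal-length profiles the value equals the plain dot
    product.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_idx = np.array([i for i, _ in path.steps])
    j_idx = np.array([j for _, j in path.steps])
    if i_idx.max() >= len(x) or j_idx.max() >= len(y):
        raise ValidationError("warp path indexes beyond the profiles")
    if path.steps[-1] != (len(x) - 1, len(y) - 1):
        raise ValidationError("warp path does not span the profiles")
    return float(np.sum(x[i_idx] * y[j_idx]) * len(x) / len(path.steps))
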