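"""Interaction scoring with permutation significance.

Two branches (edges) of a trajectory can exchange signals only if their
cells coexist in real time, so candidate cluster pairs are restricted to
edges sharing a sampling-time label.  For each candidate (sender, receiver)
pair and each ligand-receptor pair in the database, the score is the dot
product x^T y = sum_i x_i y_i between the ligand's sliding-window profile on
the sender edge (x) and the receptor's profile on the receiver edge (y).
The dot product rewards both magnitude and co-variation along pseudotime:
profiles that rise or fall together score higher than opposed profiles with
the same averages.

Significance comes from a permutation null: the (edge, pseudotime) label
vector of *all* cells in the model is randomly reassigned to cells, profiles
are rebuilt, and scores recomputed.  Permuting model-wide (rather than
within the tested pair) penalizes genes that are broadly expressed across
clusters, which would otherwise score high everywhere.  With N rounds the
attainable minimum p-value is 1/N; ties between a permuted and the observed
score count against the observed score.  Benjamini-Hochberg controls the
FDR, by default within each cluster pair (the reporting unit), optionally
pooled globally.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import alignment as _align
from .data_model import (
    ExpressionMatrix,
    RunConfig,
    TrajectoryAssignment,
    match_cells,
)
from .errors import ValidationError
from .lr_database import LRDatabase, restrict_to_measured
from .profiles import WindowLayout, assign_bins, build_window_layout, profile_from_bins

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "sender", "receiver", "time_label", "ligand", "receptor",
    "score", "p_value", "q_value", "significant", "low_confidence",
]


@dataclass(frozen=True)
class ClusterPair:
    """An ordered (sender, receiver) pair of edges sharing a time label."""

    sender: str
    receiver: str
    time_label: str


def edge_time_labels(assignments: Sequence[TrajectoryAssignment]) -> dict[str, str]:
    """Majority sampling-time label per edge (ties break lexicographically)."""
    by_edge: dict[str, Counter] = {}
    for a in assignments:
        by_edge.setdefault(a.edge, Counter())[a.sampling_time] += 1
    labels = {}
    for edge, counts in by_edge.items():
        top = max(counts.values())
        labels[edge] = min(t for t, c in counts.items() if c == top)
    return labels


def select_cluster_pairs(
    assignments: Sequence[TrajectoryAssignment],
    include_autocrine: bool = False,
) -> list[ClusterPair]:
    """All ordered pairs of edges whose majority sampling times match.

    Cells can only interact if both populations are present at the same
    time, so pairing is restricted to same-label edges.  Both directions of
    each pair are returned; self-pairs (autocrine signaling) only when
    requested.
    """
    labels = edge_time_labels(assignments)
    edges = sorted(labels)
    pairs = []
    for s in edges:
        for r in edges:
            if s == r and not include_autocrine:
                continue
            if labels[s] == labels[r]:
                pairs.append(ClusterPair(s, r, labels[s]))
    return pairs


def interaction_score(x: np.ndarray, y: np.ndarray) -> float:
    """Dot product between a ligand and a receptor window profile."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("profiles must be finite")
    return float(np.dot(x, y))


def count_to_pvalue(n_greater_equal: int | np.ndarray, n_permutations: int):
    """Permutation p-value from an exceedance count: max(c, 1) / N.

    The floor at one exceedance makes the minimum attainable p-value 1/N
    (0.00001 at the default N = 100000) — an observed score that beats every
    permuted score is never reported as p = 0.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    return np.maximum(n_greater_equal, 1) / n_permutations


def bh_adjust(
    p_values: Sequence[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance calls."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.min(p) <= 0.0 or np.max(p) > 1.0:
        raise ValidationError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per cluster pair: how many ligand-receptor pairs are significant.

    This count is the cluster-pair interaction strength plotted as a
    sender x receiver heatmap.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["sender", "receiver", "time_label", "n_significant", "n_tested"]
        )
    grouped = results.groupby(["sender", "receiver", "time_label"], sort=True)
    out = grouped.agg(
        n_significant=("significant", "sum"), n_tested=("significant", "size")
    ).reset_index()
    out["n_significant"] = out["n_significant"].astype(int)
    return out


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    """Inputs reduced to arrays for the permutation loop."""

    values: np.ndarray  # needed genes x assigned cells
    edge_codes: np.ndarray  # int per cell
    bins: np.ndarray  # int per cell
    edge_names: list[str]  # code -> edge label
    pairs: list[ClusterPair]
    lig_rows: np.ndarray  # db-pair -> row of `values`
    rec_rows: np.ndarray
    db: LRDatabase
    layout: WindowLayout
    cells_per_edge: dict[str, int]


def _prepare(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
    config: RunConfig,
) -> _Prepared:
    expr, assignments = match_cells(expr, assignments)
    layout = build_window_layout(config.n_bins, config.window_size)
    pairs = select_cluster_pairs(assignments, config.include_autocrine)
    if not pairs:
        raise ValidationError("no time-matched cluster pairs to test")
    db = restrict_to_measured(db, expr, config.min_expressed_fraction)
    if len(db) == 0:
        raise ValidationError("no ligand-receptor pair is measured")

    index = expr.gene_index()
    needed_syms: list[str] = []
    seen: set[str] = set()
    for lig, rec in db:
        for sym in (lig, rec):
            key = sym.strip().upper()
            if key not in seen:
                seen.add(key)
                needed_syms.append(key)
    row_of = {key: i for i, key in enumerate(needed_syms)}
    values = expr.values[[index[key] for key in needed_syms], :]
    lig_rows = np.array([row_of[lig.strip().upper()] for lig, _ in db])
    rec_rows = np.array([row_of[rec.strip().upper()] for _, rec in db])

    edge_names = sorted({a.edge for a in assignments})
    code = {e: i for i, e in enumerate(edge_names)}
    edge_codes = np.array([code[a.edge] for a in assignments])
    bins = assign_bins([a.pseudotime for a in assignments], config.n_bins)
    cells_per_edge = dict(
        zip(*np.unique([a.edge for a in assignments], return_counts=True))
    )
    return _Prepared(
        values=values,
        edge_codes=edge_codes,
        bins=bins,
        edge_names=edge_names,
        pairs=pairs,
        lig_rows=lig_rows,
        rec_rows=rec_rows,
        db=db,
        layout=layout,
        cells_per_edge={e: int(n) for e, n in cells_per_edge.items()},
    )


def _edge_profiles(
    prep: _Prepared,
    edge_codes: np.ndarray,
    bins: np.ndarray,
    edges: Sequence[str],
) -> dict[str, np.ndarray]:
    """Window profiles (needed genes x M) for the requested edges."""
    code = {e: i for i, e in enumerate(prep.edge_names)}
    out = {}
    for edge in edges:
        sel = edge_codes == code[edge]
        profile, _ = profile_from_bins(prep.values[:, sel], bins[sel], prep.layout)
        out[edge] = profile
    return out


def _pair_scores(
    prep: _Prepared,
    profiles: dict[str, np.ndarray],
    config: RunConfig,
) -> np.ndarray:
    """Scores for every (cluster pair, db pair): shape (n_pairs, n_db).

    Unaligned: straight dot products.  Aligned: one warp path per cluster
    pair from the smoothed, z-scored multivariate curve over all database
    genes, then the path-mean product rescaled to M terms so aligned and
    unaligned scores share a scale.
    """
    M = prep.layout.n_windows
    scores = np.empty((len(prep.pairs), len(prep.db)))
    paths = _pair_paths(prep, profiles, config) if config.use_alignment else None
    for k, pair in enumerate(prep.pairs):
        ps = profiles[pair.sender]
        pr = profiles[pair.receiver]
        if paths is not None:
            path = paths[pair]
            i_idx = np.array([i for i, _ in path.steps])
            j_idx = np.array([j for _, j in path.steps])
            prods = ps[prep.lig_rows][:, i_idx] * pr[prep.rec_rows][:, j_idx]
            scores[k] = prods.sum(axis=1) * M / len(path.steps)
        else:
            scores[k] = np.einsum(
                "km,km->k", ps[prep.lig_rows], pr[prep.rec_rows]
            )
    return scores


def _pair_paths(
    prep: _Prepared, profiles: dict[str, np.ndarray], config: RunConfig
) -> dict[ClusterPair, _align.WarpPath]:
    """One warp path per cluster pair.

    The alignment curve matches the signaling program itself: dimension k of
    the sender curve is the k-th database pair's *ligand* profile on the
    sender edge, and dimension k of the receiver curve is that pair's
    *receptor* profile on the receiver edge.  Each profile is z-scored and
    then spline-smoothed: standardization puts genes of different magnitude
    on one scale, and smoothing afterwards shrinks flat (noise-only) genes
    toward zero so they do not drown the genes with real dynamics.  DTW
    between these multivariate curves finds the real-time correspondence
    under which ligand and receptor dynamics match; the path is reused for
    every ligand-receptor pair of the cluster pair.
    """
    smoothed = {
        edge: _align.smooth_profiles(_align.zscore_rows(prof), config.spline_df)
        for edge, prof in profiles.items()
    }
    return {
        pair: _align.dtw_align(
            smoothed[pair.sender][prep.lig_rows],
            smoothed[pair.receiver][prep.rec_rows],
        )
        for pair in prep.pairs
    }


def permutation_pvalues(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
    config: RunConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ClusterPair], LRDatabase, np.ndarray, np.ndarray]:
    """Observed scores and permutation p-values for every tested pair.

    Returns (cluster_pairs, restricted database, observed scores, p-values)
    with scores and p-values shaped (n_cluster_pairs, n_db_pairs).  Each
    permutation round shuffles the joint (edge, pseudotime) label vector —
    model-wide by default, within the two clusters of each pair when
    ``permute_within_pair`` is set — rebuilds the window profiles, and
    rescores every tested pair; p = max(#{permuted >= observed}, 1) / N.
    With alignment enabled the scored quantity (observed and permuted alike)
    is the aligned dot product, so the null stays exchangeable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    prep = _prepare(expr, assignments, db, config)
    edges_needed = sorted({e for p in prep.pairs for e in (p.sender, p.receiver)})
    observed_profiles = _edge_profiles(prep, prep.edge_codes, prep.bins, edges_needed)
    observed = _pair_scores(prep, observed_profiles, config)

    n_cells = prep.values.shape[1]
    counts = np.zeros_like(observed, dtype=np.int64)
    N = config.n_permutations
    if config.permute_within_pair:
        code = {e: i for i, e in enumerate(prep.edge_names)}
        for k, pair in enumerate(prep.pairs):
            members = np.flatnonzero(
                (prep.edge_codes == code[pair.sender])
                | (prep.edge_codes == code[pair.receiver])
            )
            one = _OnePair(prep, pair)
            edges_k = sorted({pair.sender, pair.receiver})
            for _ in range(N):
                perm = rng.permutation(members.size)
                ec = prep.edge_codes.copy()
                bn = prep.bins.copy()
                ec[members] = prep.edge_codes[members][perm]
                bn[members] = prep.bins[members][perm]
                profs = _edge_profiles(one, ec, bn, edges_k)
                s = _pair_scores(one, profs, config)[0]
                counts[k] += s >= observed[k]
    else:
        for _ in range(N):
            perm = rng.permutation(n_cells)
            ec = prep.edge_codes[perm]
            bn = prep.bins[perm]
            profs = _edge_profiles(prep, ec, bn, edges_needed)
            perm_scores = _pair_scores(prep, profs, config)
            counts += perm_scores >= observed
    pvals = count_to_pvalue(counts, N)
    return prep.pairs, prep.db, observed, pvals


def _OnePair(prep: _Prepared, pair: ClusterPair) -> _Prepared:
    """A view of the prepared inputs restricted to a single cluster pair."""
    return _Prepared(
        values=prep.values,
        edge_codes=prep.edge_codes,
        bins=prep.bins,
        edge_names=prep.edge_names,
        pairs=[pair],
        lig_rows=prep.lig_rows,
        rec_rows=prep.rec_rows,
        db=prep.db,
        layout=prep.layout,
        cells_per_edge=prep.cells_per_edge,
    )


def observed_scores(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Dot-product scores only (no permutations) — cheap ranking table."""
    config = config or RunConfig()
    prep = _prepare(expr, assignments, db, config)
    edges_needed = sorted({e for p in prep.pairs for e in (p.sender, p.receiver)})
    profiles = _edge_profiles(prep, prep.edge_codes, prep.bins, edges_needed)
    scores = _pair_scores(prep, profiles, config)
    rows = []
    for k, pair in enumerate(prep.pairs):
        for d, (lig, rec) in enumerate(prep.db):
            rows.append(
                (pair.sender, pair.receiver, pair.time_label, lig, rec, scores[k, d])
            )
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "time_label", "ligand", "receptor", "score"]
    )


def score_interactions(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: scores, permutation p-values, BH-FDR, summaries.

    Returns (results, summary).  Results carry one row per (cluster pair,
    ligand, receptor) sorted by (sender, receiver, p_value, -score);
    ``low_confidence`` flags pairs in which either edge holds <= 2 cells
    (scored, but the window profiles rest on almost no data).  The summary
    counts significant ligand-receptor pairs per cluster pair.
    """
    import dataclasses

    config = config or RunConfig()
    pairs, rdb, observed, pvals = permutation_pvalues(
        expr, assignments, db, config, rng
    )
    aligned = None
    path_lengths = None
    if config.use_alignment:
        # `observed` holds aligned scores; recompute the plain dot products
        # and the per-pair path lengths for the output table
        plain_cfg = dataclasses.replace(config, use_alignment=False)
        prep = _prepare(expr, assignments, db, plain_cfg)
        edges_needed = sorted({e for p in prep.pairs for e in (p.sender, p.receiver)})
        profiles = _edge_profiles(prep, prep.edge_codes, prep.bins, edges_needed)
        aligned = observed
        observed = _pair_scores(prep, profiles, plain_cfg)
        paths = _pair_paths(prep, profiles, config)
        path_lengths = {pair: len(path) for pair, path in paths.items()}
    cells_per_edge = Counter(a.edge for a in assignments)
    rows = []
    for k, pair in enumerate(pairs):
        lowconf = (
            cells_per_edge[pair.sender] <= 2 or cells_per_edge[pair.receiver] <= 2
        )
        for d, (lig, rec) in enumerate(rdb):
            row = {
                "sender": pair.sender,
                "receiver": pair.receiver,
                "time_label": pair.time_label,
                "ligand": lig,
                "receptor": rec,
                "score": observed[k, d],
                "p_value": pvals[k, d],
                "low_confidence": lowconf,
            }
            if aligned is not None:
                row["aligned_score"] = aligned[k, d]
                row["path_length"] = path_lengths[pair]
            rows.append(row)
    results = pd.DataFrame(rows)
    if config.global_fdr:
        q, sig = bh_adjust(results["p_value"].to_numpy(), config.alpha)
        results["q_value"] = q
        results["significant"] = sig
    else:
        results["q_value"] = np.nan
        results["significant"] = False
        for _, idx in results.groupby(["sender", "receiver"]).groups.items():
            q, sig = bh_adjust(results.loc[idx, "p_value"].to_numpy(), config.alpha)
            results.loc[idx, "q_value"] = q
            results.loc[idx, "significant"] = sig
    results = results.sort_values(
        ["sender", "receiver", "p_value", "score"],
        ascending=[True, True, True, False],
        kind="mergesort",
    ).reset_index(drop=True)
    cols = ["sender", "receiver", "time_label", "ligand", "receptor",
            "score", "p_value", "q_value", "significant", "low_confidence"]
    if aligned is not None:
        cols = cols[:6] + ["aligned_score", "path_length"] + cols[6:]
    results = results[cols]
    return results, summarize(results)
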