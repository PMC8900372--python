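"""Scikit-learn-style front end.

``InteractionScorer`` is the main user-facing object: configure it with the
scoring parameters, call :meth:`fit` with an expression matrix, trajectory
assignments, and a ligand-receptor database, and read the fitted result
tables from the trailing-underscore attributes.  It follows the estimator
protocol (``get_params``/``set_params``, validation in ``fit``), so it
composes with scikit-learn tooling such as ``clone`` and grid iteration.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data_model import ExpressionMatrix, RunConfig, TrajectoryAssignment
from .lr_database import LRDatabase
from .profiles import build_window_layout
from .scoring import score_interactions


class InteractionScorer(BaseEstimator):
    """Score ligand-receptor signaling between time-matched trajectory edges.

    Parameters
    ----------
    window_size : int, default=20
        Sliding-window length L in bins (must be even).  The first window
        spans L/2 bins and grows to L over the first L bins.
    n_bins : int, default=101
        Number of equal pseudotime bins per edge.
    n_permutations : int, default=100000
        Rounds of the (edge, pseudotime) label permutation; the minimum
        attainable p-value is 1 / n_permutations.
    alpha : float, default=0.05
        Benjamini-Hochberg FDR level.
    include_autocrine : bool, default=False
        Also test each edge against itself.
    use_alignment : bool, default=False
        Warp the receiver's profile onto the sender's with B-spline-smoothed
        DTW before scoring (for edges whose pseudotime scales differ in real
        time).
    global_fdr : bool, default=False
        Pool all tests in one BH correction instead of correcting within
        each cluster pair.
    permute_within_pair : bool, default=False
        Restrict the permutation null to the two clusters of each pair
        instead of the whole model.
    spline_df : int, default=8
        Coefficients of the smoothing spline used by the alignment curve.
    min_expressed_fraction : float, default=0.0
        Drop database genes expressed in fewer than this fraction of cells.
    random_state : int or None
        Seed for the permutation stream.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (sender, receiver, ligand, receptor) with score,
        p_value, q_value, and significance call.
    summary_ : pandas.DataFrame
        Per cluster pair, the number of significant and tested pairs.
    layout_ : WindowLayout
        The window grid used.
    n_cluster_pairs_ : int
    """

    def __init__(
        self,
        window_size: int = 20,
        n_bins: int = 101,
        n_permutations: int = 100000,
        alpha: float = 0.05,
        include_autocrine: bool = False,
        use_alignment: bool = False,
        global_fdr: bool = False,
        permute_within_pair: bool = False,
        spline_df: int = 8,
        min_expressed_fraction: float = 0.0,
        random_state: int | None = None,
    ):
        self.window_size = window_size
        self.n_bins = n_bins
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.include_autocrine = include_autocrine
        self.use_alignment = use_alignment
        self.global_fdr = global_fdr
        self.permute_within_pair = permute_within_pair
        self.spline_df = spline_df
        self.min_expressed_fraction = min_expressed_fraction
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            window_size=self.window_size,
            n_bins=self.n_bins,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.random_state,
            include_autocrine=self.include_autocrine,
            use_alignment=self.use_alignment,
            global_fdr=self.global_fdr,
            permute_within_pair=self.permute_within_pair,
            spline_df=self.spline_df,
            min_expressed_fraction=self.min_expressed_fraction,
        )

    def fit(
        self,
        expression: ExpressionMatrix,
        assignments: Sequence[TrajectoryAssignment],
        lr_database: LRDatabase,
    ) -> "InteractionScorer":
        """Run the full scoring pipeline and store the result tables."""
        config = self._config()  # validates parameters
        rng = np.random.default_rng(self.random_state)
        self.layout_ = build_window_layout(self.n_bins, self.window_size)
        self.results_, self.summary_ = score_interactions(
            expression, assignments, lr_database, config, rng
        )
        self.n_cluster_pairs_ = len(self.summary_)
        return self

    def significant_interactions(self) -> pd.DataFrame:
        """The rows of ``results_`` that pass the FDR threshold."""
        check_is_fitted(self, "results_")
        return self.results_[self.results_["significant"]].reset_index(drop=True)
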