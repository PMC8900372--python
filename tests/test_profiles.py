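import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathsig.data_model import ExpressionMatrix, TrajectoryAssignment
from pathsig.errors import ValidationError
from pathsig.profiles import (
    assign_bins,
    build_window_layout,
    profile_from_bins,
    sliding_window_profile,
)


def brute_force_profile(values, bins, layout):
    """Independent per-window mean with nearest-non-empty imputation."""
    n_genes = values.shape[0]
    M = layout.n_windows
    out = np.full((n_genes, M), np.nan)
    counts = np.zeros(M, dtype=int)
    for w, (s, e) in enumerate(zip(layout.starts, layout.ends)):
        mask = (bins >= s) & (bins <= e)
        counts[w] = mask.sum()
        if counts[w]:
            out[:, w] = values[:, mask].mean(axis=1)
    nonempty = [w for w in range(M) if counts[w] > 0]
    for w in range(M):
        if counts[w] == 0:
            # nearest non-empty window; earlier wins ties
            best = min(nonempty, key=lambda v: (abs(v - w), v))
            out[:, w] = out[:, best]
    return out, counts


class TestAssignBins:
    @pytest.mark.parametrize(
        "t,n_bins,expected",
        [(0.0, 101, 0), (1.0, 101, 100), (0.5, 101, 50), (0.999, 10, 9)],
    )
    def test_boundaries_and_midpoint(self, t, n_bins, expected):
        assert assign_bins([t], n_bins)[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assign_bins([1.1], 101)


class TestWindowLayout:
    def test_default_layout_ramp_and_slide(self):
        lay = build_window_layout(101, 20)
        assert lay.n_windows == 92
        assert (lay.starts[0], lay.ends[0]) == (0, 9)  # first window L/2 bins
        assert (lay.starts[10], lay.ends[10]) == (0, 19)  # ramp reaches L
        assert (lay.starts[-1], lay.ends[-1]) == (81, 100)
        lengths = lay.lengths()
        assert list(lengths[:11]) == list(range(10, 21))
        assert (lengths[10:] == 20).all()
        # one-bin slide: consecutive windows share all but one end bin
        assert (np.diff(lay.ends) == 1).all()
        assert (np.diff(lay.starts[10:]) == 1).all()

    def test_minimal_window_size(self):
        lay = build_window_layout(101, 2)
        assert lay.n_windows == 101
        assert (lay.starts[0], lay.ends[0]) == (0, 0)
        assert (lay.lengths() <= 2).all()

    def test_window_larger_than_bins_rejected(self):
        with pytest.raises(ValidationError):
            build_window_layout(10, 20)

    def test_odd_window_rejected(self):
        with pytest.raises(ValidationError):
            build_window_layout(101, 15)

    def test_full_length_only_variant(self):
        lay = build_window_layout(101, 20, full_length_only=True)
        assert (lay.lengths() == 20).all()
        assert lay.ends[-1] == 100


def make_edge(ts, values, edge="e0"):
    cells = [
        TrajectoryAssignment(f"c{i}", edge, float(t), "d") for i, t in enumerate(ts)
    ]
    expr = ExpressionMatrix(
        np.atleast_2d(values), [f"g{j}" for j in range(np.atleast_2d(values).shape[0])],
        [c.cell_id for c in cells],
    )
    return expr, cells


class TestSlidingWindowProfile:
    def test_constant_expression_gives_constant_profile(self):
        lay = build_window_layout(101, 20)
        expr, cells = make_edge([0.1, 0.4, 0.9], [[3.0, 3.0, 3.0]])
        prof = sliding_window_profile(expr, cells, lay)
        assert np.allclose(prof.profile, 3.0)

    def test_single_cell_imputes_everywhere(self):
        lay = build_window_layout(101, 20)
        expr, cells = make_edge([0.0], [[7.0]])
        prof = sliding_window_profile(expr, cells, lay)
        # windows containing bin 0 see the cell; later empty windows copy it
        assert np.allclose(prof.profile, 7.0)
        assert prof.n_cells_per_window[0] == 1
        assert prof.n_cells_per_window[-1] == 0

    def test_two_extreme_cells(self):
        lay = build_window_layout(101, 20)
        expr, cells = make_edge([0.0, 1.0], [[0.0, 10.0]])
        prof = sliding_window_profile(expr, cells, lay).profile[0]
        # windows covering only bin 0 -> 0; only bin 100 -> 10
        assert prof[0] == 0.0 and prof[-1] == 10.0
        # interior empty windows copy the nearest non-empty window
        assert set(np.unique(prof)) == {0.0, 10.0}

    def test_empty_edge_rejected(self):
        lay = build_window_layout(101, 20)
        expr, _ = make_edge([0.5], [[1.0]])
        with pytest.raises(ValidationError):
            sliding_window_profile(expr, [], lay)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_cells = int(rng.integers(1, 25))
        n_genes = int(rng.integers(1, 4))
        n_bins = int(rng.choice([11, 23, 101]))
        L = int(rng.choice([2, 4, 10, 20]))
        if L > n_bins:
            L = 2
        lay = build_window_layout(n_bins, L)
        values = rng.gamma(1.0, 2.0, size=(n_genes, n_cells))
        bins = assign_bins(rng.uniform(0, 1, n_cells), n_bins)
        got, got_counts = profile_from_bins(values, bins, lay)
        want, want_counts = brute_force_profile(values, bins, lay)
        np.testing.assert_array_equal(got_counts, want_counts)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        ts=st.lists(st.floats(0, 1), min_size=1, max_size=15),
        seed=st.integers(0, 100),
    )
    def test_profile_bounded_by_cell_extremes(self, ts, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, size=(2, len(ts)))
        lay = build_window_layout(21, 4)
        bins = assign_bins(np.array(ts), 21)
        prof, _ = profile_from_bins(values, bins, lay)
        for g in range(2):
            assert prof[g].min() >= values[g].min() - 1e-12
            assert prof[g].max() <= values[g].max() + 1e-12

    def test_cell_order_irrelevant(self, rng):
        lay = build_window_layout(101, 20)
        n = 20
        ts = rng.uniform(0, 1, n)
        values = rng.uniform(0, 3, size=(3, n))
        bins = assign_bins(ts, 101)
        perm = rng.permutation(n)
        a, _ = profile_from_bins(values, bins, lay)
        b, _ = profile_from_bins(values[:, perm], bins[perm], lay)
        np.testing.assert_allclose(a, b, atol=1e-12)
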