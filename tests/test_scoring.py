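import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathsig.data_model import ExpressionMatrix, RunConfig, TrajectoryAssignment
from pathsig.errors import ValidationError
from pathsig.lr_database import LRDatabase
from pathsig.scoring import (
    bh_adjust,
    count_to_pvalue,
    interaction_score,
    permutation_pvalues,
    score_interactions,
    select_cluster_pairs,
    summarize,
)
from pathsig.simulate import four_archetype_scenario, generate_dataset


def asg(cell, edge, t, label):
    return TrajectoryAssignment(cell, edge, t, label)


class TestSelectClusterPairs:
    def test_only_time_matched_edges_pair(self):
        assignments = [
            asg("c1", "e1", 0.1, "day11"),
            asg("c2", "e2", 0.2, "day11"),
            asg("c3", "e3", 0.3, "day17"),
        ]
        pairs = select_cluster_pairs(assignments)
        assert {(p.sender, p.receiver) for p in pairs} == {("e1", "e2"), ("e2", "e1")}

    def test_k_edges_same_label_give_k_times_k_minus_1_pairs(self):
        assignments = [asg(f"c{i}", f"e{i}", 0.5, "d") for i in range(4)]
        assert len(select_cluster_pairs(assignments)) == 12

    def test_autocrine_adds_self_pairs(self):
        assignments = [asg("c1", "e1", 0.1, "d"), asg("c2", "e2", 0.2, "d")]
        pairs = select_cluster_pairs(assignments, include_autocrine=True)
        assert len(pairs) == 4
        assert {"e1", "e2"} == {p.sender for p in pairs if p.sender == p.receiver}

    def test_majority_label_decides(self):
        assignments = [
            asg("c1", "e1", 0.1, "day11"),
            asg("c2", "e1", 0.2, "day11"),
            asg("c3", "e1", 0.3, "day17"),
            asg("c4", "e2", 0.4, "day11"),
        ]
        pairs = select_cluster_pairs(assignments)
        assert {(p.sender, p.receiver) for p in pairs} == {("e1", "e2"), ("e2", "e1")}
        assert all(p.time_label == "day11" for p in pairs)


class TestInteractionScore:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (np.ones(92), np.ones(92), 92.0),
            ([1, 2, 3], [4, 5, 6], 32.0),
            ([1, 0], [0, 5], 0.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert interaction_score(np.asarray(x, float), np.asarray(y, float)) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            interaction_score(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 30))
    def test_matches_naive_loop_exactly_on_integers(self, seed, m):
        rng = np.random.default_rng(seed)
        x = rng.integers(-10, 10, m).astype(float)
        y = rng.integers(-10, 10, m).astype(float)
        naive = sum(float(a) * float(b) for a, b in zip(x, y))
        assert interaction_score(x, y) == naive

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_bilinearity(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 20))
        a = float(rng.normal())
        assert interaction_score(x, y) == pytest.approx(interaction_score(y, x))
        assert interaction_score(a * x + z, y) == pytest.approx(
            a * interaction_score(x, y) + interaction_score(z, y), rel=1e-9, abs=1e-9
        )


class TestCountingRule:
    @pytest.mark.parametrize(
        "c,N,expected",
        [(0, 100000, 1e-5), (2, 4, 0.5), (4, 4, 1.0), (1, 10, 0.1)],
    )
    def test_p_value_formula(self, c, N, expected):
        assert count_to_pvalue(c, N) == expected

    def test_beating_every_permutation_gives_floor(self, two_edge_fixture):
        expr, assignments, db = two_edge_fixture
        cfg = RunConfig(n_permutations=200, seed=3)
        pairs, _, obs, p = permutation_pvalues(expr, assignments, db, cfg)
        k = [i for i, q in enumerate(pairs) if (q.sender, q.receiver) == ("A", "B")][0]
        assert p[k, 0] == 1.0 / 200

    def test_constant_gene_scores_p_one(self):
        # every permutation ties the observed score -> p = 1
        cells = [asg(f"c{i}", "A" if i < 5 else "B", 0.1 * i, "t0") for i in range(10)]
        expr = ExpressionMatrix(
            np.ones((2, 10)), ["L", "R"], [c.cell_id for c in cells]
        )
        db = LRDatabase.from_pairs([("L", "R")])
        cfg = RunConfig(n_permutations=50, seed=0)
        _, _, _, p = permutation_pvalues(expr, cells, db, cfg)
        assert (p == 1.0).all()


def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} m p_(j) / j, on sorted p."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_single_p(self):
        q, sig = bh_adjust([0.01], 0.05)
        assert q[0] == pytest.approx(0.01) and sig[0]

    def test_four_equal_spaced(self):
        q, _ = bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_not_significant(self):
        q, sig = bh_adjust([1.0, 1.0, 1.0], 0.05)
        assert not sig.any() and (q == 1.0).all()

    def test_empty_input(self):
        q, sig = bh_adjust([], 0.05)
        assert q.size == 0 and sig.size == 0

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_step_up_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        q, sig = bh_adjust(p, 0.05)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-12)
        np.testing.assert_array_equal(sig, q <= 0.05)


class TestSummarize:
    def test_counts_by_threshold(self):
        results = pd.DataFrame(
            {
                "sender": ["A"] * 3,
                "receiver": ["B"] * 3,
                "time_label": ["t0"] * 3,
                "significant": [True, True, False],
            }
        )
        out = summarize(results)
        assert out.loc[0, "n_significant"] == 2 and out.loc[0, "n_tested"] == 3

    def test_empty_results(self):
        assert summarize(pd.DataFrame(columns=["sender", "receiver", "significant"])).empty


class TestPipelineBehavior:
    def test_seed_determinism(self, two_edge_fixture):
        expr, assignments, db = two_edge_fixture
        cfg = RunConfig(n_permutations=100, seed=42)
        r1, s1 = score_interactions(expr, assignments, db, cfg)
        r2, s2 = score_interactions(expr, assignments, db, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_archetype_discrimination_in_pvalues(self):
        """Co-increasing/co-decreasing planted pairs must earn lower p-values
        than the opposing-trend ones despite identical time-averaged means."""
        expr, assignments, db, truth = generate_dataset(
            four_archetype_scenario(n_decoy_pairs=10), seed=11
        )
        cfg = RunConfig(n_permutations=400, seed=5)
        results, _ = score_interactions(expr, assignments, db, cfg)
        planted = results.merge(
            truth.planted, on=["sender", "receiver", "ligand", "receptor"]
        )
        p_of = planted.set_index("archetype")["p_value"]
        assert max(p_of["co_increase"], p_of["co_decrease"]) < min(
            p_of["opposing_1"], p_of["opposing_2"]
        )

    def test_within_pair_permutation_option(self, two_edge_fixture):
        expr, assignments, db = two_edge_fixture
        cfg = RunConfig(n_permutations=100, seed=0, permute_within_pair=True)
        results, _ = score_interactions(expr, assignments, db, cfg)
        direct = results[(results.sender == "A") & (results.receiver == "B")]
        assert direct.p_value.iloc[0] <= 0.05

    def test_low_confidence_flag_for_tiny_edges(self):
        cells = [
            asg("a1", "A", 0.2, "t0"),
            asg("a2", "A", 0.8, "t0"),
            asg("b1", "B", 0.5, "t0"),
        ]
        expr = ExpressionMatrix(
            np.arange(6, dtype=float).reshape(2, 3), ["L", "R"],
            [c.cell_id for c in cells],
        )
        db = LRDatabase.from_pairs([("L", "R")])
        results, _ = score_interactions(
            expr, cells, db, RunConfig(n_permutations=10, seed=0)
        )
        assert results.low_confidence.all()
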