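import numpy as np
import pytest

from pathsig.data_model import ExpressionMatrix, TrajectoryAssignment
from pathsig.lr_database import LRDatabase


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_two_edge_fixture(n_cells=30, seed=0):
    """Two edges A and B sharing a time label, with one strongly co-varying
    ligand-receptor pair: gene L rises on A, gene R rises on B, both zero
    elsewhere."""
    rng = np.random.default_rng(seed)
    assignments = []
    values = np.zeros((2, 2 * n_cells))
    for k, edge in enumerate(("A", "B")):
        t = rng.uniform(0, 1, n_cells)
        for i, ti in enumerate(t):
            assignments.append(
                TrajectoryAssignment(f"{edge}{i}", edge, float(ti), "t0")
            )
        row = 0 if edge == "A" else 1
        values[row, k * n_cells : (k + 1) * n_cells] = 10 * t
    expr = ExpressionMatrix(values, ["L", "R"], [a.cell_id for a in assignments])
    db = LRDatabase.from_pairs([("L", "R")])
    return expr, assignments, db


@pytest.fixture
def two_edge_fixture():
    return make_two_edge_fixture()
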