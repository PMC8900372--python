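"""Synthetic trajectories with planted ligand-receptor programs.

Expression is generated from the continuous-state HMM emission model used
for trajectory inference: a gene j on edge p has mean

    mu(t) = g_a * exp(-K t) + g_b * (1 - exp(-K t)),   t in [0, 1],

interpolating between the expression levels at the edge's start (g_a) and
end (g_b) at rate K, and cells draw x ~ Normal(mu(t), sigma^2) truncated at
zero (expression is nonnegative; the scoring method makes no distributional
assumption, so the truncation bias is acceptable).

Planted ligand-receptor pairs follow one of four archetypes: the ligand and
receptor trends on their respective edges both rise (``co_increase``), both
fall (``co_decrease``), or oppose each other (``opposing_1``: ligand up,
receptor down; ``opposing_2``: the reverse).  The rate constant is chosen so
that rising and falling trends have identical time-averaged means — the
scenario in which average-expression methods cannot distinguish genuine
co-variation from opposition, but profile scoring can.  Background genes are
constant in time with edge-independent levels, making the model-wide
permutation null exact for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import ExpressionMatrix, TrajectoryAssignment, write_assignment, write_expression
from .errors import ValidationError
from .lr_database import LRDatabase, write_lr_pairs

ARCHETYPES = ("co_increase", "co_decrease", "opposing_1", "opposing_2")

# trend per archetype: (ligand rises?, receptor rises?)
_TRENDS = {
    "co_increase": (True, True),
    "co_decrease": (False, False),
    "opposing_1": (True, False),
    "opposing_2": (False, True),
}


def emission_mean(
    g_a: float | np.ndarray,
    g_b: float | np.ndarray,
    K: float | np.ndarray,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Mean expression at position t on an edge: g_a e^{-Kt} + g_b (1 - e^{-Kt})."""
    t = np.asarray(t, dtype=float)
    if t.size and (np.min(t) < 0.0 or np.max(t) > 1.0):
        raise ValidationError("t must lie in [0, 1]")
    decay = np.exp(-np.asarray(K, dtype=float) * t)
    out = np.asarray(g_a) * decay + np.asarray(g_b) * (1.0 - decay)
    return float(out) if out.ndim == 0 else out


def emission_time_average(g_a: float, g_b: float, K: float) -> float:
    """Closed-form mean of emission_mean over t in [0, 1]."""
    if K == 0:
        return float(g_a)
    phi = (1.0 - np.exp(-K)) / K
    return float(g_b + (g_a - g_b) * phi)


def balanced_rate() -> float:
    """Rate K at which rising and falling trends share a time-averaged mean.

    Solves (1 - e^{-K}) / K = 1/2, making the time average of
    ``emission_mean`` equal to (g_a + g_b) / 2 regardless of direction.
    """
    return float(brentq(lambda k: (1.0 - np.exp(-k)) / k - 0.5, 1e-9, 50.0))


@dataclass
class SimulatedEdgeModel:
    """Per-gene emission parameters for one edge."""

    edge: str
    g_a: np.ndarray
    g_b: np.ndarray
    K: np.ndarray
    sigma: np.ndarray
    sampling_time: str = "t0"

    def __post_init__(self) -> None:
        self.g_a = np.asarray(self.g_a, dtype=float)
        self.g_b = np.asarray(self.g_b, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        shapes = {a.shape for a in (self.g_a, self.g_b, self.K, self.sigma)}
        if len(shapes) != 1:
            raise ValidationError("emission parameter arrays must share a shape")
        if (self.sigma <= 0).any():
            raise ValidationError("sigma must be positive")
        if (self.K < 0).any():
            raise ValidationError("K must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.g_a)


def simulate_cells(
    model: SimulatedEdgeModel,
    n_cells: int,
    t_distribution: str = "uniform",
    beta_params: tuple[float, float] = (0.5, 0.5),
    seed: int | np.random.Generator | None = None,
    cell_prefix: str | None = None,
) -> tuple[np.ndarray, list[TrajectoryAssignment]]:
    """Draw cells along one edge from the emission model.

    Pseudotimes come from Uniform(0, 1) or Beta(a, b) (the default Beta
    parameters concentrate cells near the edge ends, as observed in fitted
    trajectories); expression is Normal(mu(t), sigma^2) truncated at zero.
    Returns a genes x cells block plus assignments.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_distribution == "uniform":
        t = rng.uniform(0.0, 1.0, size=n_cells)
    elif t_distribution == "beta":
        t = rng.beta(*beta_params, size=n_cells)
    else:
        raise ValidationError(f"unknown t_distribution {t_distribution!r}")
    mu = emission_mean(
        model.g_a[:, None], model.g_b[:, None], model.K[:, None], t[None, :]
    )
    x = rng.normal(mu, model.sigma[:, None])
    np.maximum(x, 0.0, out=x)
    prefix = cell_prefix if cell_prefix is not None else f"{model.edge}_c"
    assignments = [
        TrajectoryAssignment(
            cell_id=f"{prefix}{i}",
            edge=model.edge,
            pseudotime=float(t[i]),
            sampling_time=model.sampling_time,
        )
        for i in range(n_cells)
    ]
    return x, assignments


@dataclass
class GroundTruth:
    """The planted interactions of a simulated dataset."""

    planted: pd.DataFrame  # sender, receiver, ligand, receptor, archetype, lag

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls(
            pd.DataFrame(
                columns=["sender", "receiver", "ligand", "receptor", "archetype", "lag"]
            )
        )

    def is_planted(self, sender: str, receiver: str, ligand: str, receptor: str) -> bool:
        p = self.planted
        if p.empty:
            return False
        return bool(
            (
                (p["sender"] == sender)
                & (p["receiver"] == receiver)
                & (p["ligand"] == ligand)
                & (p["receptor"] == receptor)
            ).any()
        )


@dataclass
class Scenario:
    """Configuration of a simulated dataset.

    The default is two time-matched edges with 200 genes and 150 cells per
    edge — small enough that full permutation runs finish in minutes, large
    enough that window profiles are well populated.  ``planted`` lists the
    archetype of each planted ligand-receptor pair (sender -> receiver);
    ``n_decoy_pairs`` adds database pairs between background (constant)
    genes, which are true nulls.  ``expr_low``/``expr_high`` set the planted
    trend's endpoints (normalized expression units); ``noise_sd`` is the
    emission standard deviation for all genes.
    """

    n_genes: int = 200
    n_cells_per_edge: int = 150
    sender_edge: str = "E_send"
    receiver_edge: str = "E_recv"
    time_label: str = "t0"
    planted: tuple[str, ...] = ()
    lags: tuple[int, ...] = ()  # windows of delay on the receptor side
    n_decoy_pairs: int = 40
    expr_low: float = 0.5
    expr_high: float = 5.5
    background_low: float = 0.5
    background_high: float = 3.0
    noise_sd: float = 0.5
    t_distribution: str = "uniform"
    n_bins: int = 101  # converts window lags to pseudotime shifts
    pulse_peak: float = 0.4  # center of the transient program of lagged pairs
    pulse_width: float = 0.08  # kept narrow relative to typical lags so the
    # delayed and undelayed programs are actually distinguishable
    off_edge_level: float | None = None  # planted gene's constant level on the
    # edge it does NOT trend on; None = the trend's time-averaged mean (the
    # equal-per-edge-mean setting that isolates time coordination), a low
    # value makes planted genes cluster-specific (the realistic setting)

    def __post_init__(self) -> None:
        for a in self.planted:
            if a not in ARCHETYPES:
                raise ValidationError(f"unknown archetype {a!r}")
        if self.lags and len(self.lags) != len(self.planted):
            raise ValidationError("lags must be empty or match planted length")
        if 2 * len(self.planted) + 2 * self.n_decoy_pairs > self.n_genes:
            raise ValidationError("planted and decoy genes exceed n_genes")


def null_scenario(**kw) -> Scenario:
    """No planted pairs: every database pair is a true null."""
    return Scenario(planted=(), **kw)


def four_archetype_scenario(copies: int = 1, **kw) -> Scenario:
    """One planted pair per archetype (times ``copies``), equal averages."""
    return Scenario(planted=ARCHETYPES * copies, **kw)


def mixed_scenario(n_planted: int = 10, **kw) -> Scenario:
    """Planted co-increasing pairs amid decoys, for FDR/power evaluation.

    Planted genes are cluster-specific (low baseline on the edge they do not
    trend on): a detectable interaction is one that is both time-coordinated
    and specific to the interacting populations, which is exactly what the
    model-wide permutation null penalizes the absence of.
    """
    kw.setdefault("off_edge_level", kw.get("expr_low", 0.5))
    return Scenario(planted=("co_increase",) * n_planted, **kw)


def lagged_scenario(lag: int, n_planted: int = 4, **kw) -> Scenario:
    """Planted pulse programs whose receptor response trails by ``lag`` windows.

    Lagged pairs carry a transient (pulse) activation rather than a monotone
    trend: a delayed ramp is still a ramp, so a monotone program gives
    warping no phase landmark to recover, whereas a delayed pulse does.
    The decoy count is kept modest: the warp path is estimated from the
    database genes, and it degrades once genes with real dynamics are a
    small minority of them (see the methods note).
    """
    kw.setdefault("n_decoy_pairs", 8)
    return Scenario(
        planted=("co_increase",) * n_planted, lags=(lag,) * n_planted, **kw
    )


def _trend_params(rises: bool, lo: float, hi: float, K: float):
    return (lo, hi, K) if rises else (hi, lo, K)


def pulse_mean(
    lo: float, hi: float, peak: float, width: float, t: np.ndarray
) -> np.ndarray:
    """Transient activation profile: a Gaussian bump from lo to hi at ``peak``.

    Used for lagged planted pairs.  Monotone trends carry no phase landmark —
    any delay of a ramp is still a ramp, so warping has nothing to recover —
    whereas a pulse moves bodily under a delay, which is the situation
    alignment exists for.
    """
    t = np.asarray(t, dtype=float)
    return lo + (hi - lo) * np.exp(-0.5 * ((t - peak) / width) ** 2)


def generate_dataset(
    scenario: Scenario,
    seed: int | np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, list[TrajectoryAssignment], LRDatabase, GroundTruth]:
    """Generate (expression, assignments, LR database, ground truth).

    Background genes are constant in time with the same level on both edges
    (drawn once per gene).  Each planted pair gets a dedicated ligand gene —
    trending on the sender edge, constant at the trend's time-averaged mean
    on the receiver edge — and symmetrically a dedicated receptor gene.  All
    four archetypes share the balanced rate constant, so their time-averaged
    means are identical: methods using only averages cannot separate them.
    A positive lag delays the receptor trend by lag/n_bins pseudotime.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_planted = len(scenario.planted)
    lags = scenario.lags if scenario.lags else (0,) * n_planted
    K_star = balanced_rate()
    avg = 0.5 * (scenario.expr_low + scenario.expr_high)

    lig_names = [f"LIG{i:03d}" for i in range(n_planted)]
    rec_names = [f"REC{i:03d}" for i in range(n_planted)]
    n_background = scenario.n_genes - 2 * n_planted
    bg_names = [f"BG{i:03d}" for i in range(n_background)]
    gene_names = lig_names + rec_names + bg_names

    bg_levels = rng.uniform(
        scenario.background_low, scenario.background_high, size=n_background
    )

    off_level = scenario.off_edge_level if scenario.off_edge_level is not None else avg

    def edge_model(edge: str, is_sender: bool) -> SimulatedEdgeModel:
        g_a = np.empty(scenario.n_genes)
        g_b = np.empty(scenario.n_genes)
        K = np.zeros(scenario.n_genes)
        for i, arch in enumerate(scenario.planted):
            lig_rises, rec_rises = _TRENDS[arch]
            # ligand gene trends on the sender edge only
            if is_sender:
                g_a[i], g_b[i], K[i] = _trend_params(
                    lig_rises, scenario.expr_low, scenario.expr_high, K_star
                )
                g_a[n_planted + i] = g_b[n_planted + i] = off_level
            else:
                g_a[i] = g_b[i] = off_level
                g_a[n_planted + i], g_b[n_planted + i], K[n_planted + i] = _trend_params(
                    rec_rises, scenario.expr_low, scenario.expr_high, K_star
                )
        g_a[2 * n_planted:] = bg_levels
        g_b[2 * n_planted:] = bg_levels
        return SimulatedEdgeModel(
            edge=edge,
            g_a=g_a,
            g_b=g_b,
            K=K,
            sigma=np.full(scenario.n_genes, scenario.noise_sd),
            sampling_time=scenario.time_label,
        )

    blocks, assignments = [], []
    for edge, is_sender in (
        (scenario.sender_edge, True),
        (scenario.receiver_edge, False),
    ):
        model = edge_model(edge, is_sender)
        x, asg = simulate_cells(
            model,
            scenario.n_cells_per_edge,
            t_distribution=scenario.t_distribution,
            seed=rng,
        )
        # lagged pairs carry a transient (pulse) program: the ligand pulses
        # on the sender edge and the receptor repeats the pulse `lag` windows
        # (lag/n_bins pseudotime) later on the receiver edge
        if any(lags):
            t = np.array([a.pseudotime for a in asg])
            for i, lag in enumerate(lags):
                if lag == 0:
                    continue
                row = i if is_sender else n_planted + i
                peak = scenario.pulse_peak + (0.0 if is_sender else lag / scenario.n_bins)
                mu = pulse_mean(
                    scenario.expr_low, scenario.expr_high, peak,
                    scenario.pulse_width, t,
                )
                x[row] = np.maximum(rng.normal(mu, model.sigma[row]), 0.0)
        blocks.append(x)
        assignments.extend(asg)

    expr = ExpressionMatrix(
        np.concatenate(blocks, axis=1),
        gene_names,
        [a.cell_id for a in assignments],
    )

    pairs = list(zip(lig_names, rec_names))
    decoy_genes = rng.choice(
        bg_names, size=2 * scenario.n_decoy_pairs, replace=False
    )
    pairs += [
        (decoy_genes[2 * i], decoy_genes[2 * i + 1])
        for i in range(scenario.n_decoy_pairs)
    ]
    db = LRDatabase.from_pairs(pairs)

    truth = GroundTruth(
        pd.DataFrame(
            {
                "sender": scenario.sender_edge,
                "receiver": scenario.receiver_edge,
                "ligand": lig_names,
                "receptor": rec_names,
                "archetype": list(scenario.planted),
                "lag": list(lags),
            }
        )
        if n_planted
        else GroundTruth.empty().planted
    )
    return expr, assignments, db, truth


def write_dataset(
    expr: ExpressionMatrix,
    assignments: Sequence[TrajectoryAssignment],
    db: LRDatabase,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write expr.csv, meta.tsv, lr.csv, truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expr.csv",
        "assignment": out / "meta.tsv",
        "lr": out / "lr.csv",
        "truth": out / "truth.tsv",
    }
    write_expression(expr, paths["expression"])
    write_assignment(list(assignments), paths["assignment"])
    write_lr_pairs(db, paths["lr"])
    truth.planted.to_csv(paths["truth"], sep="\t", index=False)
    return paths
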