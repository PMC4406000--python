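"""Rank-based association between decision scores and simulated payoffs.

Spearman correlations use mid-ranks (the score distributions are tie-heavy:
many strict free riders share an all-zero schedule). Partial Spearman
correlations rank-transform every variable and then correlate the residuals
of least-squares projections on the controls. Correlation *curves* trace
how the score–payoff association changes with the horizon of an iterated
game: from a single long simulation, the cumulative mean payoff per round
through round k is correlated with each decision score for k = 1..max.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .game_engine import IteratedResult, SimulationPlan, simulate_iterated
from .strategy_data import GameConfig, Population


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] | np.ndarray | None = None,
) -> float:
    """Partial Spearman correlation of x and y given controls.

    All variables are mid-rank transformed; x and y are then residualized
    on the controls (with intercept) by least squares and the residuals are
    correlated. With no controls this reduces exactly to :func:`spearman`.
    """
    if controls is None or len(controls) == 0:
        return spearman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.column_stack([stats.rankdata(np.asarray(c, dtype=float)) for c in controls])
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y and controls must have equal length")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(len(z)), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("collinear controls: partial correlation not defined")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    if np.std(ex) == 0 or np.std(ey) == 0:
        raise ValueError("zero residual variance: partial correlation undefined")
    return float(np.corrcoef(ex, ey)[0, 1])


@dataclass
class CorrelationCurve:
    """Per-round correlations between one score and cumulative payoffs.

    ``rho[k-1]`` / ``partial_rho[k-1]`` refer to the mean payoff per round
    over rounds 1..k; entries are NaN where the correlation is undefined
    (zero rank variance), with the rounds listed in ``degenerate_rounds``.
    """

    score_label: str
    rho: np.ndarray
    partial_rho: np.ndarray
    degenerate_rounds: list[int]

    @property
    def max_round(self) -> int:
        return len(self.rho)


def payoff_curves(
    pop: Population,
    game: GameConfig | None = None,
    plan: SimulationPlan | None = None,
    scores: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
    result: IteratedResult | None = None,
) -> dict[str, CorrelationCurve]:
    """Cumulative score–payoff correlation curves from one iterated run.

    ``scores`` maps score labels to per-individual values in population
    order (a DataFrame works too). Each score's partial correlation controls
    for all the other scores. Pass ``result`` to reuse an existing
    simulation; otherwise one is run from ``plan``.
    """
    if scores is None:
        raise ValueError("scores mapping is required")
    if isinstance(scores, pd.DataFrame):
        scores = {str(c): scores[c].to_numpy() for c in scores.columns}
    score_arrays = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    n = len(pop)
    for k, v in score_arrays.items():
        if len(v) != n:
            raise ValueError(f"score {k!r} has {len(v)} values for {n} individuals")

    if result is None:
        result = simulate_iterated(pop, game, plan)
    t_max = result.plan.iterations

    # cumulative mean payoff per round, all rounds at once: (N, T)
    cum = np.cumsum(result.per_round_mean, axis=1) / np.arange(1, t_max + 1)

    curves: dict[str, CorrelationCurve] = {}
    labels = list(score_arrays)
    for label in labels:
        controls = [score_arrays[o] for o in labels if o != label]
        rho = np.full(t_max, np.nan)
        prho = np.full(t_max, np.nan)
        degenerate: list[int] = []
        for k in range(t_max):
            payoff = cum[:, k]
            try:
                rho[k] = spearman(score_arrays[label], payoff)
                prho[k] = partial_spearman(score_arrays[label], payoff, controls)
            except ValueError:
                degenerate.append(k + 1)
        curves[label] = CorrelationCurve(label, rho, prho, degenerate)
    return curves


def curves_frame(curves: Mapping[str, CorrelationCurve]) -> pd.DataFrame:
    """Long table (round, score_label, rho, partial_rho) for export/plotting."""
    rows = []
    for label, curve in curves.items():
        for k in range(curve.max_round):
            rows.append(
                {
                    "round": k + 1,
                    "score_label": label,
                    "rho": curve.rho[k],
                    "partial_rho": curve.partial_rho[k],
                }
            )
    return pd.DataFrame(rows)


def export_curves(curves: Mapping[str, CorrelationCurve], path: str | Path) -> None:
    curves_frame(curves).to_csv(path, sep="\t", index=False)
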