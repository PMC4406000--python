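"""Public goods game payoff arithmetic and Monte Carlo simulation.

Groups of four are sampled uniformly without replacement within a group and
independently across groups. Two simulation modes mirror the strategy-method
design:

* **one-shot** — one member of each sampled group is designated the
  conditional decision maker and responds (via the conditional schedule) to
  the average unconditional contribution of the other three; the rest
  contribute their unconditional decision.
* **iterated** — round 1 uses the four unconditional decisions; in every
  later round each member responds to the other three members' average
  contribution in the immediately preceding round (memory-1 play, no
  designated roles).

Payoffs follow the linear public goods rule
``payoff_i = E − c_i + m · Σ_j c_j / n``: each round grants a fresh
endowment ``E`` and reported iterated payoffs are per round.

An exhaustive enumeration oracle (:func:`exhaustive_one_shot`) provides
exact expected payoffs for populations small enough to enumerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .strategy_data import DIALECT_DOMAIN, GameConfig, Population, StrategyProfile

RoundingRule = Literal["half_up", "half_even"]


@dataclass(frozen=True)
class SimulationPlan:
    """Monte Carlo settings: group count, iterations (1 = one-shot), seed,
    and the rule that rounds the others' average to a schedule level.

    Averages of three integers have fractional parts in {0, 1/3, 2/3}, so
    the rounding rule only matters at exact halves, which arise for averages
    of the two relevant co-members in two-member cases; ``half_up`` is the
    default and ``half_even`` (banker's rounding) is available.
    """

    n_groups: int = 100_000
    iterations: int = 1
    seed: int = 0
    rounding: RoundingRule = "half_up"

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.rounding not in ("half_up", "half_even"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")


@dataclass(frozen=True)
class PayoffRecord:
    """Per-individual simulated payoff aggregates.

    For one-shot runs ``uncond_*``/``cond_*`` hold role-wise counts and mean
    payoffs and ``total`` is the sum of the two role means. For iterated
    runs ``iterations`` and ``mean_payoff_per_round`` are set instead.
    """

    individual_id: str
    uncond_count: int = 0
    cond_count: int = 0
    uncond_mean: float = float("nan")
    cond_mean: float = float("nan")
    total: float = float("nan")
    iterations: int | None = None
    mean_payoff_per_round: float = float("nan")


def _round_level(x: np.ndarray | float, rule: RoundingRule) -> np.ndarray | float:
    if rule == "half_up":
        return np.floor(np.asarray(x, dtype=float) + 0.5)
    return np.rint(np.asarray(x, dtype=float))


def round_payoffs(contributions: Sequence[float] | np.ndarray, game: GameConfig) -> np.ndarray:
    """Payoffs for one round: ``E − c_i + m·Σc/n`` for each member."""
    c = np.asarray(contributions, dtype=float)
    if c.shape[-1] != game.group_size:
        raise ValueError(
            f"expected {game.group_size} contributions, got {c.shape[-1]}"
        )
    if np.any(c < 0) or np.any(c > game.endowment):
        raise ValueError(f"contributions must lie in [0, {game.endowment}]")
    total = c.sum(axis=-1, keepdims=True)
    return game.endowment - c + game.multiplier * total / game.group_size


def conditional_response(
    profile: StrategyProfile,
    others_average: float,
    rounding: RoundingRule = "half_up",
) -> int:
    """Schedule value at the others' average, rounded to a level and clamped
    to the profile's schedule domain (total: never fails)."""
    lo, hi = profile.domain
    level = int(_round_level(float(others_average), rounding))
    level = min(max(level, lo), hi)
    return int(profile.schedule[level])


def _sample_groups(rng: np.random.Generator, n_individuals: int, n_groups: int) -> np.ndarray:
    """Uniform ordered 4-tuples of distinct individuals, (n_groups, 4).

    Rejection sampling over ordered tuples; rows with duplicate members are
    redrawn, which preserves uniformity over distinct tuples.
    """
    idx = rng.integers(0, n_individuals, size=(n_groups, 4))
    while True:
        s = np.sort(idx, axis=1)
        bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n_individuals, size=(int(bad.sum()), 4))


def _clamped_levels(others_avg: np.ndarray, lo: int, hi: int, rule: RoundingRule) -> np.ndarray:
    lev = _round_level(others_avg, rule).astype(np.int64)
    return np.clip(lev, lo, hi)


@dataclass
class OneShotResult:
    """Aggregated one-shot simulation output with Monte Carlo uncertainty."""

    records: list[PayoffRecord]
    uncond_sem: np.ndarray  # standard error of each unconditional-role mean
    cond_sem: np.ndarray
    plan: SimulationPlan
    #: per-group conservation residual bound check inputs
    total_payoff: float = 0.0
    total_contribution: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "uncond_count": [r.uncond_count for r in self.records],
                "cond_count": [r.cond_count for r in self.records],
                "uncond_mean": [r.uncond_mean for r in self.records],
                "cond_mean": [r.cond_mean for r in self.records],
                "total": [r.total for r in self.records],
            }
        )


@dataclass
class IteratedResult:
    """Aggregated iterated simulation output.

    ``per_round_mean[i, t]`` is individual *i*'s mean payoff in round *t+1*
    averaged over group memberships; cumulative per-round means through any
    round k are recoverable by averaging the first k columns, which is what
    the correlation-curve stage consumes.
    """

    records: list[PayoffRecord]
    per_round_mean: np.ndarray  # (N, iterations)
    memberships: np.ndarray  # (N,) times sampled into a group
    round_total_payoff: np.ndarray  # (iterations,) summed over all groups
    round_total_contribution: np.ndarray  # (iterations,)
    plan: SimulationPlan

    def cumulative_mean(self, k: int) -> np.ndarray:
        """Mean payoff per round over rounds 1..k, per individual."""
        if not 1 <= k <= self.plan.iterations:
            raise ValueError(f"round {k} outside 1..{self.plan.iterations}")
        return self.per_round_mean[:, :k].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "iterations": [r.iterations for r in self.records],
                "memberships": self.memberships,
                "mean_payoff_per_round": [r.mean_payoff_per_round for r in self.records],
            }
        )


def simulate_one_shot(
    pop: Population, game: GameConfig | None = None, plan: SimulationPlan | None = None
) -> OneShotResult:
    """Monte Carlo one-shot games: member 0 of each uniformly ordered group
    is the conditional decision maker, the other three contribute their
    unconditional decision."""
    game = game or pop.game
    plan = plan or SimulationPlan()
    if plan.iterations != 1:
        raise ValueError("one-shot simulation requires plan.iterations == 1")
    n = len(pop)
    if n < game.group_size:
        raise ValueError(f"population of {n} smaller than group size {game.group_size}")

    rng = np.random.default_rng(plan.seed)
    uc = pop.uc_vector().astype(float)
    sched = pop.schedule_matrix()
    lo, hi = DIALECT_DOMAIN[pop.dialect]

    idx = _sample_groups(rng, n, plan.n_groups)
    cond_idx = idx[:, 0]
    uncond_idx = idx[:, 1:]

    c = np.empty((plan.n_groups, 4), dtype=float)
    c[:, 1:] = uc[uncond_idx]
    others_avg = c[:, 1:].mean(axis=1)
    lev = _clamped_levels(others_avg, lo, hi, plan.rounding)
    c[:, 0] = sched[cond_idx, lev]

    total = c.sum(axis=1)
    p = game.endowment - c + game.multiplier * total[:, None] / game.group_size

    cond_cnt = np.bincount(cond_idx, minlength=n).astype(np.int64)
    cond_sum = np.bincount(cond_idx, weights=p[:, 0], minlength=n)
    cond_sq = np.bincount(cond_idx, weights=p[:, 0] ** 2, minlength=n)
    flat_u = uncond_idx.ravel()
    flat_pu = p[:, 1:].ravel()
    unc_cnt = np.bincount(flat_u, minlength=n).astype(np.int64)
    unc_sum = np.bincount(flat_u, weights=flat_pu, minlength=n)
    unc_sq = np.bincount(flat_u, weights=flat_pu**2, minlength=n)

    def _mean(s: np.ndarray, k: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(k > 0, s / np.maximum(k, 1), np.nan)

    def _sem(s: np.ndarray, sq: np.ndarray, k: np.ndarray) -> np.ndarray:
        m = _mean(s, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(k > 1, (sq - k * m**2) / np.maximum(k - 1, 1), np.nan)
            var = np.maximum(var, 0.0)
            return np.sqrt(var / np.maximum(k, 1))

    cond_mean = _mean(cond_sum, cond_cnt)
    unc_mean = _mean(unc_sum, unc_cnt)
    records = [
        PayoffRecord(
            individual_id=prof.individual_id,
            uncond_count=int(unc_cnt[i]),
            cond_count=int(cond_cnt[i]),
            uncond_mean=float(unc_mean[i]),
            cond_mean=float(cond_mean[i]),
            total=float(unc_mean[i] + cond_mean[i]),
        )
        for i, prof in enumerate(pop.profiles)
    ]
    return OneShotResult(
        records=records,
        uncond_sem=_sem(unc_sum, unc_sq, unc_cnt),
        cond_sem=_sem(cond_sum, cond_sq, cond_cnt),
        plan=plan,
        total_payoff=float(p.sum()),
        total_contribution=float(c.sum()),
    )


def simulate_iterated(
    pop: Population, game: GameConfig | None = None, plan: SimulationPlan | None = None
) -> IteratedResult:
    """Monte Carlo iterated games with memory-1 conditional play.

    Round 1 contributions are the unconditional decisions; afterwards every
    member responds to the other three members' previous-round average.
    """
    game = game or pop.game
    plan = plan or SimulationPlan(iterations=2)
    if plan.iterations < 2:
        raise ValueError("iterated simulation requires plan.iterations >= 2")
    n = len(pop)
    if n < game.group_size:
        raise ValueError(f"population of {n} smaller than group size {game.group_size}")

    rng = np.random.default_rng(plan.seed)
    uc = pop.uc_vector().astype(float)
    sched = pop.schedule_matrix()
    lo, hi = DIALECT_DOMAIN[pop.dialect]

    idx = _sample_groups(rng, n, plan.n_groups)
    flat = idx.ravel()
    memberships = np.bincount(flat, minlength=n).astype(np.int64)

    t_max = plan.iterations
    payoff_sum = np.zeros((n, t_max))
    round_total_payoff = np.empty(t_max)
    round_total_contribution = np.empty(t_max)

    c = uc[idx]
    for t in range(t_max):
        total = c.sum(axis=1)
        p = game.endowment - c + game.multiplier * total[:, None] / game.group_size
        payoff_sum[:, t] = np.bincount(flat, weights=p.ravel(), minlength=n)
        round_total_payoff[t] = p.sum()
        round_total_contribution[t] = total.sum()
        if t + 1 < t_max:
            others_avg = (total[:, None] - c) / (game.group_size - 1)
            lev = _clamped_levels(others_avg, lo, hi, plan.rounding)
            c = sched[idx, lev].astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        per_round_mean = np.where(
            memberships[:, None] > 0,
            payoff_sum / np.maximum(memberships[:, None], 1),
            np.nan,
        )
    per_indiv = per_round_mean.mean(axis=1)
    records = [
        PayoffRecord(
            individual_id=prof.individual_id,
            iterations=t_max,
            mean_payoff_per_round=float(per_indiv[i]),
        )
        for i, prof in enumerate(pop.profiles)
    ]
    return IteratedResult(
        records=records,
        per_round_mean=per_round_mean,
        memberships=memberships,
        round_total_payoff=round_total_payoff,
        round_total_contribution=round_total_contribution,
        plan=plan,
    )


MAX_ENUMERABLE = 12


def exhaustive_one_shot(
    pop: Population,
    game: GameConfig | None = None,
    rounding: RoundingRule = "half_up",
) -> list[PayoffRecord]:
    """Exact expected role-wise one-shot payoffs by enumerating every
    4-subset and every conditional-responder assignment uniformly."""
    game = game or pop.game
    n = len(pop)
    if n < game.group_size:
        raise ValueError(f"population of {n} smaller than group size {game.group_size}")
    if n > MAX_ENUMERABLE:
        raise ValueError(
            f"population of {n} too large to enumerate (limit {MAX_ENUMERABLE})"
        )
    uc = pop.uc_vector().astype(float)
    sched = pop.schedule_matrix()
    lo, hi = DIALECT_DOMAIN[pop.dialect]

    cond_sum = np.zeros(n)
    cond_cnt = np.zeros(n, dtype=np.int64)
    unc_sum = np.zeros(n)
    unc_cnt = np.zeros(n, dtype=np.int64)

    for subset in combinations(range(n), game.group_size):
        members = np.array(subset)
        for r in range(game.group_size):
            others = np.delete(members, r)
            avg = uc[others].mean()
            lev = int(np.clip(_round_level(avg, rounding), lo, hi))
            c = uc[members].copy()
            c[r] = sched[members[r], lev]
            p = game.endowment - c + game.multiplier * c.sum() / game.group_size
            cond_sum[members[r]] += p[r]
            cond_cnt[members[r]] += 1
            mask = np.arange(game.group_size) != r
            unc_sum[others] += p[mask]
            unc_cnt[others] += 1

    cond_mean = cond_sum / cond_cnt
    unc_mean = unc_sum / unc_cnt
    return [
        PayoffRecord(
            individual_id=prof.individual_id,
            uncond_count=int(unc_cnt[i]),
            cond_count=int(cond_cnt[i]),
            uncond_mean=float(unc_mean[i]),
            cond_mean=float(cond_mean[i]),
            total=float(unc_mean[i] + cond_mean[i]),
        )
        for i, prof in enumerate(pop.profiles)
    ]


def export_records(records: Sequence[PayoffRecord], path: str | Path, *, delimiter: str = "\t") -> None:
    """Write payoff records as a delimited table."""
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep=delimiter, index=False)
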