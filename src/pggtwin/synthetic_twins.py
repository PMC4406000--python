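"""Synthetic twin populations with known ACE latent structure.

No individual-level strategy records from the two twin experiments were
ever deposited, so downstream stages are exercised on generated populations
whose ground truth is known. Three latent traits drive each individual's
strategy:

* **baseline** — the intercept of the conditional schedule (points),
* **slope** — the degree of conditional cooperation (points per level),
* **free-rider liability** — a standardized threshold trait; individuals
  above the threshold adopt a strict free-rider strategy (all-zero schedule
  and zero unconditional contribution).

Each trait follows the additive ACE construction the twin model assumes:
standardized components A1 (shared by all co-twins), A2 (shared by MZ
co-twins only), C (shared within pair) and E (individual) combine as
``z = sqrt(a²)·(A1+A2)/√2 + sqrt(c²)·C + sqrt(e²)·E``, giving co-twin
correlations of exactly a²+c² (MZ) and a²/2+c² (DZ). Non-free-riders map
the latent line to the schedule as
``C_k = clip(round(baseline + slope·k + noise), 0, E)``; the unconditional
decision is read off the same line at a reference level (default 7, the
typical average contribution observed in the web experiment).

Defaults emulate the web experiment's strategy mixture: ~25% strict free
riders, per-level means/SDs both rising with the others' contribution
level, and a conditionality-slope distribution centred near 1 (most
non-free-riders approximately match the others' contribution). The
near-unit slope mass matters dynamically: matching is what lets
conditional cooperators sustain mutual contributions in iterated play, and
it is the ingredient behind the observed sign flip of the score–payoff
correlation as the game horizon grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .strategy_data import (
    DIALECT_DOMAIN,
    Dialect,
    GameConfig,
    Population,
    STUDY2_GAME,
    StrategyProfile,
    TwinPair,
)

_TRAITS = ("baseline", "slope", "liability")


@dataclass(frozen=True)
class TraitShares:
    """Standardized ACE variance shares of one latent trait (sum to 1)."""

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not math.isclose(self.a2 + self.c2 + self.e2, 1.0, abs_tol=1e-9):
            raise ValueError("variance shares must sum to 1")

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a synthetic twin population.

    Pair counts default to the scale of the twin experiments (~100 MZ and
    ~30 DZ complete pairs); variance shares default to the moderate
    heritability / small shared environment the decision scores showed.
    """

    n_mz: int = 100
    n_dz: int = 30
    baseline_shares: TraitShares = field(default_factory=lambda: TraitShares(0.2, 0.1, 0.7))
    slope_shares: TraitShares = field(default_factory=lambda: TraitShares(0.2, 0.1, 0.7))
    liability_shares: TraitShares = field(default_factory=lambda: TraitShares(0.2, 0.1, 0.7))
    baseline_mean: float = 0.5
    baseline_sd: float = 1.5
    slope_mean: float = 0.8
    slope_sd: float = 0.3
    fr_prevalence: float = 0.25
    noise_sd: float = 2.0
    uc_level: int = 7
    baseline_slope_correlation: float = 0.0
    endowment: int = 20
    dialect: Dialect = "study2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be nonnegative")
        if not 0.0 <= self.fr_prevalence <= 1.0:
            raise ValueError("fr_prevalence must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_sd < 0 or self.slope_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if not -1.0 < self.baseline_slope_correlation < 1.0:
            raise ValueError("baseline_slope_correlation must lie in (-1, 1)")

    @property
    def shares(self) -> dict[str, TraitShares]:
        return {
            "baseline": self.baseline_shares,
            "slope": self.slope_shares,
            "liability": self.liability_shares,
        }


@dataclass
class SyntheticTruth:
    """Latent trait values behind a generated population, plus its config."""

    config: SyntheticConfig
    table: pd.DataFrame  # per individual: ids, zygosity, latents, mapped traits

    def export(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _trait_chol(rho: float) -> np.ndarray:
    """Cholesky factor of the 3-trait correlation matrix (baseline–slope
    correlation ``rho``; liability independent)."""
    corr = np.eye(3)
    corr[0, 1] = corr[1, 0] = rho
    return np.linalg.cholesky(corr)


def _latent_class(
    rng: np.random.Generator,
    n_pairs: int,
    zygosity: Literal["MZ", "DZ"],
    shares: dict[str, TraitShares],
    chol: np.ndarray,
) -> np.ndarray:
    """Standardized latents, shape (n_pairs, 2, 3 traits)."""

    def draw(shape: tuple[int, ...]) -> np.ndarray:
        # correlate the trait axis so phenotypic cross-correlation is exact
        return rng.standard_normal(shape + (3,)) @ chol.T

    a1 = draw((n_pairs,))[:, None, :]  # shared by both co-twins
    if zygosity == "MZ":
        a2 = draw((n_pairs,))[:, None, :]
        a2 = np.broadcast_to(a2, (n_pairs, 2, 3))
    else:
        a2 = draw((n_pairs, 2))
    c = draw((n_pairs,))[:, None, :]
    e = draw((n_pairs, 2))

    sa = np.array([math.sqrt(shares[t].a2) for t in _TRAITS])
    sc = np.array([math.sqrt(shares[t].c2) for t in _TRAITS])
    se = np.array([math.sqrt(shares[t].e2) for t in _TRAITS])
    return sa * (a1 + a2) / math.sqrt(2.0) + sc * c + se * e


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_twin_population(
    config: SyntheticConfig,
) -> tuple[Population, SyntheticTruth]:
    """Generate a twin population with known latent ACE structure.

    Deterministic given ``config`` (including its seed). Returns the
    population (profiles plus twin pairs) and the ground-truth sidecar.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5711])
    )
    chol = _trait_chol(config.baseline_slope_correlation)

    blocks = []
    pairs: list[TwinPair] = []
    for zyg, n_pairs in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        z = _latent_class(rng, n_pairs, zyg, config.shares, chol)  # type: ignore[arg-type]
        for p in range(n_pairs):
            pid = f"{zyg.lower()}{p + 1:04d}"
            members = (f"{pid}a", f"{pid}b")
            pairs.append(TwinPair(pid, zyg, members, "unknown"))  # type: ignore[arg-type]
            for t in range(2):
                blocks.append(
                    {
                        "individual_id": members[t],
                        "pair_id": pid,
                        "zygosity": zyg,
                        "z_baseline": z[p, t, 0],
                        "z_slope": z[p, t, 1],
                        "z_liability": z[p, t, 2],
                    }
                )
    truth = pd.DataFrame(blocks)
    n = len(truth)

    baseline = config.baseline_mean + config.baseline_sd * truth["z_baseline"].to_numpy()
    slope = config.slope_mean + config.slope_sd * truth["z_slope"].to_numpy()
    if config.fr_prevalence > 0:
        threshold = float(sps.norm.ppf(1.0 - config.fr_prevalence))
        is_fr = truth["z_liability"].to_numpy() > threshold
    else:
        is_fr = np.zeros(n, dtype=bool)

    lo, hi = DIALECT_DOMAIN[config.dialect]
    levels = np.arange(lo, hi + 1)
    noise = rng.normal(0.0, config.noise_sd, size=(n, len(levels) + 1))
    raw = baseline[:, None] + slope[:, None] * levels[None, :] + noise[:, :-1]
    sched = np.clip(_round_half_up(raw), 0, config.endowment).astype(np.int64)
    uc_raw = baseline + slope * config.uc_level + noise[:, -1]
    uc = np.clip(_round_half_up(uc_raw), 0, config.endowment).astype(np.int64)
    sched[is_fr] = 0
    uc[is_fr] = 0

    profiles = [
        StrategyProfile(
            individual_id=truth["individual_id"].iloc[i],
            uc=int(uc[i]),
            schedule={int(k): int(v) for k, v in zip(levels, sched[i])},
            dialect=config.dialect,
        )
        for i in range(n)
    ]
    truth["baseline"] = baseline
    truth["slope"] = slope
    truth["is_free_rider"] = is_fr

    game = GameConfig(
        group_size=STUDY2_GAME.group_size,
        multiplier=STUDY2_GAME.multiplier,
        endowment=config.endowment,
    )
    pop = Population(profiles, pairs, game)
    return pop, SyntheticTruth(config, truth)


def simulate_ace_scores(
    n_mz: int,
    n_dz: int,
    shares: TraitShares,
    mean: float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
):
    """Continuous paired scores drawn exactly from the ACE model.

    Returns ``(mz, dz)`` :class:`~pggtwin.twin_genetics.PairedScores`; used
    as ground truth for parameter-recovery checks of the model fit.
    """
    from .twin_genetics import PairedScores

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xACE5]))
    chol = np.eye(3)
    traits = {t: shares for t in _TRAITS}
    out = []
    for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz)):
        z = _latent_class(rng, n_pairs, zyg, traits, chol)[:, :, 0]  # type: ignore[arg-type]
        out.append(PairedScores(zyg, mean + sd * z))  # type: ignore[arg-type]
    return tuple(out)


# ---------------------------------------------------------------------------
# deterministic fixtures


def _perfect_cc(i: str) -> StrategyProfile:
    return StrategyProfile(i, 20, {k: k for k in range(21)}, "study2")


def _free_rider(i: str) -> StrategyProfile:
    return StrategyProfile(i, 0, {k: 0 for k in range(21)}, "study2")


def _pairs_for(profiles: list[StrategyProfile]) -> list[TwinPair]:
    """Pair consecutive profiles as MZ pairs (structure placeholder)."""
    pairs = []
    ids = [p.individual_id for p in profiles]
    for j in range(0, len(ids) - 1, 2):
        pairs.append(TwinPair(f"p{j // 2 + 1:04d}", "MZ", (ids[j], ids[j + 1])))
    if len(ids) % 2:
        pairs.append(TwinPair(f"p{len(ids) // 2 + 1:04d}", "MZ", (ids[-1],)))
    return pairs


FIXTURES = ("homogeneous_cc", "eightperson_oracle", "cc75_fr25", "three_cc_one_fr")


def make_fixture(name: str, n: int = 400) -> Population:
    """Small deterministic populations for tests and worked examples.

    * ``homogeneous_cc`` — 8 perfect conditional cooperators (uc=20, C_k=k).
    * ``eightperson_oracle`` — 8 fixed heterogeneous profiles, small enough
      for exhaustive enumeration.
    * ``cc75_fr25`` — ``n`` individuals: 75% perfect conditional
      cooperators, 25% strict free riders.
    * ``three_cc_one_fr`` — 3 perfect conditional cooperators plus 1 strict
      free rider (the hand-traceable iterated-game fixture).
    """
    if name == "homogeneous_cc":
        profiles = [_perfect_cc(f"cc{i + 1}") for i in range(8)]
    elif name == "three_cc_one_fr":
        profiles = [_perfect_cc(f"cc{i + 1}") for i in range(3)] + [_free_rider("fr1")]
    elif name == "cc75_fr25":
        if n % 4:
            raise ValueError("n must be divisible by 4 for a 75/25 mixture")
        n_cc = 3 * n // 4
        profiles = [_perfect_cc(f"cc{i + 1:04d}") for i in range(n_cc)] + [
            _free_rider(f"fr{i + 1:04d}") for i in range(n - n_cc)
        ]
    elif name == "eightperson_oracle":
        profiles = [
            _perfect_cc("ind1"),
            _free_rider("ind2"),
            StrategyProfile("ind3", 5, {k: 5 for k in range(21)}, "study2"),
            StrategyProfile("ind4", 10, {k: (k + 1) // 2 for k in range(21)}, "study2"),
            StrategyProfile("ind5", 15, {k: min(k + 3, 20) for k in range(21)}, "study2"),
            StrategyProfile("ind6", 20, {k: 0 for k in range(21)}, "study2"),
            StrategyProfile("ind7", 7, {k: 20 - k for k in range(21)}, "study2"),
            StrategyProfile("ind8", 12, {k: 0 if k < 10 else 15 for k in range(21)}, "study2"),
        ]
    else:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return Population(profiles, _pairs_for(profiles), STUDY2_GAME)
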