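"""Composite decision scores, population decision summaries, and trend
regressions of per-level summaries on the others'-contribution level.

Conditional schedules are condensed into *band scores*: the mean conditional
decision over a contiguous block of levels. The group-experiment preset uses
four 5-level bands (LC = C1–C5, MLC = C6–C10, MHC = C11–C15, HC = C16–C20);
the web-experiment preset uses three 7-level bands (LC2 = C0–C6,
MC2 = C7–C13, HC2 = C14–C20). Band scores are the phenotypes passed to the
behaviour-genetic stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .strategy_data import DIALECT_DOMAIN, Dialect, Population, StrategyProfile


@dataclass(frozen=True)
class BandSpec:
    """Named, disjoint level bands jointly covering a schedule domain."""

    dialect: Dialect
    bands: Mapping[str, tuple[int, int]]  # label -> inclusive (lo, hi)

    def __post_init__(self) -> None:
        lo, hi = DIALECT_DOMAIN[self.dialect]
        covered: list[int] = []
        for label, (a, b) in self.bands.items():
            if a > b:
                raise ValueError(f"band {label!r}: empty range ({a}, {b})")
            covered.extend(range(a, b + 1))
        if sorted(covered) != list(range(lo, hi + 1)):
            raise ValueError(
                f"bands must disjointly cover levels {lo}..{hi} of dialect "
                f"{self.dialect!r}"
            )

    @property
    def labels(self) -> list[str]:
        return list(self.bands)

    def levels(self, label: str) -> range:
        a, b = self.bands[label]
        return range(a, b + 1)


STUDY1_BANDS = BandSpec(
    "study1", {"LC": (1, 5), "MLC": (6, 10), "MHC": (11, 15), "HC": (16, 20)}
)
STUDY2_BANDS = BandSpec(
    "study2", {"LC2": (0, 6), "MC2": (7, 13), "HC2": (14, 20)}
)

#: default band preset per schedule dialect
DEFAULT_BANDS: dict[str, BandSpec] = {"study1": STUDY1_BANDS, "study2": STUDY2_BANDS}


@dataclass(frozen=True)
class DecisionScores:
    """Composite scores for one individual: UC plus per-band means."""

    individual_id: str
    uc: float
    bands: Mapping[str, float]

    def as_dict(self) -> dict[str, float]:
        return {"UC": float(self.uc), **{k: float(v) for k, v in self.bands.items()}}


@dataclass(frozen=True)
class DecisionSummary:
    """Per-level mean and SD of conditional decisions across a population."""

    levels: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    uc_mean: float
    uc_sd: float
    n: int

    def band_mean(self, spec: BandSpec, label: str) -> float:
        """Population band-score mean via the per-level means (linearity)."""
        idx = [int(np.flatnonzero(self.levels == k)[0]) for k in spec.levels(label)]
        return float(np.mean(self.mean[idx]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "mean": self.mean, "sd": self.sd})

    def to_table(self, path: str | Path, *, delimiter: str = "\t") -> None:
        """Export in the level/mean/sd layout with a trailing UC row."""
        df = self.to_frame()
        uc = pd.DataFrame({"level": ["UC"], "mean": [self.uc_mean], "sd": [self.uc_sd]})
        pd.concat([df, uc]).to_csv(path, sep=delimiter, index=False)


def compute_scores(profile: StrategyProfile, band_spec: BandSpec | None = None) -> DecisionScores:
    """Band scores (arithmetic mean of the schedule over each band) plus UC."""
    spec = band_spec or DEFAULT_BANDS[profile.dialect]
    if spec.dialect != profile.dialect:
        raise ValueError(
            f"band spec dialect {spec.dialect!r} does not match profile dialect "
            f"{profile.dialect!r}"
        )
    bands = {
        label: float(np.mean([profile.schedule[k] for k in spec.levels(label)]))
        for label in spec.labels
    }
    return DecisionScores(profile.individual_id, float(profile.uc), bands)


def score_table(pop: Population, band_spec: BandSpec | None = None) -> pd.DataFrame:
    """Per-individual score table (rows follow population order)."""
    spec = band_spec or DEFAULT_BANDS[pop.dialect]
    rows = [compute_scores(p, spec).as_dict() for p in pop.profiles]
    df = pd.DataFrame(rows, index=[p.individual_id for p in pop.profiles])
    df.index.name = "individual_id"
    return df


def summarize_population(profiles: Iterable[StrategyProfile] | Population) -> DecisionSummary:
    """Per-level sample mean and sample SD (n−1 denominator) across individuals.

    With a single individual the SD is reported as 0.
    """
    if isinstance(profiles, Population):
        profiles = profiles.profiles
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot summarize an empty population")
    dialects = {p.dialect for p in profiles}
    if len(dialects) != 1:
        raise ValueError(f"profiles mix dialects: {sorted(dialects)}")
    lo, hi = DIALECT_DOMAIN[dialects.pop()]
    levels = np.arange(lo, hi + 1)
    data = np.array([[p.schedule[k] for k in levels] for p in profiles], dtype=float)
    uc = np.array([p.uc for p in profiles], dtype=float)
    ddof = 1 if len(profiles) > 1 else 0
    return DecisionSummary(
        levels=levels,
        mean=data.mean(axis=0),
        sd=data.std(axis=0, ddof=ddof),
        uc_mean=float(uc.mean()),
        uc_sd=float(uc.std(ddof=ddof)),
        n=len(profiles),
    )


def trend_regression(levels: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """OLS of ``values`` on ``levels``; returns (standardized slope, R²).

    The standardized slope of a simple regression equals the Pearson
    correlation, and R² equals its square; both are returned explicitly so
    the identity is part of the contract.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and values must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance in levels or values")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r
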