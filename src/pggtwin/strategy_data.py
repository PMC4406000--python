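"""Domain types for strategy-method decisions and twin structure, plus
tabular I/O.

A *strategy profile* is one participant's full strategy-method record: an
unconditional contribution (UC, made in ignorance of the others) and a
conditional schedule giving the contribution at every possible level of the
other group members' average contribution. Two schedule *dialects* are
supported: ``study1`` covers levels 1–20 (no level-0 decision was
collected), ``study2`` covers levels 0–20.

Twin structure is carried separately: each individual belongs to exactly one
:class:`TwinPair`, which may be incomplete when a co-twin did not
participate. Population-level statistics use all individuals; genetic
analyses use :func:`complete_pairs` to keep only pairs with both co-twins.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

Dialect = Literal["study1", "study2"]

#: schedule level domain per dialect (inclusive)
DIALECT_DOMAIN: dict[str, tuple[int, int]] = {"study1": (1, 20), "study2": (0, 20)}

MAX_LEVEL = 20


class PopulationError(ValueError):
    """Raised for malformed or invalid population tables."""


@dataclass(frozen=True)
class GameConfig:
    """Parameters of a linear public goods game.

    ``group_size`` members each receive ``endowment`` points; the aggregate
    contribution is multiplied by ``multiplier`` and split equally. The
    social-dilemma condition ``1 < multiplier < group_size`` makes
    contributing individually costly (marginal per-capita return below 1)
    but collectively beneficial.
    """

    group_size: int = 4
    multiplier: float = 2.0
    endowment: int = 20
    currency_per_point: float = 20.0  # informational only (yen per point)

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be at least 2")
        if self.endowment <= 0:
            raise ValueError("endowment must be positive")
        if not (1.0 < self.multiplier < self.group_size):
            raise ValueError(
                "social-dilemma condition violated: need 1 < multiplier < group_size"
            )

    @property
    def mpcr(self) -> float:
        """Marginal per-capita return of one contributed point."""
        return self.multiplier / self.group_size


#: on-site group experiment configuration (multiplier 1.6)
STUDY1_GAME = GameConfig(group_size=4, multiplier=1.6, endowment=20)
#: web experiment configuration (aggregate contribution doubled)
STUDY2_GAME = GameConfig(group_size=4, multiplier=2.0, endowment=20)


@dataclass(frozen=True)
class StrategyProfile:
    """One individual's strategy-method record.

    ``schedule`` maps each level ``k`` of the others' average contribution to
    the conditional contribution C_k; it must be total over the dialect's
    domain. All contributions are integer points in ``[0, endowment]``.
    """

    individual_id: str
    uc: int
    schedule: Mapping[int, int]
    dialect: Dialect = "study2"

    def __post_init__(self) -> None:
        lo, hi = self.domain
        got = set(self.schedule)
        want = set(range(lo, hi + 1))
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise PopulationError(
                f"profile {self.individual_id!r}: schedule domain mismatch "
                f"for dialect {self.dialect!r} (missing levels {missing}, "
                f"unexpected levels {extra})"
            )

    @property
    def domain(self) -> tuple[int, int]:
        return DIALECT_DOMAIN[self.dialect]

    def validate(self, endowment: int) -> None:
        """Check all contributions are integers inside [0, endowment]."""
        vals = [("uc", self.uc)] + [(f"c{k}", v) for k, v in self.schedule.items()]
        for name, v in vals:
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise PopulationError(
                    f"profile {self.individual_id!r}: {name} = {v!r} is not an integer"
                )
            if not 0 <= int(v) <= endowment:
                raise PopulationError(
                    f"profile {self.individual_id!r}: {name} = {v} outside [0, {endowment}]"
                )

    def schedule_array(self) -> np.ndarray:
        """Schedule as a dense vector over levels 0..20.

        For the ``study1`` dialect the absent level 0 is clamped to the C1
        decision, matching the response-lookup clamping rule.
        """
        lo, hi = self.domain
        arr = np.empty(MAX_LEVEL + 1, dtype=np.int64)
        for k in range(MAX_LEVEL + 1):
            arr[k] = self.schedule[min(max(k, lo), hi)]
        return arr

    def is_free_rider(self) -> bool:
        """Strict free rider: zero at every conditional level."""
        return all(v == 0 for v in self.schedule.values())


@dataclass(frozen=True)
class TwinPair:
    """A zygosity-labelled twin pair; may hold one or two member ids."""

    pair_id: str
    zygosity: Literal["MZ", "DZ"]
    members: tuple[str, ...]
    sex_composition: str = "unknown"  # annotation only: same/opposite/unknown

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise PopulationError(
                f"pair {self.pair_id!r}: unknown zygosity {self.zygosity!r}"
            )
        if not 1 <= len(self.members) <= 2:
            raise PopulationError(
                f"pair {self.pair_id!r}: must have 1 or 2 members, got {len(self.members)}"
            )
        if len(set(self.members)) != len(self.members):
            raise PopulationError(f"pair {self.pair_id!r}: duplicate member ids")

    @property
    def is_complete(self) -> bool:
        return len(self.members) == 2


@dataclass
class Population:
    """Validated profiles plus twin-pair structure.

    Convenience container bundling what :func:`read_population` returns; the
    profile order is the table row order and is preserved by round trips.
    """

    profiles: list[StrategyProfile]
    twin_pairs: list[TwinPair]
    game: GameConfig = field(default_factory=lambda: STUDY2_GAME)

    def __post_init__(self) -> None:
        ids = [p.individual_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise PopulationError("duplicate individual ids in population")
        in_pairs = [m for pair in self.twin_pairs for m in pair.members]
        if len(set(in_pairs)) != len(in_pairs):
            raise PopulationError("an individual appears in more than one pair")
        if set(ids) != set(in_pairs):
            raise PopulationError("profiles and twin pairs do not cover the same ids")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def dialect(self) -> Dialect:
        dialects = {p.dialect for p in self.profiles}
        if len(dialects) != 1:
            raise PopulationError(f"mixed dialects in population: {sorted(dialects)}")
        return next(iter(dialects))

    def profile_by_id(self, individual_id: str) -> StrategyProfile:
        for p in self.profiles:
            if p.individual_id == individual_id:
                return p
        raise KeyError(individual_id)

    def schedule_matrix(self) -> np.ndarray:
        """(N, 21) int matrix of conditional decisions over levels 0..20."""
        return np.stack([p.schedule_array() for p in self.profiles])

    def uc_vector(self) -> np.ndarray:
        return np.array([p.uc for p in self.profiles], dtype=np.int64)


_BASE_COLUMNS = ["individual_id", "pair_id", "zygosity", "sex_composition", "dialect", "uc"]
_LEVEL_COLUMNS = [f"c{k}" for k in range(MAX_LEVEL + 1)]
COLUMNS = _BASE_COLUMNS + _LEVEL_COLUMNS


def _parse_int(text: str, what: str, row: int, endowment: int) -> int:
    try:
        v = int(text)
    except (TypeError, ValueError):
        raise PopulationError(f"row {row}: {what} = {text!r} is not an integer") from None
    if not 0 <= v <= endowment:
        raise PopulationError(f"row {row}: {what} = {v} outside [0, {endowment}]")
    return v


def read_population(
    path: str | Path | io.TextIOBase,
    game: GameConfig | None = None,
) -> Population:
    """Read a strategy table (CSV or TSV, sniffed from the header line).

    One row per individual with columns ``individual_id, pair_id, zygosity,
    sex_composition, dialect, uc, c0..c20``; ``c0`` is empty for the
    ``study1`` dialect. Errors name the offending 1-based data row.
    """
    game = game or STUDY2_GAME
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline="") as fh:
            return read_population(fh, game)

    first = path.readline()
    if not first:
        raise PopulationError("empty file: missing header")
    delim = "\t" if "\t" in first else ","
    header = [h.strip() for h in first.rstrip("\r\n").split(delim)]
    if header != COLUMNS:
        raise PopulationError(f"unexpected header {header!r}; expected {COLUMNS!r}")

    profiles: list[StrategyProfile] = []
    pair_rows: dict[str, dict] = {}
    pair_order: list[str] = []
    reader = csv.reader(path, delimiter=delim)
    for row_no, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(COLUMNS):
            raise PopulationError(
                f"row {row_no}: expected {len(COLUMNS)} fields, got {len(row)}"
            )
        rec = dict(zip(COLUMNS, (c.strip() for c in row)))
        dialect = rec["dialect"]
        if dialect not in DIALECT_DOMAIN:
            raise PopulationError(f"row {row_no}: unknown dialect {dialect!r}")
        lo, hi = DIALECT_DOMAIN[dialect]
        schedule: dict[int, int] = {}
        for k in range(MAX_LEVEL + 1):
            cell = rec[f"c{k}"]
            if lo <= k <= hi:
                if cell == "":
                    raise PopulationError(f"row {row_no}: missing schedule level c{k}")
                schedule[k] = _parse_int(cell, f"c{k}", row_no, game.endowment)
            elif cell != "":
                raise PopulationError(
                    f"row {row_no}: level c{k} outside dialect {dialect!r} domain "
                    "must be empty"
                )
        uc = _parse_int(rec["uc"], "uc", row_no, game.endowment)
        try:
            prof = StrategyProfile(rec["individual_id"], uc, schedule, dialect)  # type: ignore[arg-type]
        except PopulationError as exc:
            raise PopulationError(f"row {row_no}: {exc}") from None
        profiles.append(prof)

        pid = rec["pair_id"]
        if pid not in pair_rows:
            pair_rows[pid] = {
                "zygosity": rec["zygosity"],
                "sex_composition": rec["sex_composition"],
                "members": [],
            }
            pair_order.append(pid)
        info = pair_rows[pid]
        if rec["zygosity"] != info["zygosity"]:
            raise PopulationError(
                f"row {row_no}: pair {pid!r} has inconsistent zygosity labels"
            )
        info["members"].append(rec["individual_id"])

    try:
        pairs = [
            TwinPair(
                pid,
                pair_rows[pid]["zygosity"],
                tuple(pair_rows[pid]["members"]),
                pair_rows[pid]["sex_composition"],
            )
            for pid in pair_order
        ]
        pop = Population(profiles, pairs, game)
    except PopulationError:
        raise
    for i, p in enumerate(profiles, start=1):
        try:
            p.validate(game.endowment)
        except PopulationError as exc:
            raise PopulationError(f"row {i}: {exc}") from None
    return pop


def write_population(pop: Population, path: str | Path | io.TextIOBase, *, delimiter: str = "\t") -> None:
    """Write the canonical strategy table; inverse of :func:`read_population`."""
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            write_population(pop, fh, delimiter=delimiter)
        return

    pair_of = {m: pair for pair in pop.twin_pairs for m in pair.members}
    writer = csv.writer(path, delimiter=delimiter, lineterminator="\n")
    writer.writerow(COLUMNS)
    for prof in pop.profiles:
        pair = pair_of[prof.individual_id]
        lo, hi = prof.domain
        cells = [
            prof.individual_id,
            pair.pair_id,
            pair.zygosity,
            pair.sex_composition,
            prof.dialect,
            str(prof.uc),
        ]
        for k in range(MAX_LEVEL + 1):
            cells.append(str(prof.schedule[k]) if lo <= k <= hi else "")
        writer.writerow(cells)


def complete_pairs(twin_pairs: Iterable[TwinPair]) -> list[TwinPair]:
    """Keep only pairs in which both co-twins participated, preserving order."""
    return [p for p in twin_pairs if p.is_complete]


def restrict_to_pairs(pop: Population, pairs: Sequence[TwinPair]) -> Population:
    """Sub-population containing exactly the members of ``pairs``."""
    keep = {m for p in pairs for m in p.members}
    profiles = [p for p in pop.profiles if p.individual_id in keep]
    return Population(profiles, list(pairs), pop.game)
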