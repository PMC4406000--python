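"""End-to-end orchestration of the three-stage workflow.

:func:`run_study` takes a population (a strategy table on disk or a
synthetic-generation config) and produces, in order: the per-level decision
summary and trend regressions; composite band scores; intraclass
correlations per score and zygosity; ACE posteriors per decision score
(optionally refitted with informative priors chained from the first fit);
one-shot and iterated payoff simulations; score–payoff rank correlations;
ACE posteriors on payoffs across the iteration ladder; and cumulative
correlation curves. All outputs are plain delimited tables plus a JSON
manifest holding the config, the derived per-stage seeds and wall times, so
any table is regenerable from the manifest alone.

A single top-level seed deterministically derives one sub-seed per stage
(``SeedSequence([seed, stage_index])``), so stages can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import curves_frame, payoff_curves, spearman
from .game_engine import SimulationPlan, simulate_iterated, simulate_one_shot
from .scores import DEFAULT_BANDS, score_table, summarize_population, trend_regression
from .strategy_data import Population, read_population
from .synthetic_twins import SyntheticConfig, generate_twin_population
from .twin_genetics import (
    ACEModelSpec,
    fit_ace,
    intraclass_correlation,
    paired_scores_from_values,
    posterior_to_priors,
)

log = logging.getLogger("pggtwin")

#: stage order; indices double as sub-seed derivation keys
STAGES = (
    "load",
    "summary",
    "scores",
    "icc",
    "ace_scores",
    "ace_chained",
    "one_shot",
    "iterated",
    "payoff_association",
    "ace_payoffs",
    "curves",
)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str = "pggtwin_run"
    seed: int = 0
    mcmc: ACEModelSpec = field(default_factory=ACEModelSpec.reduced)
    one_shot_groups: int = 250_000
    iterated_groups: int = 100_000
    iteration_ladder: tuple[int, ...] = (2, 5, 10, 20, 50, 100)
    curve_iterations: int = 100
    chained_refit: bool = False
    fit_payoff_ace: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic config")
        ladder = tuple(self.iteration_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])) or any(
            k < 1 for k in ladder
        ):
            raise ValueError("iteration ladder must be strictly increasing positive ints")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            from .synthetic_twins import TraitShares

            for key in ("baseline_shares", "slope_shares", "liability_shares"):
                if key in syn:
                    syn[key] = TraitShares(**syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "mcmc" in raw and raw["mcmc"] is not None:
            raw["mcmc"] = ACEModelSpec(**raw["mcmc"])
        if "iteration_ladder" in raw:
            raw["iteration_ladder"] = tuple(raw["iteration_ladder"])
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, idx]).generate_state(1)[0] & 0x7FFFFFFF)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_study(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline; returns a report bundle of in-memory results.

    Tables are also written under ``config.out_dir``. A stage failure aborts
    with the stage name and cause; the manifest written so far marks the
    run incomplete and already-produced tables are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
        "complete": False,
    }
    bundle: dict[str, Any] = {"manifest": manifest}

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = {
            "seed": stage_seed(config.seed, name),
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
        _write_manifest(out, manifest)
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    def run_stage(name: str, fn) -> Any:
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            _write_manifest(out, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        finish_stage(name, t0)
        return result

    # --- load -------------------------------------------------------------
    def _load() -> Population:
        if config.input_path is not None:
            return read_population(config.input_path)
        syn = dataclasses.replace(
            config.synthetic, seed=stage_seed(config.seed, "load")
        )
        pop, truth = generate_twin_population(syn)
        truth.export(out / "truth.tsv")
        return pop

    pop = run_stage("load", _load)
    bundle["population"] = pop
    game = pop.game
    bands = DEFAULT_BANDS[pop.dialect]

    # --- summary + trend regressions --------------------------------------
    def _summary():
        summary = summarize_population(pop)
        summary.to_table(out / "decision_summary.tsv")
        trends = {}
        for stat, vec in (("mean", summary.mean), ("sd", summary.sd)):
            try:
                slope, r2 = trend_regression(summary.levels, vec)
                trends[stat] = {"slope": slope, "r_squared": r2, "degenerate": False}
            except ValueError:
                trends[stat] = {
                    "slope": float("nan"),
                    "r_squared": float("nan"),
                    "degenerate": True,
                }
        pd.DataFrame(trends).T.to_csv(out / "trend_regressions.tsv", sep="\t")
        return summary, trends

    bundle["summary"], bundle["trends"] = run_stage("summary", _summary)

    # --- scores ------------------------------------------------------------
    def _scores():
        table = score_table(pop, bands)
        table.to_csv(out / "scores.tsv", sep="\t")
        return table

    scores = run_stage("scores", _scores)
    bundle["scores"] = scores
    score_labels = list(scores.columns)

    # --- intraclass correlations -------------------------------------------
    def _icc():
        rows = []
        icc_seed = stage_seed(config.seed, "icc")
        for label in score_labels:
            paired = paired_scores_from_values(pop, scores[label].to_dict())
            for zyg in ("MZ", "DZ"):
                ps = paired.get(zyg)
                row = {"score": label, "zygosity": zyg}
                try:
                    est, ci = intraclass_correlation(ps, seed=icc_seed)
                    row.update(icc=est, ci_low=ci[0], ci_high=ci[1], degenerate=False)
                except (ValueError, AttributeError) as exc:
                    row.update(
                        icc=float("nan"),
                        ci_low=float("nan"),
                        ci_high=float("nan"),
                        degenerate=True,
                    )
                rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / "icc.tsv", sep="\t", index=False)
        return df

    bundle["icc"] = run_stage("icc", _icc)

    # --- ACE on decision scores --------------------------------------------
    def _fit_scores(stage: str, spec_for):
        rows = []
        posteriors = {}
        base_seed = stage_seed(config.seed, stage)
        for k, label in enumerate(score_labels):
            paired = paired_scores_from_values(pop, scores[label].to_dict())
            spec = spec_for(label)
            if spec is None:
                continue
            try:
                post = fit_ace(paired["MZ"], paired["DZ"], spec, seed=base_seed + k)
            except ValueError as exc:  # unidentifiable / degenerate scores
                log.warning("ACE fit for %s skipped: %s", label, exc)
                rows.append(
                    pd.DataFrame(
                        [{"score": label, "component": "A", "degenerate": True}]
                    )
                )
                continue
            posteriors[label] = post
            summ = post.share_summary()
            summ.insert(0, "score", label)
            summ["converged"] = post.converged
            rows.append(summ)
            post.export(out / f"{stage}_{label}_draws.tsv")
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        df.to_csv(out / f"{stage}.tsv", sep="\t", index=False)
        return posteriors, df

    bundle["ace_scores"], bundle["ace_scores_table"] = run_stage(
        "ace_scores", lambda: _fit_scores("ace_scores", lambda label: config.mcmc)
    )

    if config.chained_refit:
        chained_specs = {
            label: posterior_to_priors(post)
            for label, post in bundle["ace_scores"].items()
        }
        bundle["ace_chained"], bundle["ace_chained_table"] = run_stage(
            "ace_chained",
            lambda: _fit_scores("ace_chained", lambda label: chained_specs.get(label)),
        )

    # --- simulations --------------------------------------------------------
    def _one_shot():
        plan = SimulationPlan(
            n_groups=config.one_shot_groups,
            iterations=1,
            seed=stage_seed(config.seed, "one_shot"),
        )
        res = simulate_one_shot(pop, game, plan)
        res.to_frame().to_csv(out / "one_shot_payoffs.tsv", sep="\t", index=False)
        return res

    one_shot = run_stage("one_shot", _one_shot)
    bundle["one_shot"] = one_shot

    def _iterated():
        results = {}
        base_seed = stage_seed(config.seed, "iterated")
        for k, t in enumerate(config.iteration_ladder):
            plan = SimulationPlan(
                n_groups=config.iterated_groups, iterations=t, seed=base_seed + k
            )
            results[t] = simulate_iterated(pop, game, plan)
        frames = [r.to_frame() for r in results.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / "iterated_payoffs.tsv", sep="\t", index=False
        )
        return results

    iterated = run_stage("iterated", _iterated)
    bundle["iterated"] = iterated

    # --- score-payoff correlations -----------------------------------------
    def _assoc():
        rows = []
        payoff_sets = {
            "uncond": [r.uncond_mean for r in one_shot.records],
            "cond": [r.cond_mean for r in one_shot.records],
        }
        for t, res in iterated.items():
            payoff_sets[f"it{t}"] = [r.mean_payoff_per_round for r in res.records]
        for label in score_labels:
            for pname, payoffs in payoff_sets.items():
                row = {"score": label, "payoff": pname}
                try:
                    row["rho"] = spearman(scores[label].to_numpy(), payoffs)
                    row["degenerate"] = False
                except ValueError:
                    row["rho"] = float("nan")
                    row["degenerate"] = True
                rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / "score_payoff_rho.tsv", sep="\t", index=False)
        return df

    bundle["payoff_association"] = run_stage("payoff_association", _assoc)

    # --- ACE on payoffs -----------------------------------------------------
    if config.fit_payoff_ace:

        def _ace_payoffs():
            rows = []
            base_seed = stage_seed(config.seed, "ace_payoffs")
            payoff_sets = {
                "uncond": {r.individual_id: r.uncond_mean for r in one_shot.records},
                "cond": {r.individual_id: r.cond_mean for r in one_shot.records},
            }
            for t, res in iterated.items():
                payoff_sets[f"it{t}"] = {
                    r.individual_id: r.mean_payoff_per_round for r in res.records
                }
            for k, (pname, values) in enumerate(payoff_sets.items()):
                paired = paired_scores_from_values(pop, values)
                try:
                    post = fit_ace(
                        paired["MZ"], paired["DZ"], config.mcmc, seed=base_seed + k
                    )
                except ValueError as exc:
                    log.warning("ACE fit for payoff %s skipped: %s", pname, exc)
                    rows.append(
                        pd.DataFrame(
                            [{"payoff": pname, "component": "A", "degenerate": True}]
                        )
                    )
                    continue
                summ = post.share_summary()
                summ.insert(0, "payoff", pname)
                summ["converged"] = post.converged
                rows.append(summ)
            df = pd.concat(rows, ignore_index=True)
            df.to_csv(out / "ace_payoffs.tsv", sep="\t", index=False)
            return df

        bundle["ace_payoffs"] = run_stage("ace_payoffs", _ace_payoffs)

    # --- correlation curves -------------------------------------------------
    def _curves():
        plan = SimulationPlan(
            n_groups=config.iterated_groups,
            iterations=config.curve_iterations,
            seed=stage_seed(config.seed, "curves"),
        )
        curves = payoff_curves(pop, game, plan, scores=scores)
        curves_frame(curves).to_csv(out / "curves.tsv", sep="\t", index=False)
        return curves

    bundle["curves"] = run_stage("curves", _curves)

    manifest["complete"] = True
    _write_manifest(out, manifest)
    return bundle


def _write_manifest(out: Path, manifest: dict[str, Any]) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, default=str)
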