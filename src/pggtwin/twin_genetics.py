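"""Classical twin statistics: intraclass correlations and a Bayesian ACE
variance-components model fitted by MCMC.

The ACE model for a score :math:`Y_{ij}` of twin *i* in family *j* is

.. math:: Y_{ij} = \\mu + A1_j + A2_{ij} + C_j + E_{ij}

where the two additive-genetic half-components A1 and A2 have equal
variance. MZ co-twins share both halves, DZ co-twins share only A1, so the
genetic covariance in MZ pairs is twice that in DZ pairs; C is shared
within every pair and E is individual-specific. Marginalizing the latent
components, co-twin scores are bivariate normal with common variance
:math:`\\sigma^2_A+\\sigma^2_C+\\sigma^2_E` and covariance
:math:`\\sigma^2_A+\\sigma^2_C` (MZ) or
:math:`\\sigma^2_A/2+\\sigma^2_C` (DZ). The sampler works on this
marginal likelihood via sufficient statistics, which makes each MCMC
iteration O(1) in the number of pairs.

Sampling is component-wise random-walk Metropolis with proposal scales
adapted toward a 44% acceptance rate during burn-in only (frozen
afterwards, so the retained chain is a valid Markov chain). Convergence is
checked with the Gelman–Rubin potential scale reduction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .scores import BandSpec, score_table
from .strategy_data import Population, complete_pairs

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PairedScores:
    """Complete pairs of one zygosity with both co-twins' score values."""

    zygosity: Literal["MZ", "DZ"]
    values: np.ndarray  # (n_pairs, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("values must have shape (n_pairs, 2)")
        if not np.all(np.isfinite(v)):
            raise ValueError("paired scores must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_pairs(self) -> int:
        return len(self.values)


def paired_scores_from_values(
    pop: Population, values_by_id: Mapping[str, float]
) -> dict[str, PairedScores]:
    """Pair up an arbitrary per-individual score by zygosity class.

    Only complete pairs whose both members appear in ``values_by_id`` with
    finite values are used.
    """
    out: dict[str, list[list[float]]] = {"MZ": [], "DZ": []}
    for pair in complete_pairs(pop.twin_pairs):
        a, b = pair.members
        if a in values_by_id and b in values_by_id:
            va, vb = float(values_by_id[a]), float(values_by_id[b])
            if math.isfinite(va) and math.isfinite(vb):
                out[pair.zygosity].append([va, vb])
    return {
        z: PairedScores(z, np.array(rows).reshape(-1, 2))  # type: ignore[arg-type]
        for z, rows in out.items()
    }


def paired_scores_from_population(
    pop: Population, score: str, band_spec: BandSpec | None = None
) -> dict[str, PairedScores]:
    """Paired decision scores (``"UC"`` or a band label) by zygosity."""
    table = score_table(pop, band_spec)
    if score not in table.columns:
        raise KeyError(f"unknown score {score!r}; available: {list(table.columns)}")
    return paired_scores_from_values(pop, table[score].to_dict())


# ---------------------------------------------------------------------------
# intraclass correlation


def _double_entry_icc(values: np.ndarray) -> float:
    x = np.concatenate([values[:, 0], values[:, 1]])
    y = np.concatenate([values[:, 1], values[:, 0]])
    if np.std(x) == 0:
        raise ValueError("zero variance: intraclass correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _anova_icc(values: np.ndarray) -> float:
    # one-way random effects ICC(1,1) with k = 2 raters
    n = len(values)
    grand = values.mean()
    pair_means = values.mean(axis=1)
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((values - pair_means[:, None]) ** 2) / n
    denom = msb + msw
    if denom == 0:
        raise ValueError("zero variance: intraclass correlation undefined")
    return float((msb - msw) / denom)


def intraclass_correlation(
    paired: PairedScores,
    interval_method: Literal["bootstrap", "none"] = "bootstrap",
    estimator: Literal["double_entry", "anova"] = "double_entry",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """Within-pair intraclass correlation with a 95% interval.

    The default estimator is the double-entry (pairwise-symmetrized)
    Pearson correlation; an ANOVA one-way random-effects estimator is also
    available. Intervals are bootstrap percentile intervals over pairs.
    """
    if paired.n_pairs < 3:
        raise ValueError("need at least 3 pairs for an intraclass correlation")
    est_fn = _double_entry_icc if estimator == "double_entry" else _anova_icc
    estimate = est_fn(paired.values)
    if interval_method == "none":
        return estimate, None
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, paired.n_pairs, size=paired.n_pairs)
        try:
            stats.append(est_fn(paired.values[idx]))
        except ValueError:  # degenerate resample
            continue
    if not stats:
        raise ValueError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return estimate, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Gelman–Rubin diagnostic


def gelman_rubin(chains_of_draws: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Potential scale reduction factor over m chains of n draws each.

    With chain means :math:`\\bar x_j`, within-chain variance
    :math:`W = \\frac1m \\sum_j s_j^2` (sample variances) and between-chain
    variance :math:`B = \\frac{n}{m-1} \\sum_j (\\bar x_j - \\bar x)^2`,
    the pooled posterior-variance estimate is
    :math:`\\hat V = \\frac{n-1}{n} W + \\frac1n B` and the statistic is
    :math:`\\hat R = \\sqrt{\\hat V / W}`.
    """
    x = np.asarray(chains_of_draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array: chains x draws")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 2:
        raise ValueError("need at least 2 draws per chain")
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    if w == 0.0:
        raise ValueError("degenerate chains: zero within-chain variance")
    b = n * float(np.var(np.mean(x, axis=1), ddof=1))
    v_hat = (n - 1) / n * w + b / n
    return math.sqrt(v_hat / w)


# ---------------------------------------------------------------------------
# ACE model specification and posterior containers


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise ValueError("prior parameters must be finite")
        if self.variance <= 0:
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class ACEModelSpec:
    """Priors and MCMC settings for the Bayesian ACE model.

    Non-informative variant (``prior_kind='uniform'``): each additive
    half-component gets a uniform prior up to ``half_additive_bound`` (so
    the total additive variance ranges up to twice that), and the shared and
    non-shared variances get uniform priors up to ``c_bound``/``e_bound``.
    ``prior_scale`` selects whether those bounds are read on the variance
    scale (default) or the SD scale; the stated bounds are ambiguous between
    the two conventions and both are supported.

    Informative variant (``prior_kind='normal'``): normal priors on the
    total variance components, truncated at zero, typically chained from a
    previous posterior via :func:`posterior_to_priors`.
    """

    prior_kind: Literal["uniform", "normal"] = "uniform"
    prior_scale: Literal["variance", "sd"] = "variance"
    half_additive_bound: float = 50.0
    c_bound: float = 100.0
    e_bound: float = 100.0
    mu_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 100.0))
    a_prior: NormalPrior | None = None  # on total additive variance
    c_prior: NormalPrior | None = None
    e_prior: NormalPrior | None = None
    chains: int = 3
    iterations: int = 100_000
    thinning: int = 100
    burn_in: int = 10_000

    def __post_init__(self) -> None:
        for name in ("half_additive_bound", "c_bound", "e_bound"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for the Gelman-Rubin check")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.prior_kind == "normal" and None in (self.a_prior, self.c_prior, self.e_prior):
            raise ValueError("normal prior_kind requires a_prior, c_prior and e_prior")

    @classmethod
    def reduced(cls, **kwargs) -> "ACEModelSpec":
        """Desk-scale MCMC settings: 3 chains x 10,000, thin 10, burn-in 1,000."""
        kwargs.setdefault("chains", 3)
        kwargs.setdefault("iterations", 10_000)
        kwargs.setdefault("thinning", 10)
        kwargs.setdefault("burn_in", 1_000)
        return cls(**kwargs)

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ACEPosterior:
    """Retained MCMC draws and summaries of the ACE decomposition.

    ``sigma2_a/sigma2_c/sigma2_e/mu`` have shape (chains, draws); the
    standardized shares ``a2/c2/e2`` divide each variance draw by the total,
    so they sum to 1 draw-wise.
    """

    sigma2_a: np.ndarray
    sigma2_c: np.ndarray
    sigma2_e: np.ndarray
    mu: np.ndarray
    spec: ACEModelSpec
    seed: int
    gr: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def a2(self) -> np.ndarray:
        return self.sigma2_a / self._total()

    @property
    def c2(self) -> np.ndarray:
        return self.sigma2_c / self._total()

    @property
    def e2(self) -> np.ndarray:
        return self.sigma2_e / self._total()

    def _total(self) -> np.ndarray:
        return self.sigma2_a + self.sigma2_c + self.sigma2_e

    @property
    def converged(self) -> bool:
        return all(v < 1.1 for v in self.gr.values())

    @property
    def max_gr(self) -> float:
        return max(self.gr.values())

    def share_summary(self) -> pd.DataFrame:
        """Posterior mean and 95% central interval of each standardized share."""
        rows = []
        for label, draws in [("A", self.a2), ("C", self.c2), ("E", self.e2)]:
            flat = draws.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(
                {
                    "component": label,
                    "mean": float(flat.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        df = pd.DataFrame(rows)
        df.insert(1, "gr_max", self.max_gr)
        return df

    def draws_frame(self) -> pd.DataFrame:
        """Long table of retained draws (chain, draw, parameters)."""
        chains, draws = self.mu.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(chains), draws),
                "draw": np.tile(np.arange(draws), chains),
                "sigma2_A": self.sigma2_a.ravel(),
                "sigma2_C": self.sigma2_c.ravel(),
                "sigma2_E": self.sigma2_e.ravel(),
                "mu": self.mu.ravel(),
            }
        )

    def export(self, draws_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.draws_frame().to_csv(draws_path, sep="\t", index=False)
        if summary_path is not None:
            self.share_summary().to_csv(summary_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# marginal likelihood machinery


class _SuffStats:
    __slots__ = ("n", "s1", "s2", "s11", "s22", "s12")

    def __init__(self, values: np.ndarray) -> None:
        y1 = values[:, 0]
        y2 = values[:, 1]
        self.n = float(len(values))
        self.s1 = float(y1.sum())
        self.s2 = float(y2.sum())
        self.s11 = float((y1 * y1).sum())
        self.s22 = float((y2 * y2).sum())
        self.s12 = float((y1 * y2).sum())


def _class_loglik(mu: float, v: float, cov: float, st: _SuffStats) -> float:
    det = v * v - cov * cov
    if det <= 0.0 or v <= 0.0:
        return -math.inf
    e11 = st.s11 - 2.0 * mu * st.s1 + st.n * mu * mu
    e22 = st.s22 - 2.0 * mu * st.s2 + st.n * mu * mu
    e12 = st.s12 - mu * (st.s1 + st.s2) + st.n * mu * mu
    quad = (v * (e11 + e22) - 2.0 * cov * e12) / det
    return -st.n * _LOG_2PI - 0.5 * st.n * math.log(det) - 0.5 * quad


def _identifiability_check(mz: PairedScores, dz: PairedScores) -> None:
    if mz.zygosity != "MZ" or dz.zygosity != "DZ":
        raise ValueError("arguments must be (MZ paired scores, DZ paired scores)")
    if mz.n_pairs == 0 or dz.n_pairs == 0:
        raise ValueError(
            "ACE model needs both MZ and DZ pairs: with a single zygosity "
            "class the additive-genetic and shared-environment variances are "
            "not separately identified"
        )


def fit_ace(
    paired_scores_mz: PairedScores,
    paired_scores_dz: PairedScores,
    model_spec: ACEModelSpec | None = None,
    seed: int = 0,
) -> ACEPosterior:
    """Sample the posterior of the ACE model by Metropolis-within-Gibbs.

    Returns draws of the variance components and mean, standardized shares,
    and the Gelman–Rubin statistic per parameter. Non-convergence (any
    statistic >= 1.1) is flagged on the result, never silent.
    """
    spec = model_spec or ACEModelSpec()
    _identifiability_check(paired_scores_mz, paired_scores_dz)

    st_mz = _SuffStats(paired_scores_mz.values)
    st_dz = _SuffStats(paired_scores_dz.values)
    all_vals = np.concatenate(
        [paired_scores_mz.values.ravel(), paired_scores_dz.values.ravel()]
    )
    data_var = float(np.var(all_vals)) or 1.0
    data_mean = float(np.mean(all_vals))
    n_total = len(all_vals)

    scale_is_sd = spec.prior_scale == "sd"
    if spec.prior_kind == "uniform":
        # parameter 0 is the half-additive component (bound as stated);
        # total additive variance is twice it
        bounds = [
            (0.0, spec.half_additive_bound),
            (0.0, spec.c_bound),
            (0.0, spec.e_bound),
        ]
    else:
        bounds = [(0.0, math.inf)] * 3

    mu_m, mu_v = spec.mu_prior.mean, spec.mu_prior.variance

    def to_variances(theta: list[float]) -> tuple[float, float, float]:
        if spec.prior_kind == "normal":
            return theta[0], theta[1], theta[2]
        if scale_is_sd:
            return 2.0 * theta[0] ** 2, theta[1] ** 2, theta[2] ** 2
        return 2.0 * theta[0], theta[1], theta[2]

    def log_post(theta: list[float], mu: float) -> float:
        sa, sc, se = to_variances(theta)
        if se <= 0.0:
            return -math.inf
        lp = -0.5 * (mu - mu_m) ** 2 / mu_v
        if spec.prior_kind == "normal":
            for t, pr in zip(theta, (spec.a_prior, spec.c_prior, spec.e_prior)):
                lp += -0.5 * (t - pr.mean) ** 2 / pr.variance  # type: ignore[union-attr]
        v = sa + sc + se
        lp += _class_loglik(mu, v, sa + sc, st_mz)
        lp += _class_loglik(mu, v, 0.5 * sa + sc, st_dz)
        return lp

    n_keep = spec.draws_per_chain
    out = {
        k: np.empty((spec.chains, n_keep))
        for k in ("sigma2_a", "sigma2_c", "sigma2_e", "mu")
    }
    acc_totals = np.zeros(4)
    prop_totals = np.zeros(4)

    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x0ACE])
    for chain, ss in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(ss)
        # overdispersed initial values around rough moment estimates
        frac = rng.uniform(0.05, 0.6, size=3)
        init_var = frac / frac.sum() * data_var * rng.uniform(0.5, 1.5)
        if spec.prior_kind == "normal":
            theta = [float(init_var[0]), float(init_var[1]), float(init_var[2])]
        elif scale_is_sd:
            theta = [
                math.sqrt(init_var[0] / 2.0),
                math.sqrt(init_var[1]),
                math.sqrt(init_var[2]),
            ]
        else:
            theta = [init_var[0] / 2.0, float(init_var[1]), float(init_var[2])]
        for i, (lo, hi) in enumerate(bounds):
            theta[i] = min(max(theta[i], lo + 1e-8), hi if math.isfinite(hi) else theta[i])
        mu = data_mean + rng.normal(0.0, math.sqrt(data_var / n_total) * 3)

        if scale_is_sd and spec.prior_kind == "uniform":
            step = [0.3 * math.sqrt(data_var)] * 3
        else:
            step = [0.3 * data_var] * 3
        step.append(1.5 * math.sqrt(data_var / n_total))
        acc = np.zeros(4)
        win = np.zeros(4)

        lp = log_post(theta, mu)
        kept = 0
        normals = rng.standard_normal  # local alias
        uniforms = rng.random
        for it in range(spec.iterations):
            for j in range(4):
                if j < 3:
                    cand = theta[j] + step[j] * normals()
                    lo, hi = bounds[j]
                    if cand < lo or cand > hi:
                        win[j] += 1
                        continue
                    old = theta[j]
                    theta[j] = cand
                    lp_new = log_post(theta, mu)
                    if math.log(uniforms() + 1e-300) < lp_new - lp:
                        lp = lp_new
                        acc[j] += 1
                    else:
                        theta[j] = old
                else:
                    cand_mu = mu + step[3] * normals()
                    lp_new = log_post(theta, cand_mu)
                    if math.log(uniforms() + 1e-300) < lp_new - lp:
                        mu = cand_mu
                        lp = lp_new
                        acc[3] += 1
                win[j] += 1
            # adapt proposal scales during burn-in only
            if it < spec.burn_in and (it + 1) % 100 == 0:
                for j in range(4):
                    rate = acc[j] / max(win[j], 1.0)
                    step[j] *= math.exp(0.6 * (rate - 0.44))
                acc[:] = 0
                win[:] = 0
            elif it == spec.burn_in - 1:
                acc[:] = 0
                win[:] = 0
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                sa, sc, se = to_variances(theta)
                out["sigma2_a"][chain, kept] = sa
                out["sigma2_c"][chain, kept] = sc
                out["sigma2_e"][chain, kept] = se
                out["mu"][chain, kept] = mu
                kept += 1
        acc_totals += acc
        prop_totals += win

    gr = {k: gelman_rubin(out[k]) for k in out}
    acceptance = {
        k: float(a / p) if p else float("nan")
        for k, a, p in zip(out, acc_totals, prop_totals)
    }
    return ACEPosterior(
        sigma2_a=out["sigma2_a"],
        sigma2_c=out["sigma2_c"],
        sigma2_e=out["sigma2_e"],
        mu=out["mu"],
        spec=spec,
        seed=seed,
        gr=gr,
        acceptance=acceptance,
    )


_PRIOR_VARIANCE_FLOOR = 1e-6


def posterior_to_priors(ace_posterior: ACEPosterior) -> ACEModelSpec:
    """Informative spec whose normal priors are centred at the posterior
    means of the variance components (and mean) with the posterior
    variances, truncated at zero for variance components.

    A small variance floor guards against degenerate (constant) posteriors.
    """
    post = ace_posterior

    def prior_of(draws: np.ndarray) -> NormalPrior:
        flat = draws.ravel()
        return NormalPrior(
            float(flat.mean()),
            max(float(flat.var(ddof=1)), _PRIOR_VARIANCE_FLOOR),
        )

    return replace(
        post.spec,
        prior_kind="normal",
        a_prior=prior_of(post.sigma2_a),
        c_prior=prior_of(post.sigma2_c),
        e_prior=prior_of(post.sigma2_e),
        mu_prior=prior_of(post.mu),
    )


def falconer_a2(r_mz: float, r_dz: float) -> float:
    """Falconer's approximation to heritability: 2(r_MZ − r_DZ)."""
    return 2.0 * (r_mz - r_dz)
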