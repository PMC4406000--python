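# Methods

## Game and scoring

The payoff rule is the linear public goods game: member *i* of a group of
n = 4 receives `E − c_i + m·Σ_j c_j / n` per round, with endowment E = 20
points and multiplier m = 1.6 (group-experiment preset) or m = 2.0
(web-experiment preset). `1 < m < n` is enforced: contributing is
individually costly (marginal per-capita return m/n < 1) but collectively
beneficial, which is what makes the game a social dilemma.

Strategy-method records carry an unconditional contribution and a
conditional schedule over the others'-average level. Two schedule dialects
exist: levels 1–20 (the on-site experiment collected no level-0 decision)
and levels 0–20. The type records its domain explicitly; whenever a
simulated others' average rounds to a level outside the domain it is
clamped to the nearest collected level (relevant only for the 1–20 dialect
at level 0).

Band scores are arithmetic means of the schedule over contiguous level
blocks: LC/MLC/MHC/HC (C1–C5, C6–C10, C11–C15, C16–C20) for the 1–20
dialect and LC2/MC2/HC2 (C0–C6, C7–C13, C14–C20) for the 0–20 dialect.
Population summaries use the sample SD (n−1); at the sample sizes involved
(~280–300) the distinction from the population SD is below printed
precision. Trend regressions are OLS of the 20 or 21 per-level summary
values on the level index — summary-level, not individual-level, so the
standardized slope is exactly the Pearson correlation of the summary
vector with the levels.

## Monte Carlo game simulation

Groups of four distinct individuals are sampled uniformly (rejection
sampling over ordered tuples; co-twins may co-occur). One-shot games
designate member 0 of the uniformly ordered tuple as the conditional
decision maker; the other three contribute their unconditional decision and
the responder plays the schedule value at their rounded average. Iterated
games have no designated roles: round 1 uses the four unconditional
decisions, and in round t > 1 every member responds to the other three
members' round-(t−1) average. Each round grants a fresh endowment; iterated
results are payoffs per round.

The others' average is rounded half-up to an integer level by default.
Averages of three integers have fractional parts {0, ⅓, ⅔}, so the rule
only matters at exact halves; banker's rounding is available as an option.

Default problem sizes follow the study protocol: 250,000 groups for
one-shot runs, 100,000 groups per iterated run, iteration ladder
{2, 5, 10, 20, 50, 100}. An exhaustive enumerator over all 4-subsets ×
4 role assignments (guarded at N ≤ 12) provides exact expected payoffs and
serves as the independent oracle for the Monte Carlo path. Conservation
(Σ payoffs = n·E + (m−1)·Σ contributions, each round) is exposed via
per-round totals and asserted in tests at 1e-9 relative tolerance.

## ACE model and sampler

The hierarchical model `Y_ij = μ + A1_j + A2_ij + C_j + E_ij` with equal
half-additive variances is fitted on its *marginal* form: co-twin pairs are
bivariate normal with common variance σ²A + σ²C + σ²E and covariance
σ²A + σ²C (MZ) or σ²A/2 + σ²C (DZ). Sufficient statistics per zygosity
class make each likelihood evaluation O(1) in the number of pairs, so the
full 3 × 100,000-iteration schedule runs in seconds.

Priors (non-informative preset): each half-additive component variance
uniform on (0, 50) — hence total additive variance up to 100, matching the
uniform (0, 100) priors on σ²C and σ²E — and μ normal with mean 0 and
variance 100. The stated bounds are ambiguous between a variance and an SD
parameterization; both are implemented behind `prior_scale`, with the
variance reading as default. The informative preset places normal priors
truncated at zero on the total variance components; `posterior_to_priors`
builds such a spec from a previous posterior's means and variances (with a
1e-6 variance floor against degenerate posteriors), which is how estimates
from one study are chained into the next.

Sampling is component-wise random-walk Metropolis over (σ²A, σ²C, σ²E, μ).
Proposal scales adapt toward 44% acceptance during burn-in only and are
frozen afterwards, so retained draws come from a valid Markov chain. Chains
start from overdispersed random fractions of the phenotypic variance.
Burn-in is discarded before thinning; with the full settings (100,000
iterations, burn-in 10,000, thin 100) each of 3 chains retains 900 draws.
The desk-scale default used throughout the tests and pipeline is
3 × 10,000 with burn-in 1,000 and thinning 10 — also 900 draws per chain.

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor, `R̂ = sqrt(((n−1)/n·W + B/n)/W)`, per parameter; any R̂ ≥ 1.1 flags
the posterior as non-converged (a flagged result, never a silent one). With
a single zygosity class A and C are not separately identified and the fit
refuses to run. Identifiability also bounds interpretation: E absorbs
measurement error and, for simulated payoffs, Monte Carlo sampling noise.

Intraclass correlations use the double-entry (pairwise symmetrized)
Pearson estimator by default, with a one-way ANOVA estimator available;
intervals are bootstrap percentile intervals over pairs (2,000 resamples,
seeded). Falconer's approximation a² ≈ 2(r_MZ − r_DZ) is used as a
closed-form cross-check of the Bayesian fit, not as an estimator.

## Rank-based association

Spearman correlations are Pearson correlations of mid-ranks — the score
distributions are tie-heavy because strict free riders share identical
all-zero schedules. Partial Spearman correlations rank-transform all
variables, residualize on the controls by least squares with intercept, and
correlate residuals; the matrix-inversion form of the first-order partial
is used only as a test oracle. Correlation curves correlate each score with
the cumulative mean payoff per round through round k (k = 1…100) from a
single long iterated run, reproducing how the association's sign flips
with the game horizon. Degenerate cases (zero rank variance) are reported
as flagged NaNs, never silently dropped.

## Synthetic twin populations

Three latent traits drive each individual: schedule **baseline**
(intercept, points), **conditionality slope** (points per level) and
**free-rider liability** (standardized threshold trait). Each trait is
built from standardized components A1/A2/C/E with weights √(a²/2), √(a²/2),
√c², √e² and the same sharing pattern the ACE model assumes, so co-twin
correlations are a² + c² (MZ) and a²/2 + c² (DZ) *by construction* and
recovery tests compare against exact generating values. A configurable
baseline–slope correlation (default 0) is applied at the component level.

Individuals above the liability threshold (default prevalence 0.25,
matching the observed ~25% of all-zero schedules) are strict free riders.
Everyone else maps the latent line to integers:
`C_k = clip(round(baseline + slope·k + noise), 0, 20)` with level-wise
N(0, 2²) noise, and the unconditional decision is read off the same line at
reference level 7 (the typical average contribution in the web experiment).

Default trait scales are baseline ~ N(0.5, 1.5²) and slope ~ N(0.8, 0.3²).
The slope distribution is deliberately centred near 1 rather than at the
population-level mean trend (~0.45 per level): the observed strategy
mixture was dominated by near-perfect matchers, and near-unit slopes are
what let conditional cooperators sustain mutual contributions in iterated
play. With a slope centred at the marginal trend, iterated cooperation
always collapses and the payoff–cooperativeness correlation never turns
positive; centred at 0.8 the generated populations reproduce, at once, the
rising per-level means and SDs (population C0 mean ≈ 0.9, C20 ≈ 11.5), the
sign flip of the correlation ladder (negative through ~10 iterations, ≈0
at 20, +0.3–0.5 at 50–100), and the dip-and-recover pattern of payoff
heritability across the iteration ladder. Clipping and integer rounding
attenuate realized twin correlations relative to the latent shares; the
attenuation is accepted and covered by test tolerances.

What the generator does **not** emulate: demographic covariates, zygosity
misclassification, repeated participation across studies, non-Gaussian
latent traits, and any dependence of strategies on the social setting.
Passing recovery tests therefore show the estimator chain is correct under
the model's own assumptions, not that those assumptions hold in real data.

## Pipeline, determinism, problem sizes

The pipeline derives one sub-seed per stage from the top-level seed via
`SeedSequence([seed, stage_index])`, so stages can be rerun in isolation
and a rerun with the same seed is byte-identical. Every numeric table is a
plain delimited text file regenerable from the JSON manifest (config, seed,
stage seeds, wall times).

Test and acceptance runs use scaled problem sizes chosen for desk-scale
runtime while keeping Monte Carlo error well inside the asserted
tolerances: 200,000 groups for the oracle-equivalence check (3 MC standard
errors), 100,000 groups for iterated runs, 500 + 500 pairs for ACE
recovery (posterior shares within ±0.08 of truth), and 150 MZ + 75 DZ
pairs × 5 replicates for the payoff-heritability ladder. The ladder
comparison is genuinely stochastic at this scale: the dip at 20 iterations
relative to both 2 and 100 holds in a majority of replicates in most seed
sets (per-replicate success ≈ 0.6), mirroring how modest the published
effect itself is (0.30 → 0.15 → 0.19).

## Known limitations

* Memory-1 conditional play only; no longer-memory strategies, no strategy
  updating, no evolutionary dynamics.
* The ACE model assumes bivariate normal scores; band scores of integer
  schedules with a free-rider point mass violate this, as they did in the
  original analyses — E absorbs the misfit.
* No ADE, sex-limitation or multivariate twin models; opposite-sex DZ
  pairs are pooled with same-sex DZ pairs.
* ICC intervals are bootstrap percentile intervals; with ≲30 pairs they
  are noticeably wide and slightly anti-conservative.
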