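# pggtwin

Twin-study analysis of public goods game strategies and their simulated
outcomes: strategy-method decision scoring, Bayesian ACE variance
decomposition by MCMC, and Monte Carlo simulation of one-shot and iterated
games.

## The scientific problem

In an N-person public goods game, four group members each hold an endowment
of E = 20 points; whatever they contribute is multiplied by m (1.6 or 2.0)
and shared equally. Because the marginal per-capita return m/n is below 1,
free riding dominates in a one-shot game, yet most people are *conditional
cooperators* who match the others' contributions. The **strategy method**
elicits each participant's full contingent policy: an unconditional
contribution (UC) plus a conditional schedule C₀…C₂₀ giving the
contribution at every possible level of the others' average.

With monozygotic (MZ) and dizygotic (DZ) twin pairs, the variance of any
score Y can be decomposed with the classical **ACE model**

    Y_ij = μ + A1_j + A2_ij + C_j + E_ij

where the additive-genetic half-components A1, A2 have equal variance and
are both shared by MZ co-twins while DZ co-twins share only A1 (so genetic
covariance halves), C is the shared environment and E the non-shared
environment plus error. Marginally, co-twin scores are bivariate normal
with covariance σ²A + σ²C (MZ) or σ²A/2 + σ²C (DZ); the package samples the
posterior of (σ²A, σ²C, σ²E, μ) by Metropolis-within-Gibbs on this marginal
likelihood, reports standardized shares a² + c² + e² = 1, and checks
convergence with the Gelman–Rubin statistic.

Because strategies only become *behaviour* in interaction, the package also
simulates games among sampled groups of four: one-shot games with a
designated conditional decision maker responding to the other three
members' average unconditional contribution, and iterated games where from
round 2 on every member responds (memory-1) to the others' previous-round
average. Rank correlations between decision scores and simulated payoffs —
including cumulative per-round correlation curves — show how the payoff
consequences of cooperativeness reverse sign as the game horizon grows, and
how the heritability of *outcomes* first dips and then recovers with the
number of iterations.

No individual-level records of the original experiments were deposited, so
the package ships a synthetic twin-population generator whose three latent
traits (schedule baseline, conditionality slope, free-rider liability)
carry exact ACE structure, making every downstream stage testable against
known ground truth.

## Worked example

```
$ pggtwin synth --out pop.tsv --seed 7 --n-mz 100 --n-dz 30
wrote 260 individuals to pop.tsv

$ pggtwin scores pop.tsv
mean-trend standardized slope 0.998 (R^2 0.997)
sd-trend standardized slope 0.996 (R^2 0.992)

$ pggtwin icc pop.tsv --score HC2 --seed 1
HC2 MZ: ICC 0.000 95% CI [-0.196, 0.190]
HC2 DZ: ICC 0.021 95% CI [-0.370, 0.382]

$ pggtwin fit-ace pop.tsv --score HC2 --seed 1
component  gr_max     mean   ci_low  ci_high
        A 1.00121 0.062815 0.001657 0.195773
        C 1.00121 0.060031 0.002695 0.177712
        E 1.00121 0.877154 0.742176 0.978056
```

The first command generates 260 individuals (100 MZ + 30 DZ pairs) with the
default latent structure. The trend slopes confirm the two marginal
signatures of conditional cooperation: per-level mean contributions and
their SDs both rise almost linearly with the others' contribution level.
The intraclass correlations and the ACE fit for the high-contribution band
score (HC2, mean of C₁₄–C₂₀) show what a sample of this size can resolve:
with generating shares a² = 0.2, c² = 0.1 diluted by schedule noise,
integer rounding and the free-rider mixture, the posterior attributes most
variance to E (0.88) with small A and C shares and tight Gelman–Rubin
convergence (max 1.001) — the same orders of magnitude the original twin
experiments reported.

`pggtwin simulate`, `pggtwin curves` and `pggtwin run-all` expose the
simulation and the full pipeline (decision summary → scores → ICC → ACE →
simulations → correlation curves) with a JSON manifest for reproducibility;
see `docs/methods.md` for the model and design details.

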