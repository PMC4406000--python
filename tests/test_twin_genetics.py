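import math

import numpy as np
import pytest

from pggtwin import (
    ACEModelSpec,
    PairedScores,
    TraitShares,
    fit_ace,
    gelman_rubin,
    intraclass_correlation,
    posterior_to_priors,
    simulate_ace_scores,
)
from pggtwin.twin_genetics import NormalPrior, falconer_a2


def paired(values, zyg="MZ"):
    return PairedScores(zyg, np.asarray(values, dtype=float))


class TestICC:
    def test_identical_co_twins_give_one(self):
        ps = paired([[1, 1], [4, 4], [2, 2], [9, 9]])
        est, ci = intraclass_correlation(ps)
        assert est == pytest.approx(1.0)
        assert ci[0] <= 1.0 <= ci[1] + 1e-12

    def test_perfect_anticorrelation_gives_minus_one(self):
        ps = paired([[1, -1], [-2, 2], [3, -3], [0.5, -0.5]])
        est, _ = intraclass_correlation(ps, interval_method="none")
        assert est == pytest.approx(-1.0)

    def test_matches_brute_force_double_entry(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
        est, _ = intraclass_correlation(paired(vals), interval_method="none")
        # independent double-entry computation from raw sums
        x = np.r_[vals[:, 0], vals[:, 1]]
        y = np.r_[vals[:, 1], vals[:, 0]]
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        assert est == pytest.approx(num / den, abs=1e-12)

    def test_anova_estimator_close_on_balanced_data(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(200, 2)) + 2 * rng.normal(size=(200, 1))
        de, _ = intraclass_correlation(paired(vals), interval_method="none")
        an, _ = intraclass_correlation(paired(vals), interval_method="none", estimator="anova")
        assert de == pytest.approx(an, abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            intraclass_correlation(paired([[1, 2], [3, 4]]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            intraclass_correlation(paired([[1, 1]] * 5), interval_method="none")


class TestGelmanRubin:
    def test_identical_chains_formula_limit(self):
        chain = [1.0, 2.0, 3.0, 4.0]
        assert gelman_rubin([chain, chain]) == pytest.approx(math.sqrt(3 / 4))

    def test_hand_computed_fixture(self):
        # chains {1,2,3,4}, {2,3,4,5}: W=5/3, B=2, Vhat=7/4 -> sqrt(1.05)
        stat = gelman_rubin([[1, 2, 3, 4], [2, 3, 4, 5]])
        assert stat == pytest.approx(math.sqrt(1.05), abs=1e-12)

    def test_iid_chains_converge_below_1_1(self):
        rng = np.random.default_rng(0)
        assert gelman_rubin(rng.normal(size=(3, 1000))) < 1.1

    def test_separated_chains_flagged_large(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500)) + np.array([[0.0], [10.0]])
        assert gelman_rubin(chains) > 2.0

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError, match="within-chain"):
            gelman_rubin([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])


class TestModelSpec:
    def test_retained_draw_bookkeeping(self):
        spec = ACEModelSpec()
        assert spec.draws_per_chain == 900
        assert ACEModelSpec.reduced().draws_per_chain == 900

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ACEModelSpec(chains=1)
        with pytest.raises(ValueError):
            ACEModelSpec(burn_in=200_000)
        with pytest.raises(ValueError):
            ACEModelSpec(prior_kind="normal")  # missing component priors


@pytest.fixture(scope="module")
def recovery_fixture():
    """Continuous scores from the ACE model at a2=.4, c2=.2, e2=.4."""
    return simulate_ace_scores(500, 500, TraitShares(0.4, 0.2, 0.4), mean=5.0, sd=3.0, seed=21)


@pytest.fixture(scope="module")
def recovery_posterior(recovery_fixture):
    mz, dz = recovery_fixture
    return fit_ace(mz, dz, ACEModelSpec.reduced(), seed=2)


class TestFitACE:
    def test_parameter_recovery(self, recovery_posterior):
        post = recovery_posterior
        assert post.a2.mean() == pytest.approx(0.4, abs=0.12)
        assert post.c2.mean() == pytest.approx(0.2, abs=0.12)
        assert post.e2.mean() == pytest.approx(0.4, abs=0.12)
        assert post.converged

    def test_shares_sum_to_one_and_lie_in_unit_interval(self, recovery_posterior):
        post = recovery_posterior
        total = post.a2 + post.c2 + post.e2
        assert np.allclose(total, 1.0, atol=1e-12)
        for share in (post.a2, post.c2, post.e2):
            assert np.all((share >= 0) & (share <= 1))

    def test_summaries_lie_inside_intervals(self, recovery_posterior):
        summ = recovery_posterior.share_summary()
        assert (summ["ci_low"] <= summ["mean"]).all()
        assert (summ["mean"] <= summ["ci_high"]).all()

    def test_falconer_cross_check(self, recovery_fixture, recovery_posterior):
        mz, dz = recovery_fixture
        r_mz, _ = intraclass_correlation(mz, interval_method="none")
        r_dz, _ = intraclass_correlation(dz, interval_method="none")
        assert recovery_posterior.a2.mean() == pytest.approx(
            falconer_a2(r_mz, r_dz), abs=0.12
        )

    def test_null_data_attributes_variance_to_e(self):
        rng = np.random.default_rng(17)
        mz = paired(rng.normal(size=(200, 2)), "MZ")
        dz = paired(rng.normal(size=(200, 2)), "DZ")
        post = fit_ace(mz, dz, ACEModelSpec.reduced(), seed=4)
        assert post.a2.mean() < 0.15
        assert post.c2.mean() < 0.15
        assert post.e2.mean() > 0.7

    def test_seed_determinism(self, recovery_fixture):
        mz, dz = recovery_fixture
        spec = ACEModelSpec.reduced(iterations=2_000, burn_in=200)
        a = fit_ace(mz, dz, spec, seed=9)
        b = fit_ace(mz, dz, spec, seed=9)
        assert np.array_equal(a.sigma2_a, b.sigma2_a)
        assert np.array_equal(a.mu, b.mu)

    def test_single_zygosity_class_refused(self, recovery_fixture):
        mz, _ = recovery_fixture
        empty_dz = PairedScores("DZ", np.empty((0, 2)))
        with pytest.raises(ValueError, match="not separately identified"):
            fit_ace(mz, empty_dz)
        with pytest.raises(ValueError, match="MZ paired scores"):
            fit_ace(empty_dz, mz)

    def test_sd_scale_prior_interpretation_agrees(self, recovery_fixture):
        mz, dz = recovery_fixture
        post = fit_ace(
            mz, dz, ACEModelSpec.reduced(prior_scale="sd", half_additive_bound=10.0,
                                         c_bound=15.0, e_bound=15.0), seed=6
        )
        assert post.a2.mean() == pytest.approx(0.4, abs=0.15)

    def test_doubling_draws_is_mc_stable(self, recovery_fixture):
        mz, dz = recovery_fixture
        short = fit_ace(mz, dz, ACEModelSpec.reduced(), seed=13)
        long = fit_ace(mz, dz, ACEModelSpec.reduced(iterations=19_000), seed=13)
        # batch-means Monte Carlo SE of the a2 posterior mean from the short run
        a2 = short.a2.reshape(-1, 30)
        mcse = a2.mean(axis=1).std(ddof=1) / math.sqrt(a2.shape[0])
        assert abs(short.a2.mean() - long.a2.mean()) < 4 * mcse


class TestChainedPriors:
    def test_posterior_to_priors_matches_moments(self, recovery_posterior):
        spec = posterior_to_priors(recovery_posterior)
        assert spec.prior_kind == "normal"
        assert spec.a_prior.mean == pytest.approx(recovery_posterior.sigma2_a.mean())
        assert spec.a_prior.variance > 0

    def test_degenerate_posterior_gets_variance_floor(self, recovery_posterior):
        import copy

        post = copy.copy(recovery_posterior)
        post.sigma2_a = np.full_like(post.sigma2_a, 3.0)
        spec = posterior_to_priors(post)
        assert spec.a_prior.mean == pytest.approx(3.0)
        assert spec.a_prior.variance == pytest.approx(1e-6)

    def test_chained_refit_still_recovers(self, recovery_posterior):
        """Fitting fresh data from the same truth with informative priors
        chained from a previous posterior recovers the shares."""
        spec = posterior_to_priors(recovery_posterior)
        mz2, dz2 = simulate_ace_scores(
            500, 500, TraitShares(0.4, 0.2, 0.4), mean=5.0, sd=3.0, seed=22
        )
        post2 = fit_ace(mz2, dz2, spec, seed=7)
        assert post2.a2.mean() == pytest.approx(0.4, abs=0.12)
        assert post2.c2.mean() == pytest.approx(0.2, abs=0.12)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            NormalPrior(0.0, 0.0)
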