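import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from ebsbm import (
    BlockStats,
    HyperParams,
    OptimizerConfig,
    Partition,
    block_counts,
    eb_theta,
    fit_hyperparams,
    marginal_loglik,
    mle_theta,
    shrinkage_factors,
)

from conftest import random_graph


def diag_stats(counts, caps):
    """BlockStats with given diagonal blocks and empty off-diagonal side."""
    k = len(counts)
    return BlockStats(
        K=k, edge_counts=np.diag(counts).astype(int), capacities=np.diag(caps).astype(int)
    )


class TestMarginalLoglik:
    def test_uniform_prior_closed_form(self):
        # one block, n=3, x=1, alpha=beta=1: marginal is 1/((n+1) C(n,x)) = 1/12
        stats = diag_stats([1], [3])
        assert marginal_loglik(stats, 1, 1, "diagonal") == pytest.approx(np.log(1 / 12), abs=1e-12)

    def test_two_blocks_beta_arithmetic(self):
        # (n=2,x=1) and (n=2,x=0) under the uniform prior: 1/6 * 1/3 = 1/18
        stats = diag_stats([1, 0], [2, 2])
        assert marginal_loglik(stats, 1, 1, "diagonal") == pytest.approx(np.log(1 / 18), abs=1e-12)

    def test_offdiagonal_empty_at_k1(self):
        stats = diag_stats([1], [3])
        assert marginal_loglik(stats, 2.0, 3.0, "offdiagonal") == 0.0

    def test_zero_capacity_block_contributes_zero(self):
        base = marginal_loglik(diag_stats([1], [3]), 1.5, 2.5, "diagonal")
        with_empty = marginal_loglik(diag_stats([1, 0], [3, 0]), 1.5, 2.5, "diagonal")
        assert with_empty == pytest.approx(base, abs=1e-12)

    def test_nonpositive_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            marginal_loglik(diag_stats([1], [3]), 0.0, 1.0, "diagonal")

    @pytest.mark.parametrize("alpha,beta", [(0.7, 1.3), (2.0, 5.0), (10.0, 0.5)])
    def test_matches_numeric_integration_oracle(self, alpha, beta):
        """Per-block marginal equals quad of Bernoulli-product times Beta density."""
        counts, caps = [2, 0, 11], [9, 14, 30]
        stats = diag_stats(counts, caps)
        expected = 0.0
        for x, n in zip(counts, caps):
            val, _ = quad(
                lambda t: t**x * (1 - t) ** (n - x) * beta_dist.pdf(t, alpha, beta), 0, 1
            )
            expected += np.log(val)
        assert marginal_loglik(stats, alpha, beta, "diagonal") == pytest.approx(expected, abs=1e-6)


def grid_oracle_max(counts, caps, grid=400):
    """Dense grid search over log alpha, log beta in [-6, 6]."""
    logs = np.linspace(-6, 6, grid)
    a = np.exp(logs)[:, None, None]
    b = np.exp(logs)[None, :, None]
    x = np.asarray(counts)[None, None, :]
    n = np.asarray(caps)[None, None, :]
    ll = np.sum(betaln(a + x, b + n - x) - betaln(a, b), axis=2)
    return ll.max()


class TestFitHyperparams:
    def test_matches_grid_search_oracle(self):
        counts, caps = [2, 3, 2], [10, 10, 10]
        fit = fit_hyperparams(diag_stats(counts, caps))
        assert fit.loglik_diag >= grid_oracle_max(counts, caps) - 1e-3

    def test_recovers_beta_ratio_from_simulated_blocks(self):
        """alpha/beta ratio recovered from many Beta(2,5)-Binomial blocks."""
        ratios = []
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            thetas = rng.beta(2, 5, size=200)
            counts = rng.binomial(50, thetas)
            fit = fit_hyperparams(diag_stats(counts, np.full(200, 50)))
            ratios.append(fit.hyperparams.alpha0 / fit.hyperparams.beta0)
        assert np.mean(ratios) == pytest.approx(2 / 5, rel=0.25)

    def test_all_zero_counts_pushes_to_degenerate_prior(self):
        """With every block empty the fit approaches the prior concentrated at 0:
        alpha at the lower box bound, beta large, likelihood at its supremum 0."""
        fit = fit_hyperparams(diag_stats([0, 0, 0], [20, 20, 20]))
        assert fit.hyperparams.alpha0 <= 1e-5
        assert fit.hyperparams.beta0 >= 1e3
        assert fit.loglik_diag == pytest.approx(0.0, abs=1e-6)

    def test_never_below_uniform_prior_value(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            caps = rng.integers(0, 40, size=6)
            counts = rng.binomial(caps, 0.3)
            stats = diag_stats(counts, caps)
            fit = fit_hyperparams(stats)
            assert fit.loglik_diag >= marginal_loglik(stats, 1, 1, "diagonal") - 1e-9

    def test_k1_offdiagonal_neutral(self):
        fit = fit_hyperparams(diag_stats([4], [10]))
        assert fit.hyperparams.alpha1 == fit.hyperparams.beta1 == 1.0
        assert fit.loglik_offdiag == 0.0

    def test_hyperparams_invariant_to_relabeling(self):
        g = random_graph(30, 0.4, seed=8)
        labels = np.random.default_rng(9).integers(1, 4, size=30)
        z = Partition(labels, K=3)
        perm = np.array([3, 1, 2])
        z_perm = Partition(perm[labels - 1], K=3)
        f1 = fit_hyperparams(block_counts(g, z))
        f2 = fit_hyperparams(block_counts(g, z_perm))
        assert f1.hyperparams.alpha0 == pytest.approx(f2.hyperparams.alpha0, rel=1e-4)
        assert f1.loglik_diag == pytest.approx(f2.loglik_diag, abs=1e-6)


class TestShrinkage:
    def test_zero_capacity_pure_prior(self):
        stats = diag_stats([0], [0])
        eta = shrinkage_factors(stats, HyperParams(2, 3, 1, 1))
        assert eta[0, 0] == 1.0

    def test_direct_arithmetic(self):
        stats = diag_stats([3], [15])
        eta = shrinkage_factors(stats, HyperParams(2, 3, 1, 1))
        assert eta[0, 0] == pytest.approx(0.25)

    def test_vanishes_for_large_capacity(self):
        stats = diag_stats([0], [10**6])
        eta = shrinkage_factors(stats, HyperParams(2, 3, 1, 1))
        assert eta[0, 0] == pytest.approx(0.0, abs=1e-5)

    def test_strictly_decreasing_in_capacity(self):
        hp = HyperParams(1.5, 2.5, 1, 1)
        etas = [shrinkage_factors(diag_stats([0], [n]), hp)[0, 0] for n in (0, 1, 5, 50, 500)]
        assert all(a > b for a, b in zip(etas, etas[1:]))


class TestEbTheta:
    def test_both_forms_of_posterior_mean_agree(self):
        stats = diag_stats([4], [10])
        hp = HyperParams(2, 3, 1, 1)
        est = eb_theta(stats, hp)
        assert est.theta[0, 0] == pytest.approx(0.4)
        eta = 5 / 15
        assert est.theta[0, 0] == pytest.approx(eta * (2 / 5) + (1 - eta) * (4 / 10))

    def test_zero_capacity_gives_prior_mean(self):
        est = eb_theta(diag_stats([0], [0]), HyperParams(2, 3, 1, 1))
        assert est.theta[0, 0] == pytest.approx(2 / 5)

    def test_vanishing_prior_recovers_mle(self):
        stats = diag_stats([4], [10])
        est = eb_theta(stats, HyperParams(1e-6, 1e-6, 1, 1))
        assert est.theta[0, 0] == pytest.approx(0.4, abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.integers(0, 30),
        extra=st.integers(0, 30),
        a=st.floats(1e-3, 1e3),
        b=st.floats(1e-3, 1e3),
    )
    def test_convex_combination_property(self, x, extra, a, b):
        """Every EB entry lies weakly between the block MLE and the prior mean."""
        n = x + extra
        stats = diag_stats([x], [n])
        hp = HyperParams(a, b, 1, 1)
        est = eb_theta(stats, hp)
        mle = x / n if n else 0.0
        prior_mean = a / (a + b)
        lo, hi = min(mle, prior_mean), max(mle, prior_mean)
        assert lo - 1e-12 <= est.theta[0, 0] <= hi + 1e-12

    def test_relabeling_equivariance(self):
        g = random_graph(24, 0.5, seed=12)
        labels = np.random.default_rng(13).integers(1, 4, size=24)
        perm = np.array([2, 3, 1])
        hp = HyperParams(2.0, 2.0, 0.5, 1.5)
        t1 = eb_theta(block_counts(g, Partition(labels, K=3)), hp).theta
        t2 = eb_theta(block_counts(g, Partition(perm[labels - 1], K=3)), hp).theta
        idx = perm - 1
        assert np.allclose(t2[np.ix_(idx, idx)], t1)
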