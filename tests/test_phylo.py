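"""Tree handling, Brownian likelihood, priors, MCMC, and HPD summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import larvakin as lk
from larvakin.phylo import (
    BMParameters,
    NotPositiveDefiniteError,
    TreeError,
    gamma_to_correlation,
    log_vine_density,
)


class TestReadNewick:
    def test_small_tree_structure(self, small_tree):
        assert sorted(small_tree.tip_labels) == ["A", "B", "C"]
        assert small_tree.n_branches == 4  # 2n - 2 for n = 3

    def test_round_trip_preserves_lengths(self, fixture_tree):
        back = lk.read_newick(fixture_tree.to_newick())
        assert sorted(back.tip_labels) == sorted(fixture_tree.tip_labels)
        # depth of every tip is preserved
        for tree in (fixture_tree, back):
            C = lk.phylo_covariance(tree, np.ones(tree.n_branches))
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-10)

    def test_polytomy_rejected(self):
        with pytest.raises(TreeError, match="polytomy"):
            lk.read_newick("(A:1,B:1,C:1);")

    def test_missing_length_rejected(self):
        with pytest.raises(TreeError, match="branch length"):
            lk.read_newick("((A:1,B):1,C:2);")


class TestPhyloCovariance:
    def test_path_sums_on_small_tree(self, small_tree):
        C = lk.phylo_covariance(small_tree, np.ones(4))
        order = small_tree.tip_labels
        idx = {name: i for i, name in enumerate(order)}
        assert C[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert C[idx["C"], idx["C"]] == pytest.approx(2.0)
        assert C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)

    def test_linearity_in_rates(self, fixture_tree, rng):
        r = rng.gamma(2, 0.5, fixture_tree.n_branches)
        C1 = lk.phylo_covariance(fixture_tree, r)
        C2 = lk.phylo_covariance(fixture_tree, 2 * r)
        np.testing.assert_allclose(C2, 2 * C1)

    def test_rate_length_mismatch(self, small_tree):
        with pytest.raises(ValueError):
            lk.phylo_covariance(small_tree, np.ones(3))


class TestLogLikelihood:
    def test_two_tip_star_reduces_to_independent_normals(self):
        tree = lk.read_newick("(A:0.7,B:1.3);")
        mu = np.array([0.4])
        params = BMParameters(
            branch_rates=np.ones(2), relative_trait_rates=np.ones(1),
            global_scale=1.0, correlation=np.eye(1), root_state=mu,
        )
        Z = np.array([[1.1], [-0.3]])
        order = tree.tip_labels
        lengths = {"A": 0.7, "B": 1.3}
        expected = sum(
            multivariate_normal.logpdf(Z[i, 0], mu[0], lengths[name])
            for i, name in enumerate(order)
        )
        assert lk.log_likelihood(Z, tree, params) == pytest.approx(expected, abs=1e-10)

    def test_matches_kronecker_mvn_oracle(self, rng):
        tree = lk.read_newick("((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.2,E:0.6):0.4);")
        n = tree.n_tips
        for k in (1, 3, 4):
            rates = rng.gamma(2.0, 0.5, tree.n_branches)
            v = rng.dirichlet(np.ones(k)) * k
            R = gamma_to_correlation(rng.normal(0, 0.5, k * (k - 1) // 2), k)
            mu = rng.normal(0, 1, k)
            params = BMParameters(rates, v, float(rng.gamma(2, 0.5)), R, mu)
            Z = rng.normal(0, 1, (n, k))
            C = lk.phylo_covariance(tree, rates)
            Sigma = params.trait_covariance()
            big = np.kron(Sigma, C)
            expected = multivariate_normal.logpdf(
                Z.flatten(order="F"), np.repeat(mu, n), big
            )
            assert lk.log_likelihood(Z, tree, params) == pytest.approx(
                expected, abs=1e-8
            )

    def test_tips_at_root_leave_only_normalizer(self, small_tree):
        mu = np.array([2.0, -1.0])
        params = BMParameters(
            np.ones(4), np.ones(2), 1.0, np.eye(2), mu
        )
        Z = np.tile(mu, (3, 1))
        C = lk.phylo_covariance(small_tree, np.ones(4))
        expected = (
            -0.5 * 3 * 2 * np.log(2 * np.pi)
            - 0.5 * 2 * np.linalg.slogdet(C)[1]
        )
        assert lk.log_likelihood(Z, small_tree, params) == pytest.approx(expected)

    def test_rescaling_invariance(self, fixture_tree, rng):
        # r_b -> c r_b with sigma^2 -> sigma^2 / c leaves the density unchanged
        k = 3
        rates = rng.gamma(2, 0.5, 20)
        R = gamma_to_correlation(rng.normal(0, 0.3, 3), k)
        Z = rng.normal(0, 1, (11, k))
        p1 = BMParameters(rates, np.ones(k), 0.8, R, np.zeros(k))
        p2 = BMParameters(3.0 * rates, np.ones(k), 0.8 / 3.0, R, np.zeros(k))
        assert lk.log_likelihood(Z, fixture_tree, p1) == pytest.approx(
            lk.log_likelihood(Z, fixture_tree, p2), abs=1e-8
        )

    def test_non_pd_sigma_named(self, small_tree):
        params = BMParameters(
            np.ones(4), np.ones(2), 1.0,
            np.array([[1.0, 1.0], [1.0, 1.0]]), np.zeros(2),
        )
        with pytest.raises(NotPositiveDefiniteError, match="Sigma"):
            lk.log_likelihood(np.zeros((3, 2)), small_tree, params)


class TestPriors:
    def test_uced_branch_rate_density(self):
        prior = lk.PriorConfig(family="uced", rate_lambda=10.0)
        rates = np.full(5, 0.1)
        expected = 5 * (np.log(10.0) - 10.0 * 0.1)
        assert prior.log_branch_rate_prior(rates) == pytest.approx(expected)

    def test_ucg_mean_one(self, rng):
        # Gamma(alpha, alpha) has mean 1 for any alpha
        from scipy.stats import gamma as gamma_dist

        prior = lk.PriorConfig(family="ucg", gamma_alpha=2.0)
        r = rng.gamma(2.0, 0.5, 10)
        expected = gamma_dist.logpdf(r, a=2.0, scale=0.5).sum()
        assert prior.log_branch_rate_prior(r) == pytest.approx(expected, abs=1e-10)

    def test_lkj_flat_in_R(self, rng, fixture_tree):
        # under LKJ(1) two valid correlation matrices have equal prior density
        k = 3
        base = dict(
            branch_rates=np.ones(20), relative_trait_rates=np.ones(k),
            global_scale=1.0, root_state=np.zeros(k),
        )
        prior = lk.PriorConfig(root_mean=np.zeros(k), root_sd=np.ones(k))
        R1 = gamma_to_correlation(rng.normal(0, 0.5, 3), k)
        R2 = gamma_to_correlation(rng.normal(0, 0.5, 3), k)
        lp1 = lk.log_prior(BMParameters(correlation=R1, **base), prior)
        lp2 = lk.log_prior(BMParameters(correlation=R2, **base), prior)
        assert lp1 == pytest.approx(lp2, abs=1e-12)

    def test_vine_map_always_positive_definite(self, rng):
        for k in (2, 3, 5):
            for _ in range(50):
                g = rng.normal(0, 2.0, k * (k - 1) // 2)
                R = gamma_to_correlation(g, k)
                assert np.linalg.eigvalsh(R).min() > 0
                np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)

    def test_vine_density_k2_matches_uniform(self):
        # for k=2, LKJ(1) is uniform on (-1,1): density of gamma is
        # (1/2) * dtanh/dgamma
        g = np.array([0.3])
        expected = np.log(0.5) + np.log(1 - np.tanh(0.3) ** 2)
        assert log_vine_density(g, 2) == pytest.approx(expected, abs=1e-12)


class TestHPDInterval:
    def test_constant_samples_zero_width(self):
        lo, hi = lk.hpd_interval(np.ones(100))
        assert lo == hi == 1.0

    def test_uniform_width(self, rng):
        x = rng.uniform(0, 1, 10_000)
        lo, hi = lk.hpd_interval(x, 0.95)
        assert (hi - lo) == pytest.approx(0.95, abs=0.01)

    def test_normal_matches_quantiles(self, rng):
        x = rng.standard_normal(100_000)
        lo, hi = lk.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_contains_median_of_unimodal_sample(self, rng):
        x = rng.gamma(3.0, 1.0, 5000)
        lo, hi = lk.hpd_interval(x, 0.95)
        assert lo <= np.median(x) <= hi

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lk.hpd_interval(np.arange(10))


class TestMCMC:
    def test_prior_only_recovers_exponential_mean(self, fixture_tree):
        post = lk.run_mcmc(
            np.zeros((11, 2)), fixture_tree,
            lk.MCMCConfig(iterations=8000, chains=1, seed=11, thin=4,
                          likelihood=False),
            lk.PriorConfig(family="uced", rate_lambda=10.0),
        )
        assert post.branch_rates.mean() == pytest.approx(0.1, rel=0.05)

    def test_prior_only_recovers_gamma_mean(self, fixture_tree):
        post = lk.run_mcmc(
            np.zeros((11, 2)), fixture_tree,
            lk.MCMCConfig(iterations=8000, chains=1, seed=12, thin=4,
                          likelihood=False),
            lk.PriorConfig(family="ucg", gamma_alpha=2.0),
        )
        assert post.branch_rates.mean() == pytest.approx(1.0, rel=0.05)

    def test_seeded_reproducibility(self, fixture_tree, rng):
        Z = rng.normal(0, 1, (11, 2))
        cfg = lk.MCMCConfig(iterations=400, chains=1, seed=7, thin=2)
        a = lk.run_mcmc(Z, fixture_tree, cfg)
        b = lk.run_mcmc(Z, fixture_tree, cfg)
        np.testing.assert_array_equal(a.global_scale, b.global_scale)
        np.testing.assert_array_equal(a.correlation, b.correlation)

    def test_two_seeds_agree_within_monte_carlo_error(self, fixture_tree):
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        Z = lk.simulate_brownian_traits(
            fixture_tree, np.ones(20), np.ones(2), R, np.zeros(2), seed=1
        ).to_numpy()
        posts = [
            lk.run_mcmc(Z, fixture_tree,
                        lk.MCMCConfig(iterations=2500, chains=1, seed=s, thin=2))
            for s in (101, 202)
        ]
        means = [p.correlation[:, 0, 1].mean() for p in posts]
        ses = [
            p.correlation[:, 0, 1].std() / np.sqrt(max(p.ess["corr[trait_0,trait_1]"], 1))
            for p in posts
        ]
        tol = 2 * np.hypot(*ses) + 0.02
        assert abs(means[0] - means[1]) < tol

    def test_posterior_concentrates_on_planted_correlation(self, fixture_tree):
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        Z = lk.simulate_brownian_traits(
            fixture_tree, np.ones(20), np.ones(2), R, np.zeros(2), seed=5
        ).to_numpy()
        post = lk.run_mcmc(
            Z, fixture_tree, lk.MCMCConfig(iterations=2500, chains=1, seed=3, thin=2)
        )
        lo, hi = lk.hpd_interval(post.correlation[:, 0, 1])
        assert lo < 0.8 < hi or post.correlation[:, 0, 1].mean() > 0.4


class TestSummarizePosterior:
    def test_summary_tables(self, fixture_tree, rng):
        Z = rng.normal(0, 1, (11, 3))
        post = lk.run_mcmc(
            Z, fixture_tree, lk.MCMCConfig(iterations=600, chains=1, seed=2, thin=2)
        )
        summary = lk.summarize_posterior(post, fixture_tree)
        # correlation tables symmetric with unit diagonal
        cm = summary.correlation_mean.to_numpy()
        np.testing.assert_allclose(cm, cm.T)
        np.testing.assert_allclose(np.diag(cm), 1.0)
        assert (summary.correlation_hpd_lo.to_numpy()
                <= summary.correlation_hpd_hi.to_numpy()).all()
        # annotated newick keeps the topology and carries rate annotations
        assert "[&rate=" in summary.annotated_newick
        stripped = lk.read_newick(
            "".join(
                part.split("]")[-1] if "]" in part else part
                for part in summary.annotated_newick.replace("[&rate=", "[").split("[")
            )
        )
        assert sorted(stripped.tip_labels) == sorted(fixture_tree.tip_labels)
        assert len(summary.trait_rates) == 3
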