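import numpy as np
import pytest
from scipy.stats import multivariate_normal

from famlipid.heritability import (
    BlockEigh,
    MCMCConfig,
    fit_polygenic_ml,
    gelman_rubin,
    gibbs_gaussian,
    gibbs_probit,
    summarize_posterior,
)
from famlipid.pedigree import kinship_matrix, relationship_matrix
from famlipid.simulate import (
    SimulationConfig,
    simulate_breeding_values,
    simulate_disease_status,
    simulate_pedigree,
)


class TestBlockEigh:
    def test_rotations_are_orthogonal(self, cohort300):
        _, A, eig = cohort300
        v = np.random.default_rng(0).standard_normal(eig.n)
        assert np.allclose(eig.from_eigen(eig.to_eigen(v)), v)
        # reconstruct A = U diag(lam) U'
        w = eig.to_eigen(v)
        assert np.allclose(eig.from_eigen(eig.lam * w), A @ v)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            BlockEigh(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPolygenicML:
    def test_unrelated_cohort_is_uninformative(self, rng):
        y = rng.normal(size=400)
        vc = fit_polygenic_ml(y, A=np.eye(400))
        assert vc.boundary  # profile is flat/boundary: no resemblance info

    def test_noiseless_limit(self, cohort300, rng):
        _, A, eig = cohort300
        idx = np.arange(200)
        g = simulate_breeding_values(A=A[np.ix_(idx, idx)], sigma_g2=1.0, seed=rng)
        vc = fit_polygenic_ml(g, A=A[np.ix_(idx, idx)])
        assert vc.h2 >= 0.99

    def test_matches_dense_mvn_loglik(self, rng):
        """ML profile log-likelihood at the optimum equals the dense
        multivariate-normal log-density with the fitted parameters."""
        cfg = SimulationConfig(n_families=6, sibship=(2, 3), seed=31)
        ped = simulate_pedigree(cfg, seed=31)
        A = relationship_matrix(kinship_matrix(ped))
        n = len(ped)
        assert n <= 30
        g = simulate_breeding_values(A=A, sigma_g2=0.5, seed=rng)
        y = 1.0 + g + rng.normal(0, np.sqrt(0.5), n)
        vc = fit_polygenic_ml(y, A=A, method="ML")
        X = np.ones((n, 1))
        dense = multivariate_normal(
            mean=(X @ vc.beta), cov=vc.sigma_g2 * A + vc.sigma_e2 * np.eye(n)
        ).logpdf(y)
        assert vc.loglik == pytest.approx(dense, abs=1e-8)

    def test_ml_optimum_beats_neighbours(self, cohort300, rng):
        _, A, eig = cohort300
        g = simulate_breeding_values(eig=eig, sigma_g2=0.42, seed=rng)
        y = g + rng.normal(0, np.sqrt(0.58), eig.n)
        vc = fit_polygenic_ml(y, A=A, method="ML", eig=eig)

        def ll_at(h):
            from famlipid.heritability import _profile_loglik

            yt, Xt = eig.to_eigen(y), eig.to_eigen(np.ones((eig.n, 1)))
            return _profile_loglik(h, eig.lam, yt, Xt, reml=False)[0]

        assert ll_at(vc.h2) >= ll_at(vc.h2 + 0.02) - 1e-9
        assert ll_at(vc.h2) >= ll_at(vc.h2 - 0.02) - 1e-9

    def test_recovery_of_planted_h2(self, cohort300, rng):
        _, A, eig = cohort300
        ests = []
        for _ in range(20):
            g = simulate_breeding_values(eig=eig, sigma_g2=0.42, seed=rng)
            y = g + rng.normal(0, np.sqrt(0.58), eig.n)
            ests.append(fit_polygenic_ml(y, A=A, eig=eig).h2)
        assert abs(np.mean(ests) - 0.42) < 0.04

    def test_se_reported_off_boundary(self, cohort300, rng):
        _, A, eig = cohort300
        g = simulate_breeding_values(eig=eig, sigma_g2=0.5, seed=rng)
        y = g + rng.normal(0, np.sqrt(0.5), eig.n)
        vc = fit_polygenic_ml(y, A=A, eig=eig)
        assert vc.se_h2 is not None and 0.0 < vc.se_h2 < 0.3


class TestMCMCConfig:
    def test_retained_counts(self):
        assert MCMCConfig(400_000, 200_000, 40).retained == 5000
        assert MCMCConfig(50_000, 25_000, 25).retained == 1000

    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestGibbsGaussian:
    def test_prior_only_run_recovers_prior_moments(self):
        """With no data rows the sampler draws the scaled-inverse-chi-square
        prior: mean = nu*s0^2/(nu-2) for nu=5, s0^2=0.5."""
        cfg = MCMCConfig(n_iter=30_000, burn_in=2_000, thin=1, n_chains=2,
                         seed=8, prior_scale=0.5)
        res = gibbs_gaussian(np.zeros(0), cfg=cfg)
        prior_mean = 5 * 0.5 / 3
        assert res.samples("sigma_g2").mean() == pytest.approx(prior_mean, rel=0.05)
        assert res.samples("sigma_e2").mean() == pytest.approx(prior_mean, rel=0.05)

    def test_identity_A_concentrates_h2_near_zero(self, rng):
        y = rng.normal(size=600)
        cfg = MCMCConfig(n_iter=4000, burn_in=1000, thin=1, n_chains=2, seed=9)
        res = gibbs_gaussian(y, A=np.eye(600), cfg=cfg)
        # no pedigree signal: posterior h2 has no pull away from the prior
        # toward 1; upper quartile stays moderate
        assert np.median(res.samples("h2")) < 0.55

    def test_recovery_and_convergence(self, cohort300):
        """Planted h2 = 0.4 recovered within 0.05; PSRF(sigma_g2) < 1.03."""
        _, A, eig = cohort300
        rng = np.random.default_rng(10)
        g = simulate_breeding_values(eig=eig, sigma_g2=0.4, seed=rng)
        y = 2.0 + g + rng.normal(0, np.sqrt(0.6), eig.n)
        cfg = MCMCConfig(n_iter=10_000, burn_in=4_000, thin=3, n_chains=2, seed=11)
        res = gibbs_gaussian(y, A=A, cfg=cfg)
        assert abs(res.samples("h2").mean() - 0.4) < 0.05
        assert gelman_rubin(res.per_chain("sigma_g2")) < 1.03

    def test_reproducible_given_seed(self, cohort300, rng):
        _, A, eig = cohort300
        y = rng.normal(size=eig.n)
        cfg = MCMCConfig(n_iter=300, burn_in=100, thin=2, n_chains=2, seed=12)
        a = gibbs_gaussian(y, A=A, cfg=cfg)
        b = gibbs_gaussian(y, A=A, cfg=cfg)
        assert np.array_equal(a.chains, b.chains)

    def test_agrees_with_likelihood_on_large_cohort(self, cohort300):
        _, A, eig = cohort300
        rng = np.random.default_rng(13)
        g = simulate_breeding_values(eig=eig, sigma_g2=0.45, seed=rng)
        y = g + rng.normal(0, np.sqrt(0.55), eig.n)
        ml = fit_polygenic_ml(y, A=A, eig=eig)
        cfg = MCMCConfig(n_iter=8_000, burn_in=3_000, thin=2, n_chains=2, seed=14)
        bayes = gibbs_gaussian(y, A=A, cfg=cfg)
        assert abs(bayes.samples("h2").mean() - ml.h2) < 0.05


class TestGibbsProbit:
    def test_link_at_zero(self):
        from scipy.special import ndtr

        assert ndtr(0.0) == 0.5

    def test_one_class_rejected(self, cohort300):
        _, A, _ = cohort300
        with pytest.raises(ValueError, match="both affected and unaffected"):
            gibbs_probit(np.ones(A.shape[0], dtype=bool), A=A)

    def test_null_heritability_concentrates_near_zero(self):
        cfg_sim = SimulationConfig(n_families=400, sibship=(2, 4), seed=15)
        ped = simulate_pedigree(cfg_sim, seed=15)
        A = relationship_matrix(kinship_matrix(ped))
        status = simulate_disease_status(ped, 0.0, 0.5, seed=16)
        cfg = MCMCConfig(n_iter=6_000, burn_in=2_000, thin=2, n_chains=2, seed=17)
        res = gibbs_probit(status.to_numpy(), A=A, cfg=cfg)
        assert np.percentile(res.samples("h2"), 95) < 0.15

    def test_recovery_of_planted_liability_h2(self, cohort300):
        _, A, eig = cohort300
        ped = cohort300[0]
        means = []
        cfg = MCMCConfig(n_iter=6_000, burn_in=2_500, thin=2, n_chains=2, seed=18)
        for s in (18, 19):
            status = simulate_disease_status(ped, 0.41, 0.40, seed=s, eig=eig)
            res = gibbs_probit(status.to_numpy(), A=A,
                               cfg=MCMCConfig(**{**cfg.__dict__, "seed": s}))
            means.append(res.samples("h2").mean())
        assert abs(np.mean(means) - 0.41) < 0.1

    def test_implied_prevalence_matches_simulated(self, cohort300):
        """Phi(mu / sqrt(sigma_g2 + 1)) from the posterior matches the
        simulated prevalence within MC error."""
        from scipy.special import ndtr

        ped, A, eig = cohort300
        status = simulate_disease_status(ped, 0.4, 0.35, seed=20, eig=eig)
        cfg = MCMCConfig(n_iter=6_000, burn_in=2_500, thin=2, n_chains=2, seed=21)
        res = gibbs_probit(status.to_numpy(), A=A, cfg=cfg)
        mu = res.samples("beta_0")
        sg2 = res.samples("sigma_g2")
        implied = ndtr(mu / np.sqrt(sg2 + 1.0)).mean()
        assert abs(implied - status.mean()) < 0.05


class TestDiagnostics:
    def test_identical_chains_closed_form(self):
        c = np.tile(np.arange(100.0), (2, 1))
        assert gelman_rubin(c) == pytest.approx(np.sqrt(99 / 100))

    def test_same_distribution_chains(self, rng):
        c = rng.normal(size=(3, 10_000))
        assert gelman_rubin(c) < 1.01

    def test_disjoint_chains_diverge(self, rng):
        c = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(c) > 1.1

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError, match="within-chain variance"):
            gelman_rubin(np.ones((2, 50)))
        with pytest.raises(ValueError, match="2 equal-length"):
            gelman_rubin(np.ones((1, 50)))

    def test_summary_h2_is_mean_of_ratios(self, cohort300, rng):
        _, A, _ = cohort300
        y = rng.normal(size=A.shape[0])
        cfg = MCMCConfig(n_iter=400, burn_in=100, thin=1, n_chains=2, seed=22)
        res = gibbs_gaussian(y, A=A, cfg=cfg)
        summ = summarize_posterior(res).set_index("parameter")
        sg = res.samples("sigma_g2")
        se = res.samples("sigma_e2")
        assert summ.loc["h2", "mean"] == pytest.approx((sg / (sg + se)).mean())
        ratio_of_means = sg.mean() / (sg.mean() + se.mean())
        assert summ.loc["h2", "mean"] != pytest.approx(ratio_of_means, abs=1e-12)

    def test_summary_of_near_constant_parameter(self):
        from famlipid.heritability import GibbsResult

        chains = np.full((2, 50, 1), 3.14)
        res = GibbsResult(chains=chains, names=["x"], cfg=MCMCConfig(100, 10, 1, 2, 0))
        summ = summarize_posterior(res)
        assert summ.loc[0, "sd"] == pytest.approx(0.0, abs=1e-12)
        assert summ.loc[0, "ci_low"] == summ.loc[0, "ci_high"] == pytest.approx(3.14)
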