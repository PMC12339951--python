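"""Priors, likelihood, tempered SMC and marginal-likelihood estimation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from bmmi.inference import (
    PosteriorEnsemble,
    PriorSpec,
    SMCSettings,
    average_log_ml,
    calibrate,
    log_likelihood,
    lognormal_prior_scale,
    run_smc,
)
from bmmi.synthetic_data import (
    CalibrationData,
    SyntheticGroundTruth,
    aggregate_cells,
    generate_single_cell_trajectories,
)


class TestPriorScale:
    def test_two_decade_coverage_gives_published_scale(self):
        """95% of lognormal mass within a factor 100 of the median."""
        assert lognormal_prior_scale(100.0, 0.95) == pytest.approx(
            2.350, abs=5e-4
        )

    def test_degenerate_factor(self):
        assert lognormal_prior_scale(1.0, 0.95) == 0.0

    def test_quantile_cancels(self):
        z = norm.ppf(0.975)
        assert lognormal_prior_scale(np.exp(z), 0.95) == pytest.approx(1.0)

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            lognormal_prior_scale(10.0, 1.5)

    def test_prior_spec_mass_within_two_decades(self):
        prior = PriorSpec(np.log([1.0, 10.0]))
        rng = np.random.default_rng(0)
        z = prior.sample(rng, 20000)
        theta = np.exp(z)
        nominal = np.array([1.0, 10.0])
        inside = (theta >= nominal * 1e-2) & (theta <= nominal * 1e2)
        assert inside.mean() == pytest.approx(0.95, abs=0.01)


class TestLogLikelihood:
    def test_zero_residual_density(self, ma_model, doses_10):
        from bmmi.models import dose_response

        curve = dose_response(ma_model, ma_model.params_nominal, doses_10)
        sigma = 0.1
        data = CalibrationData(doses_10, curve, np.full(10, sigma),
                               "dose_response")
        total, pw = log_likelihood(ma_model.params_nominal, ma_model, data)
        expected = -0.5 * np.log(2 * np.pi * sigma**2)
        assert np.allclose(pw, expected)
        assert total == pytest.approx(10 * expected)

    def test_matches_gaussian_density_oracle(self, ma_model, doses_10,
                                             dose_response_data):
        total, pw = log_likelihood(
            ma_model.params_nominal, ma_model, dose_response_data
        )
        from bmmi.models import dose_response

        pred = dose_response(ma_model, ma_model.params_nominal, doses_10)
        oracle = norm.logpdf(dose_response_data.y, pred,
                             dose_response_data.sigma)
        assert np.allclose(pw, oracle)
        assert total == pytest.approx(pw.sum())
        # doubling sigma: compare to the oracle again
        doubled = CalibrationData(
            dose_response_data.design, dose_response_data.y,
            2 * dose_response_data.sigma, "dose_response",
        )
        _, pw2 = log_likelihood(ma_model.params_nominal, ma_model, doubled)
        assert np.allclose(
            pw2, norm.logpdf(doubled.y, pred, doubled.sigma)
        )

    def test_unsolvable_parameters_score_minus_infinity(self, ma_model,
                                                        dose_response_data):
        theta = np.zeros(ma_model.n_params)  # degenerate: no response at all
        total, pw = log_likelihood(theta, ma_model, dose_response_data)
        assert total == -np.inf
        assert np.all(pw == -np.inf)


def _conjugate_problem(seed=3, n=10, m0=0.0, s0=2.0, sig=0.7, mu=1.0):
    rng = np.random.default_rng(seed)
    y = rng.normal(mu, sig, n)
    prior = PriorSpec(np.array([m0]), s0)

    def loglik(z):
        return norm.logpdf(y, z[0], sig)

    post_var = 1.0 / (1.0 / s0**2 + n / sig**2)
    post_mean = post_var * (m0 / s0**2 + y.sum() / sig**2)
    cov = sig**2 * np.eye(n) + s0**2 * np.ones((n, n))
    log_ev = multivariate_normal.logpdf(y, mean=m0 * np.ones(n), cov=cov)
    return prior, loglik, y, post_mean, post_var, log_ev


class TestRunSMC:
    def test_zero_observation_data_returns_prior(self):
        """loglik == 0 leaves the prior untouched and log ML at 0."""
        prior = PriorSpec(np.array([0.5]), 1.5)

        def loglik(z):
            return np.zeros(1)

        ests = []
        for seed in range(6):
            ens = run_smc(
                prior, loglik,
                SMCSettings(n_chains=2, s_per_chain=300, max_mh_steps=6, seed=seed),
            )
            ests.append(
                [ens.samples.mean(), ens.samples.std(), average_log_ml(ens)]
            )
        ests = np.array(ests)
        se = ests.std(axis=0) / np.sqrt(len(ests))
        assert abs(ests[:, 0].mean() - 0.5) <= 3 * max(se[0], 1e-3)
        assert abs(ests[:, 1].mean() - 1.5) <= 3 * max(se[1], 1e-3)
        assert abs(ests[:, 2].mean()) <= max(3 * se[2], 1e-6)

    def test_conjugate_posterior_and_evidence_recovered(self):
        """Closed-form normal-normal posterior within 3 MC standard errors."""
        prior, loglik, _, post_mean, post_var, log_ev = _conjugate_problem()
        stats = []
        for seed in range(8):
            ens = run_smc(
                prior, loglik,
                SMCSettings(n_chains=2, s_per_chain=400, max_mh_steps=6, seed=seed),
            )
            stats.append([
                ens.samples.mean(), ens.samples.var(), average_log_ml(ens)
            ])
        stats = np.array(stats)
        mean_est, var_est, ev_est = stats.mean(axis=0)
        se = stats.std(axis=0, ddof=1) / np.sqrt(stats.shape[0])
        assert abs(mean_est - post_mean) <= 3 * se[0]
        assert abs(var_est - post_var) <= 3 * se[1]
        assert abs(ev_est - log_ev) <= 3 * se[2]

    def test_all_minus_inf_initialization_fails(self):
        prior = PriorSpec(np.array([0.0]), 1.0)

        def loglik(z):
            return np.array([-np.inf])

        with pytest.raises(RuntimeError, match="initialization failure"):
            run_smc(prior, loglik, SMCSettings(n_chains=1, s_per_chain=50,
                                               seed=0))

    def test_exactly_reproducible_under_seed(self):
        prior, loglik, *_ = _conjugate_problem()
        settings = SMCSettings(n_chains=2, s_per_chain=100, max_mh_steps=6, seed=123)
        a = run_smc(prior, loglik, settings)
        b = run_smc(prior, loglik, settings)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.log_ml_per_chain, b.log_ml_per_chain)


class TestAverageLogML:
    def test_mean_of_chain_values(self):
        def make(vals):
            return PosteriorEnsemble(
                samples=np.zeros((2, 1)),
                pointwise_loglik=np.zeros((2, 1)),
                log_ml_per_chain=np.array(vals),
                n_chains=len(vals),
                s_per_chain=1,
                seed=0,
            )

        assert average_log_ml(make([3.3, 3.3])) == pytest.approx(3.3)
        assert average_log_ml(make([0.0, np.log(4.0)])) == pytest.approx(
            np.log(2.0)
        )
        assert average_log_ml(make([-7.1])) == pytest.approx(-7.1)


class TestEvidenceConsistency:
    def test_log_ml_advantage_grows_with_data(self):
        """More data from one model widens its evidence margin (BMA limit)."""
        from dataclasses import replace

        from bmmi.models import build_model

        settings = SMCSettings(n_chains=1, s_per_chain=100, max_mh_steps=3,
                               seed=0)
        sizes = (5, 10, 20, 40)
        adv = {n: [] for n in sizes}
        for seed in range(3):
            truth = SyntheticGroundTruth(
                "FB_CASCADE", build_model("FB_CASCADE").params_nominal,
                cell_cv=0.0, noise_sd=0.1, seed=700 + seed,
            )
            for n in sizes:
                t = np.linspace(0.0, 40.0, n)
                cells = generate_single_cell_trajectories(
                    truth, n_cells=4, t_grid=t
                )
                d = aggregate_cells(cells)
                d = CalibrationData(d.design, d.y, np.full(n, 0.1), d.kind)
                lml = {}
                for name, free in (
                    ("FB_CASCADE", ("k_Raf_act", "k_Raf_deact", "K_fb")),
                    ("MA_CASCADE",
                     ("k_Raf_act", "k_Raf_deact", "k_ERK_phos")),
                ):
                    model = build_model(name)
                    model.free_mask = np.array(
                        [p in free for p in model.param_names]
                    )
                    ens = calibrate(model, d, replace(settings, seed=seed))
                    lml[name] = average_log_ml(ens)
                adv[n].append(lml["FB_CASCADE"] - lml["MA_CASCADE"])
        means = [np.mean(adv[n]) for n in sizes]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestParameterRecovery:
    def test_posterior_intervals_cover_truth(self, fb_model):
        """95% marginal intervals cover the generating parameters."""
        from dataclasses import replace

        from bmmi.models import build_model

        free_names = ("k_Raf_act", "k_Raf_deact", "K_fb")
        model = build_model("FB_CASCADE")
        model.free_mask = np.array(
            [p in free_names for p in model.param_names]
        )
        budget = SMCSettings(n_chains=1, s_per_chain=100, max_mh_steps=3,
                             seed=0)
        t = np.linspace(0.0, 40.0, 11)
        covered = total = 0
        for seed in range(4):
            truth = SyntheticGroundTruth(
                "FB_CASCADE", fb_model.params_nominal, cell_cv=0.0,
                noise_sd=0.1, seed=seed,
            )
            cells = generate_single_cell_trajectories(
                truth, n_cells=8, t_grid=t
            )
            data = aggregate_cells(cells)
            data = CalibrationData(
                data.design, data.y, np.full(data.n_train, 0.1), data.kind
            )
            ens = calibrate(model, data, replace(budget, seed=seed))
            for name in free_names:
                j = model.param_index(name)
                lo, hi = np.percentile(ens.samples[:, j], [2.5, 97.5])
                covered += lo <= fb_model.params_nominal[j] <= hi
                total += 1
        assert covered / total >= 0.9
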