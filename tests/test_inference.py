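"""Inference tests: joint-density oracle equivalence, prior handling,
R-hat behaviour, summary arithmetic, sampler determinism and a prior-only
MCMC calibration check. The full parameter-recovery study lives in the
acceptance suite."""

import math

import numpy as np
import pandas as pd
import pytest

from emodeg import (Dataset, McmcConfig, ModelParameters, PosteriorFit, Prior,
                    PriorSpec, compute_rhat, fit_mcmc, joint_log_density,
                    particle_loglik, posterior_summary, synthetic_priors)
from emodeg.inference import (DegenerateChainsError, adni_style_priors,
                              _observed_impact_terms)
from emodeg.model import (logpdf_degradation_increment,
                          logpdf_emotion_increment, logpdf_observation)


class TestPriorSpec:
    def test_every_parameter_accounted_for(self):
        spec = synthetic_priors()
        assert set(spec.free_names) == {"c_mu", "sigma", "c_ga", "beta",
                                        "h_0", "h_d", "h_m", "sigma_eps"}
        p = spec.build_params({n: 1.0 for n in spec.free_names})
        assert p.k_pos == 5 and p.w_delta_neg == -0.1

    def test_free_and_fixed_disjoint(self):
        with pytest.raises(ValueError, match="both free and fixed"):
            PriorSpec(priors={"c_ga": Prior("lognormal", 0, 1)},
                      fixed={n: 1.0 for n in
                             ("k_pos", "k_neg", "lambda_pos", "lambda_neg",
                              "w_delta_pos", "w_delta_neg", "w_d", "w_0",
                              "c_mu", "sigma", "c_ga", "beta", "h_0", "h_d",
                              "h_m", "sigma_eps")})

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError, match="neither free nor fixed"):
            PriorSpec(priors={}, fixed={"c_mu": 1.0})

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            Prior("normal", 0.0, 0.0)

    def test_adni_profile_has_covariate_and_no_impacts(self):
        spec = adni_style_priors()
        assert spec.p_covariates == 1
        assert spec.fixed["w_delta_pos"] == 0.0
        p = spec.build_params({n: (0.5 if n != "w_z_0" else 0.3)
                               for n in spec.free_names})
        assert p.w_z.tolist() == [0.3]

    def test_prior_offsets_from_generating_values(self):
        # the synthetic profile is deliberately mis-centered by >= 1 prior sd
        spec = synthetic_priors()
        truth = dict(c_mu=3, sigma=0.5, c_ga=10, beta=10, h_0=30, h_d=-1,
                     h_m=-0.5, sigma_eps=1)
        for name, v in truth.items():
            pr = spec.priors[name]
            if pr.family == "lognormal":
                offset = abs(math.log(v) - pr.loc) / pr.scale
            else:
                offset = abs(v - pr.loc) / pr.scale
            assert offset >= 1.0, name


class TestJointLogDensity:
    def test_matches_termwise_oracle(self, tiny_dataset):
        # brute-force term-by-term evaluation via the core density functions
        p = tiny_dataset.preset.params
        rng = np.random.default_rng(4)
        latents = []
        for traj in tiny_dataset:
            d = np.cumsum(rng.exponential(0.5, len(traj)))
            m = rng.normal(0, 1, len(traj))
            latents.append((d, m))
        got = joint_log_density(p, tiny_dataset, latents)
        want = 0.0
        for traj, (d, m) in zip(tiny_dataset, latents):
            for i in range(len(traj)):
                want += logpdf_observation(p, traj.y[i], d[i], m[i])
            for i in range(1, len(traj)):
                imp = traj.impacts[i - 1]
                dt = traj.times[i] - traj.times[i - 1]
                want += logpdf_emotion_increment(
                    p, m[i] - m[i - 1], imp.delta_neg, imp.delta_pos,
                    np.zeros(0), d[i - 1], dt)
                want += logpdf_degradation_increment(p, d[i] - d[i - 1],
                                                     m[i - 1], dt)
        assert got == pytest.approx(want, abs=1e-10)

    def test_additivity_at_density_peaks(self, tiny_dataset):
        # single subject, single interval, latent path at the exact modes
        p = tiny_dataset.preset.params
        traj = tiny_dataset.trajectories[0].prefix(2)
        ds = Dataset([traj], seed=0)
        imp = traj.impacts[0]
        from emodeg.model import drift_mu, gamma_shape
        mu = drift_mu(p, imp.delta_neg, imp.delta_pos, np.zeros(0), 0.0, 1.0)
        alpha = gamma_shape(p, 0.0, 1.0)
        dd_mode = (alpha - 1) / p.beta
        d = np.array([0.0, dd_mode])
        m = np.array([0.0, mu])
        y_fit = np.array([p.h_0, p.h_0 + p.h_d * dd_mode + p.h_m * mu])
        traj.y = y_fit
        got = joint_log_density(p, ds, [(d, m)])
        want = (2 * logpdf_observation(p, p.h_0, 0.0, 0.0)
                + logpdf_emotion_increment(p, mu, imp.delta_neg,
                                           imp.delta_pos, np.zeros(0), 0, 1.0)
                + logpdf_degradation_increment(p, dd_mode, 0.0, 1.0))
        assert got == pytest.approx(want, abs=1e-10)

    def test_decreasing_degradation_is_minus_inf(self, tiny_dataset):
        p = tiny_dataset.preset.params
        n = len(tiny_dataset.trajectories[0])
        latents = [(np.linspace(1, 0, n), np.zeros(n))
                   for _ in tiny_dataset.trajectories]
        assert joint_log_density(p, tiny_dataset, latents) == -math.inf

    def test_misaligned_latents_rejected(self, tiny_dataset):
        p = tiny_dataset.preset.params
        latents = [(np.zeros(2), np.zeros(2)) for _ in tiny_dataset.trajectories]
        with pytest.raises(ValueError, match="misaligned"):
            joint_log_density(p, tiny_dataset, latents)


class TestParticleLoglik:
    def test_matches_brute_force_prior_sampling(self, setting1_params):
        # independent oracle: average the observation-density product over
        # latent paths sampled straight from the transition prior
        from emodeg import generate_setting
        from scipy import special
        traj = generate_setting(1, seed=11, n_sequences=1, n_obs=4).trajectories[0]
        ds = Dataset([traj])
        p = setting1_params
        rng = np.random.default_rng(99)
        K = 400_000
        D = np.zeros(K)
        M = np.zeros(K)
        acc = np.full(K, -0.5 * ((traj.y[0] - p.h_0) / p.sigma_eps) ** 2
                      - np.log(p.sigma_eps * np.sqrt(2 * np.pi)))
        for i in range(1, 4):
            dt = traj.times[i] - traj.times[i - 1]
            im = traj.impacts[i - 1]
            arg = (p.w_delta_pos * im.delta_pos + p.w_delta_neg * im.delta_neg
                   + p.w_d * D + p.w_0)
            M_new = (M + p.c_mu * np.tanh(arg) * dt
                     + p.sigma * np.sqrt(dt) * rng.standard_normal(K))
            D = D + rng.standard_gamma(p.c_ga * special.expit(M) * dt) / p.beta
            M = M_new
            r = (traj.y[i] - (p.h_0 + p.h_d * D + p.h_m * M)) / p.sigma_eps
            acc += -0.5 * r * r - np.log(p.sigma_eps * np.sqrt(2 * np.pi))
        brute = special.logsumexp(acc) - np.log(K)
        rng2 = np.random.default_rng(1)
        ll = np.mean([particle_loglik(p, ds, rng2, n_particles=1024)
                      - _observed_impact_terms(p, ds) for _ in range(10)])
        assert ll == pytest.approx(brute, abs=0.05)

    def test_degenerate_params_rejected(self, small_dataset, rng):
        p = small_dataset.preset.params.replace(c_ga=0.0)
        from emodeg import DegenerateModelError
        with pytest.raises(DegenerateModelError):
            particle_loglik(p, small_dataset, rng)


class TestComputeRhat:
    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.standard_normal((3, 10_000))
        assert compute_rhat(chains) < 1.01

    def test_separated_chains_far_above_threshold(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert compute_rhat(chains) > 1.05 * 2

    def test_identical_noisy_chains_near_one(self, rng):
        stream = rng.standard_normal(2000)
        assert compute_rhat(np.stack([stream, stream, stream])) == \
               pytest.approx(1.0, abs=0.01)

    def test_within_chain_trend_detected(self, rng):
        # split-chain construction flags a drifting chain even when the
        # chains agree with each other
        drift = np.linspace(0, 5, 2000)
        chains = np.stack([drift + rng.normal(0, 0.1, 2000) for _ in range(3)])
        assert compute_rhat(chains) > 1.05

    def test_degenerate_constant_chains_flagged(self):
        with pytest.raises(DegenerateChainsError):
            compute_rhat(np.ones((3, 100)))

    def test_too_few_chains_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_rhat(rng.standard_normal((1, 100)))

    def test_agrees_with_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        chains = np.cumsum(rng.standard_normal((3, 500)), axis=1) * 0.05 \
            + rng.standard_normal((3, 500))
        data = az.convert_to_dataset(chains)  # (chain, draw)
        want = float(az.rhat(data, method="split")["x"].values)
        assert compute_rhat(chains) == pytest.approx(want, rel=1e-6)


class TestPosteriorSummary:
    def _fake_fit(self, draws, names):
        spec = synthetic_priors()
        return PosteriorFit(draws=draws, param_names=names, priors=spec,
                            config=McmcConfig(), rhat={n: 1.0 for n in names})

    def test_constant_parameter(self):
        fit = self._fake_fit(np.full((2, 10, 1), 3.25), ["c_mu"])
        row = posterior_summary(fit).iloc[0]
        assert row["mean"] == 3.25 and row["sd"] == 0.0

    def test_pooled_mean_arithmetic(self):
        draws = np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1)
        fit = self._fake_fit(draws, ["c_ga"])
        assert posterior_summary(fit).iloc[0]["mean"] == pytest.approx(2.5)

    def test_summary_matches_raw_recomputation(self, rng):
        draws = rng.lognormal(1.0, 0.3, size=(3, 200, 2))
        fit = self._fake_fit(draws, ["c_ga", "beta"])
        tab = posterior_summary(fit).set_index("parameter")
        for j, name in enumerate(["c_ga", "beta"]):
            pooled = draws[:, :, j].ravel()
            assert tab.loc[name, "mean"] == pytest.approx(pooled.mean(), abs=1e-12)
            assert tab.loc[name, "sd"] == pytest.approx(pooled.std(ddof=1), abs=1e-12)
            assert tab.loc[name, "q05"] == pytest.approx(
                np.quantile(pooled, 0.05), abs=1e-12)


class TestFitMcmc:
    def test_all_fixed_returns_pinned_values(self, tiny_dataset):
        spec = PriorSpec(priors={}, fixed={
            "k_pos": 5.0, "k_neg": 4.0, "lambda_pos": 3.0, "lambda_neg": 3.0,
            "w_delta_pos": 0.1, "w_delta_neg": -0.1, "w_d": 0.05, "w_0": 0.0,
            "c_mu": 3.0, "sigma": 0.5, "c_ga": 10.0, "beta": 10.0,
            "h_0": 30.0, "h_d": -1.0, "h_m": -0.5, "sigma_eps": 1.0})
        fit = fit_mcmc(tiny_dataset, spec, McmcConfig(n_warmup=5, n_samples=5))
        assert fit.draws.shape[2] == 0
        assert fit.summary.empty
        p = fit.params_at(0)
        assert (p.c_ga, p.beta, p.h_0) == (10.0, 10.0, 30.0)

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg = McmcConfig(n_chains=2, n_warmup=30, n_samples=20, seed=5,
                         n_particles=64)
        a = fit_mcmc(tiny_dataset, synthetic_priors(), cfg)
        b = fit_mcmc(tiny_dataset, synthetic_priors(), cfg)
        assert np.array_equal(a.draws, b.draws)
        c = fit_mcmc(tiny_dataset, synthetic_priors(),
                     McmcConfig(n_chains=2, n_warmup=30, n_samples=20, seed=6,
                                n_particles=64))
        assert not np.array_equal(a.draws, c.draws)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_mcmc(Dataset([]), synthetic_priors(), McmcConfig())

    def test_covariate_dimension_mismatch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="covariate"):
            fit_mcmc(tiny_dataset, adni_style_priors(), McmcConfig())

    def test_prior_only_sampling_recovers_prior(self, tiny_dataset):
        # with the likelihood disabled the chain must sample the prior:
        # compare posterior quantiles to prior quantiles
        spec = synthetic_priors()
        cfg = McmcConfig(n_chains=2, n_warmup=500, n_samples=2500, seed=11)
        fit = fit_mcmc(tiny_dataset, spec, cfg, prior_only=True)
        for name in ("c_ga", "h_0", "sigma_eps"):
            pr = spec.priors[name]
            j = fit.param_names.index(name)
            pooled = fit.pooled()[:, j]
            for q in (0.25, 0.5, 0.75):
                want = float(pr.ppf(q))
                spread = float(pr.ppf(0.75) - pr.ppf(0.25))
                assert np.quantile(pooled, q) == pytest.approx(
                    want, abs=0.2 * spread)
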