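import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

import statsmodels.api as sm

from mastpheno.ordinal import (
    MCMCConfig,
    ObservationParams,
    PriorSpec,
    SpeciesModel,
    delta_from_raw,
    ess,
    fit_species,
    observation_loglik,
    ordinal_probs,
    predict_classes,
    raw_from_delta,
    species_loglik,
)
from mastpheno.process import simulate_trajectory


class TestOrdinalProbs:
    def test_first_class_half_at_zero_predictor(self):
        P = ordinal_probs(0.0, np.array([0.0, 1.0, 2.0, 3.0]), 1.0)
        assert P[0] == pytest.approx(0.5)

    def test_closed_form_beta_zero(self):
        P = ordinal_probs(3.7, np.array([0.0, 1.0, 2.0, 3.0]), 0.0)
        q = expit(np.array([0.0, 1.0, 2.0, 3.0]))
        expected = np.array([q[0], q[1] - q[0], q[2] - q[1], q[3] - q[2], 1 - q[3]])
        assert np.abs(P - expected).max() < 1e-12

    def test_simplex_on_random_battery(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            delta = np.sort(rng.normal(0, 3, 4))
            delta += np.arange(4) * 1e-6  # ensure strict ordering
            x = rng.normal(0, 2, 50)
            beta = rng.normal(0, 3)
            P = ordinal_probs(x, delta, beta)
            assert np.all(P >= 0)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-12

    def test_mass_concentrates_at_top_class(self):
        P = ordinal_probs(1e4, np.array([0.0, 1.0, 2.0, 3.0]), 1.0)
        assert P[-1] == pytest.approx(1.0)

    def test_non_increasing_delta_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ordinal_probs(0.0, np.array([1.0, 0.5, 2.0, 3.0]), 1.0)

    def test_printed_variant_differs_and_breaks_normalisation(self):
        delta = np.array([0.0, 1.0, 2.0, 3.0])
        P = ordinal_probs(0.0, delta, 0.0, printed_form=True)
        assert P[1] == 0.0  # |Q_1 - Q_1|
        assert P.sum() != pytest.approx(1.0)


class TestDeltaTransform:
    def test_round_trip(self):
        raw = np.array([-0.7, 0.1, -1.2, 0.5])
        assert np.allclose(raw_from_delta(delta_from_raw(raw)), raw)

    def test_always_increasing(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            d = delta_from_raw(rng.normal(0, 3, 4))
            assert np.all(np.diff(d) > 0)


class TestObservationLoglik:
    def test_examples(self):
        P = np.array([0.5, 0.2, 0.15, 0.1, 0.05])
        assert observation_loglik(0, P) == pytest.approx(np.log(0.5))
        assert observation_loglik(3, np.array([0, 0, 0, 1.0, 0])) == 0.0
        assert sum(np.exp(observation_loglik(y, P)) for y in range(5)) == pytest.approx(1.0)

    def test_zero_probability_flagged(self):
        P = np.array([1.0, 0, 0, 0, 0])
        assert observation_loglik(4, P) == -np.inf


class TestSpeciesLoglik:
    @pytest.fixture(scope="class")
    def model(self, small_study):
        obs, roster, cl, truth, arch = small_study
        return SpeciesModel(obs, cl, arch.process_params), arch

    def test_single_observation_equals_categorical(self, small_study):
        obs, roster, cl, truth, arch = small_study
        one = obs.iloc[[100]]
        model = SpeciesModel(one, cl, arch.process_params,
                             study_start=obs["date"].min())
        ll = model.loglik(arch.obs_params)
        ph = one["phenophase"].iloc[0]
        lam = arch.obs_params.lam.get(ph, 0.0) if ph in ("flower", "fruit") else 0.0
        weeks = (one["date"].iloc[0] - cl["week_start_date"].iloc[0]).days / 7.0
        x = model.predictor(ph, one["site"].iloc[0], np.array([weeks]), lam)
        P = ordinal_probs(float(x[0]), arch.obs_params.delta[ph], arch.obs_params.beta[ph])
        assert ll == pytest.approx(observation_loglik(one["score"].iloc[0], P))

    def test_duplication_doubles_loglik(self, small_study):
        obs, roster, cl, truth, arch = small_study
        sub = obs.iloc[:50]
        m1 = SpeciesModel(sub, cl, arch.process_params, study_start=obs["date"].min())
        doubled = pd.concat([sub, sub], ignore_index=True)
        m2 = SpeciesModel(doubled, cl, arch.process_params, study_start=obs["date"].min())
        assert m2.loglik(arch.obs_params) == pytest.approx(2 * m1.loglik(arch.obs_params))

    def test_row_order_invariance(self, small_study):
        obs, roster, cl, truth, arch = small_study
        shuffled = obs.sample(frac=1.0, random_state=3)
        l1 = species_loglik(arch.process_params, arch.obs_params, obs, cl)
        l2 = species_loglik(arch.process_params, arch.obs_params, shuffled, cl)
        assert l1 == pytest.approx(l2)

    def test_agrees_with_straight_line_oracle(self, small_study):
        """Independent scalar-loop recomputation on a 10-observation slice."""
        obs, roster, cl, truth, arch = small_study
        sub = obs.iloc[200:210]
        model = SpeciesModel(sub, cl, arch.process_params, study_start=obs["date"].min())
        ll = model.loglik(arch.obs_params)

        traj = simulate_trajectory(cl, arch.process_params)
        win = pd.DatetimeIndex(traj["date"]) >= obs["date"].min()
        u = traj["U_C"].to_numpy()
        s = traj["S"].to_numpy()
        zu = (u - u[win].mean()) / u[win].std()
        zs = (s - s[win].mean()) / s[win].std()
        t0 = traj["date"].iloc[0]
        total = 0.0
        for _, row in sub.iterrows():
            ph = row["phenophase"]
            lam = arch.obs_params.lam.get(ph, 0.0) if ph in ("flower", "fruit") else 0.0
            series = zu if ph == "leaf" else zs
            tq = (row["date"] - t0) / pd.Timedelta(days=7) - lam
            x = float(np.interp(tq, np.arange(len(traj)), series))
            P = ordinal_probs(x, arch.obs_params.delta[ph], arch.obs_params.beta[ph])
            total += np.log(P[row["score"]])
        assert ll == pytest.approx(total, abs=1e-10)


class TestBinaryCollapse:
    def test_two_class_model_is_logistic_regression(self):
        """With J = 2 the cumulative-link MLE equals a direct logistic fit."""
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 400)
        true_p = expit(1.3 * x - 0.4)
        y = (rng.uniform(size=400) < true_p).astype(int)

        def nll(theta):
            delta, beta = theta
            P = ordinal_probs(x, np.array([delta]), beta)
            return -np.log(P[np.arange(len(y)), y]).sum()

        res = optimize.minimize(nll, [0.0, 0.5], method="BFGS")
        glm = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        # P(y=1) = expit(x*beta - delta): intercept = -delta, slope = beta
        assert res.x[0] == pytest.approx(-glm.params[0], abs=1e-6)
        assert res.x[1] == pytest.approx(glm.params[1], abs=1e-6)


class TestESS:
    def test_independent_draws(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10_000)
        assert ess(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(6)
        n, rho = 20_000, 0.5
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        # ESS -> N (1-rho)/(1+rho) = N/3
        assert ess(x) == pytest.approx(n / 3, rel=0.15)

    def test_constant_chain(self):
        assert ess(np.ones(100)) == 0.0

    def test_short_chain_errors(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestFitSpecies:
    @pytest.fixture
    def short_cfg(self):
        return MCMCConfig(n_iter=1200, burn=300, max_iter=1200, ess_threshold=10)

    def test_same_seed_identical_chains(self, small_study, short_cfg):
        obs, roster, cl, truth, arch = small_study
        kw = dict(config=short_cfg, seed=7, process_params=arch.process_params,
                  phenophases=("flower",))
        f1 = fit_species(obs, cl, **kw)
        f2 = fit_species(obs, cl, **kw)
        assert np.array_equal(f1.chain, f2.chain)

    def test_beta_zero_fit_matches_multinomial_intercepts(self, small_study):
        """With the slope pinned at zero the posterior intercepts match the
        closed-form cumulative-logit MLE of the class frequencies."""
        obs, roster, cl, truth, arch = small_study
        sub = obs.loc[obs["phenophase"] == "flower"]
        cfg = MCMCConfig(n_iter=8000, burn=2000, max_iter=8000)
        fit = fit_species(
            obs, cl, config=cfg, seed=3, process_params=arch.process_params,
            phenophases=("flower",),
            fixed={"beta_flower": 0.0, "lambda_flower": 0.0},
        )
        med_raw = np.array(
            [fit.summary.loc[f"delta_flower_{j}", "median"] for j in range(1, 5)]
        )
        delta_hat = delta_from_raw(med_raw)
        freq = np.bincount(sub["score"], minlength=5) / len(sub)
        cum = np.cumsum(freq)[:4]
        expected = np.log(cum / (1 - cum))
        assert np.abs(delta_hat - expected).max() < 0.15

    def test_prior_only_sampling_recovers_priors(self, small_study):
        obs, roster, cl, truth, arch = small_study
        priors = PriorSpec()
        cfg = MCMCConfig(n_iter=30_000, burn=5_000, max_iter=30_000,
                         prior_only=True, ess_threshold=10)
        fit = fit_species(obs, cl, priors=priors, config=cfg, seed=12,
                          process_params=arch.process_params, phenophases=("flower",))
        beta = fit.chain[:, fit.param_names.index("beta_flower")][::5]
        lam = fit.chain[:, fit.param_names.index("lambda_flower")][::5]
        ks_beta = stats.kstest(beta, "norm", args=(0, priors.beta_sd)).statistic
        ks_lam = stats.kstest(lam, "uniform", args=(0, 52)).statistic
        assert ks_beta < 0.05
        assert ks_lam < 0.05

    def test_nonconvergence_flagged(self, small_study):
        obs, roster, cl, truth, arch = small_study
        cfg = MCMCConfig(n_iter=200, burn=50, max_iter=200, ess_threshold=1e6)
        fit = fit_species(obs, cl, config=cfg, seed=1,
                          process_params=arch.process_params, phenophases=("flower",))
        assert not fit.converged


class TestPredict:
    def test_accuracy_and_tie_rule(self, small_study, ):
        obs, roster, cl, truth, arch = small_study
        cfg = MCMCConfig(n_iter=1500, burn=400, max_iter=1500, ess_threshold=10)
        model = SpeciesModel(obs, cl, arch.process_params, phenophases=("flower",))
        fit = fit_species(obs, cl, config=cfg, seed=2, model=model)
        preds, acc = predict_classes(fit, model)
        assert set(acc) == {"flower"}
        assert 0.0 <= acc["flower"] <= 1.0
        assert (preds["predicted"].between(0, 4)).all()
        # argmax tie-breaking: equal probabilities resolve to the lowest class
        assert int(np.argmax(np.full(5, 0.2))) == 0
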