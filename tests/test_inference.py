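import math

import numpy as np
import pytest
from scipy.special import betaln

import prefbandit as pb
from prefbandit.core_data import TaskType
from prefbandit.inference import (
    BayesFactor,
    PriorSpec,
    SamplerConfig,
    bayes_factor,
    compare_models,
    default_recovery_grid,
    fit_point_estimates,
    kass_raftery_label,
    log_tempered_posterior,
    make_recovery_design,
    parameter_recovery,
    pool_participants,
    prepare_participant,
    sample_posterior,
    sample_posterior_fn,
    split_rhat,
    study_wbic,
    wbic,
)
from prefbandit.rl_models import ParamSet, get_model, simulate_session
from prefbandit.core_data import ParticipantDataset


def one_participant(seed=0, model="RL2", params=ParamSet(0.3, 4.0, (0.7, 0.4))):
    rng = np.random.default_rng(seed)
    spec = get_model(model)
    schedules = make_recovery_design(rng)
    ds = ParticipantDataset(participant_id="p")
    table = {}
    for task in TaskType:
        sched = schedules[task]
        ds.gamble_trials.extend(simulate_session(spec, params, sched, rng,
                                                 participant_id="p"))
        table[task] = sched.stimuli
    return prepare_participant(spec, ds.validate(), table)


class TestTemperedPosterior:
    def test_probe_point_matches_straight_line_recomputation(self):
        model = get_model("RL2")
        data = one_participant()
        prior = PriorSpec.default(model)
        theta = np.array([0.22, 1.7, 0.6, 0.35])
        tau = 0.4
        # independent recomputation: loop over trials in plain python
        q = np.array([theta[2:][s] for s in data.slot_of_stim], dtype=float)
        ll = 0.0
        for c, o, r in zip(data.chosen, data.other, data.reward):
            p = 1.0 / (1.0 + math.exp(-theta[1] * (q[c] - q[o])))
            ll += math.log(p)
            q[c] += theta[0] * (r - q[c])
        expected = tau * ll + prior.log_density(theta)
        got = log_tempered_posterior(model, theta, data, prior, tau)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_tau_one_is_ordinary_posterior(self):
        model = get_model("RL1")
        data = one_participant(model="RL1", params=ParamSet(0.3, 2.0, (0.5,)))
        prior = PriorSpec.default(model)
        theta = ParamSet(0.4, 1.0, (0.5,))
        lp = log_tempered_posterior(model, theta, data, prior, 1.0)
        from prefbandit.inference import _loglik
        assert lp == pytest.approx(
            _loglik(data, theta.as_vector()) + prior.log_density(theta.as_vector()),
            abs=1e-12)

    def test_out_of_support_is_minus_inf(self):
        model = get_model("RL1")
        data = one_participant(model="RL1", params=ParamSet(0.3, 2.0, (0.5,)))
        prior = PriorSpec.default(model, beta_max=1.0)
        assert log_tempered_posterior(model, np.array([0.5, 2.0, 0.5]),
                                      data, prior, 1.0) == -math.inf


class TestGenericSampler:
    def test_conjugate_bernoulli_posterior_mean(self):
        n, k = 30, 21
        ll = lambda th: k * math.log(th[0]) + (n - k) * math.log(1 - th[0])
        prior = PriorSpec(bounds=((1e-9, 1 - 1e-9),))
        draws = sample_posterior_fn(ll, prior, 1.0, SamplerConfig(), 5)
        assert draws.flat[:, 0].mean() == pytest.approx((k + 1) / (n + 2),
                                                        abs=0.02)

    def test_no_data_recovers_prior(self):
        draws = sample_posterior_fn(lambda th: 0.0,
                                    PriorSpec(bounds=((0.0, 1.0),)),
                                    1.0, SamplerConfig(), 9)
        assert draws.flat[:, 0].mean() == pytest.approx(0.5, abs=0.02)

    def test_same_seed_identical(self):
        ll = lambda th: -10 * (th[0] - 0.3) ** 2
        prior = PriorSpec(bounds=((0.0, 1.0),))
        cfg = SamplerConfig(n_chains=2, n_draws=300, n_warmup=100)
        a = sample_posterior_fn(ll, prior, 1.0, cfg, 3)
        b = sample_posterior_fn(ll, prior, 1.0, cfg, 3)
        assert np.array_equal(a.draws, b.draws)


class TestRlSampler:
    def test_same_seed_identical_draws(self, light_sampler):
        model = get_model("RL2")
        data = one_participant()
        prior = PriorSpec.default(model)
        a = sample_posterior(model, data, prior, 1.0, light_sampler, 21)
        b = sample_posterior(model, data, prior, 1.0, light_sampler, 21)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.logliks, b.logliks)

    def test_prior_dominated_estimate_near_prior_mean(self, light_sampler):
        model = get_model("RL1")
        full = one_participant(model="RL1", params=ParamSet(0.3, 2.0, (0.5,)))
        from prefbandit.inference import ParticipantData
        tiny = ParticipantData("p", full.chosen[:1], full.other[:1],
                               full.reward[:1], full.slot_of_stim)
        draws = sample_posterior(model, tiny, PriorSpec.default(model, 1.0),
                                 1.0, light_sampler, 4)
        # a single binary observation barely moves alpha off its prior
        assert draws.mean()[0] == pytest.approx(0.5, abs=0.05)

    def test_split_rhat_flags_disagreeing_chains(self):
        rng = np.random.default_rng(0)
        good = rng.normal(size=(4, 500, 1))
        assert split_rhat(good)[0] < 1.05
        bad = good.copy()
        bad[0] += 5.0
        assert split_rhat(bad)[0] > 1.5


class TestWbic:
    def test_more_data_increases_wbic(self, light_sampler):
        model = get_model("RL2")
        data = one_participant()
        prior = PriorSpec.default(model)
        w1, _ = wbic(model, data, prior, light_sampler, 2)
        doubled = pool_participants([data, data])
        w2, _ = wbic(model, doubled, prior, light_sampler, 2)
        assert w2 > w1

    def test_sampling_noise_small_between_runs(self, light_sampler):
        model = get_model("RL2")
        data = one_participant()
        prior = PriorSpec.default(model)
        w1, _ = wbic(model, data, prior, light_sampler, 2)
        w2, _ = wbic(model, data, prior, light_sampler, 3)
        assert abs(w1 - w2) < 1.5

    def test_needs_two_trials(self, light_sampler):
        model = get_model("RL1")
        full = one_participant(model="RL1", params=ParamSet(0.3, 2.0, (0.5,)))
        from prefbandit.inference import ParticipantData
        tiny = ParticipantData("p", full.chosen[:1], full.other[:1],
                               full.reward[:1], full.slot_of_stim)
        with pytest.raises(ValueError):
            wbic(model, tiny, PriorSpec.default(model), light_sampler, 1)

    def test_tracks_quadrature_marginal_likelihood_across_n(self):
        """On a conjugate Bernoulli toy the tempered-run WBIC stays within
        the documented band (1.0) of -log marginal likelihood by quadrature."""
        for n, seed in ((20, 1), (100, 2), (500, 3)):
            rng = np.random.default_rng(seed)
            k = int(rng.binomial(n, 0.6))
            ll = lambda th: k * math.log(th[0]) + (n - k) * math.log(1 - th[0])
            prior = PriorSpec(bounds=((1e-9, 1 - 1e-9),))
            draws = sample_posterior_fn(ll, prior, 1.0 / math.log(n),
                                        SamplerConfig(), seed + 10)
            w = float(-draws.logliks.mean())
            nlml = float(-betaln(k + 1, n - k + 1))
            assert abs(w - nlml) < 1.0


class TestBayesFactors:
    def test_equal_wbics_unimportant(self):
        bf = bayes_factor(10.0, 10.0)
        assert bf.value == 1.0 and bf.label == "unimportant" and bf.favored == "a"

    def test_reported_example_value(self):
        bf = bayes_factor(0.0, math.log(110.0))
        assert bf.value == pytest.approx(110.0)
        assert bf.label == "strong"

    def test_antisymmetry(self):
        ab = bayes_factor(3.0, 5.0)
        ba = bayes_factor(5.0, 3.0)
        assert ab.value == pytest.approx(ba.value)
        assert ab.favored == "a" and ba.favored == "b"

    @pytest.mark.parametrize("bf,label", [
        (1.0, "unimportant"), (2.99, "unimportant"),
        (3.0, "positive"), (19.99, "positive"),
        (20.0, "strong"), (149.99, "strong"),
        (150.0, "very strong"), (1e9, "very strong"),
    ])
    def test_kass_raftery_bins(self, bf, label):
        assert kass_raftery_label(bf) == label

    def test_label_requires_bf_at_least_one(self):
        with pytest.raises(ValueError):
            kass_raftery_label(0.5)


class TestModelComparison:
    def test_single_model_table(self, light_sampler):
        data = [one_participant()]
        table = compare_models(data, ["RL2"], config=light_sampler, rng=1)
        assert list(table.table.model) == ["RL2"]
        assert "bf_vs_best" not in table.table.columns
        assert table.best == "RL2"

    def test_best_model_has_minimum_wbic(self, light_sampler):
        from prefbandit.inference import _simulate_recovery_participant
        rng = np.random.default_rng(5)
        units = [_simulate_recovery_participant(
            get_model("RL2"), ParamSet(0.3, 4.0, (0.8, 0.3)), rng, i)
            for i in range(3)]
        by_model = {
            name: [prepare_participant(get_model(name), ds, tab)
                   for ds, tab in units]
            for name in ("RL1", "RL2", "RL3", "RL4")
        }
        table = compare_models(by_model, ["RL1", "RL2", "RL3", "RL4"],
                               config=light_sampler, rng=2)
        df = table.table
        assert df.loc[df.model == table.best, "wbic"].iloc[0] == df.wbic.min()
        assert (df.loc[df.model != table.best, "bf_vs_best"] >= 1.0).all()


class TestPointEstimatesAndRecovery:
    def test_alpha_recovered_on_long_sessions(self, light_sampler):
        model = get_model("RL2")
        truth = ParamSet(0.3, 4.0, (0.7, 0.4))
        data = [one_participant(seed=s, params=truth) for s in (11, 12, 13)]
        fits = fit_point_estimates(model, data, PriorSpec.default(model),
                                   light_sampler, 6)
        alphas = [p.alpha for p in fits.values()]
        assert np.mean(alphas) == pytest.approx(0.3, abs=0.1)

    def test_same_seed_identical_estimates(self, light_sampler):
        model = get_model("RL2")
        data = [one_participant()]
        f1 = fit_point_estimates(model, data, PriorSpec.default(model),
                                 light_sampler, 8)
        f2 = fit_point_estimates(model, data, PriorSpec.default(model),
                                 light_sampler, 8)
        assert f1 == f2

    def test_degenerate_grid_flagged(self, light_sampler):
        model = get_model("RL1")
        truth = [ParamSet(0.3, 4.0, (0.5,))] * 3
        report = parameter_recovery(model, truth, light_sampler, 4)
        row = report.summary.set_index("parameter")
        assert math.isnan(row.loc["alpha", "correlation"])
        assert any("alpha" in note for note in report.notes)

    def test_recovery_grid_spans_support(self):
        grid = default_recovery_grid("RL2", 100, 3)
        alphas = [p.alpha for p in grid]
        assert min(alphas) < 0.2 and max(alphas) > 0.8
        assert all(len(p.etas) == 2 for p in grid)

    def test_more_trials_do_not_worsen_alpha_rmse(self, light_sampler):
        """Recovery degrades gracefully: average RMSE(alpha) with 25 trials
        per pair is no better than with 100 trials per pair."""
        model = get_model("RL2")
        truths = default_recovery_grid(model, 20, 31)
        rmse = {}
        for reps in (25, 100):
            report = parameter_recovery(model, truths, light_sampler, rng=32,
                                        reps_per_pair=reps)
            rmse[reps] = report.summary.set_index("parameter") \
                .loc["alpha", "rmse"]
        assert rmse[25] >= rmse[100]

    def test_maximum_likelihood_respects_nesting(self):
        """RL1 is nested in RL2/RL3, which are nested in RL4, so the
        maximised session likelihood cannot decrease along the nesting."""
        from scipy.optimize import minimize
        from prefbandit.inference import _loglik, _simulate_recovery_participant
        rng = np.random.default_rng(77)
        ds, table = _simulate_recovery_participant(
            get_model("RL4"), ParamSet(0.3, 4.0, (0.8, 0.2, 0.5)), rng, 0)
        best = {}
        for name in ("RL1", "RL2", "RL3", "RL4"):
            spec = get_model(name)
            data = prepare_participant(spec, ds, table)
            d = spec.n_params
            lo = np.zeros(d)
            hi = np.array([1.0, 5.0] + [1.0] * spec.n_etas)
            vals = []
            for s in range(4):
                x0 = np.random.default_rng(100 + s).uniform(
                    lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
                res = minimize(lambda th: -_loglik(data, th), x0,
                               bounds=list(zip(lo, hi)), method="L-BFGS-B")
                vals.append(-res.fun)
            best[name] = max(vals)
        assert best["RL2"] >= best["RL1"] - 1e-6
        assert best["RL3"] >= best["RL1"] - 1e-6
        assert best["RL4"] >= best["RL2"] - 1e-6
        assert best["RL4"] >= best["RL3"] - 1e-6
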