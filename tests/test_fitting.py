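"""Hierarchical Bayesian fitting: transforms, sampler, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socialdiscounting.design import generative_pairs
from socialdiscounting.fitting import (
    FitConfig,
    PosteriorFit,
    block_data_from_frame,
    check_convergence,
    constrain,
    fit_block,
    individual_point_estimates,
    posterior_predictive,
    unconstrain,
)
from socialdiscounting.models import choice_prob_ku
from socialdiscounting.selection import simulate_ku_choices


def _simulated_block(n_sub, seed, km_loc=-2.0, km_scale=0.7, ku_log_loc=np.log(0.7),
                     ku_log_scale=0.3, n_trials=50):
    rng = np.random.default_rng(seed)
    truth = pd.DataFrame(
        {
            "km": rng.normal(km_loc, km_scale, n_sub),
            "ku": np.exp(rng.normal(ku_log_loc, ku_log_scale, n_sub)),
        }
    )
    offers = generative_pairs(n_trials)
    return truth, simulate_ku_choices(truth, offers, rng)


class TestTransforms:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sampled_from(["k", "km", "ku", "t", "xi", "tau"]), st.floats(-20, 20))
    def test_constraints_hold_and_roundtrip(self, name, raw):
        value = float(constrain(name, raw))
        if name in ("k", "km"):
            assert value < 0
        elif name == "ku":
            assert value > 0
        elif name == "t":
            assert -1 <= value <= 1
        elif name == "xi":
            assert 0 <= value <= 1
        else:
            assert 0 <= value <= 10
        if name in ("k", "km", "ku") or abs(raw) < 15:
            assert float(unconstrain(name, value)) == pytest.approx(raw, abs=1e-6)


class TestBlockData:
    def test_frame_roundtrip(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "trial_index": [0, 1, 0, 1],
                "m_ss": [5.0, 6.0, 7.0, 8.0],
                "m_ll": [10.0, 12.0, 14.0, 16.0],
                "delay_days": [10.0, 20.0, 30.0, 40.0],
                "choice_ll": [1, 0, 1, 1],
            }
        )
        data, ids = block_data_from_frame(df)
        assert ids == ["a", "b"]
        assert data["choice"].shape == (2, 2)
        assert data["m_ss"][1, 0] == 7.0
        assert data["choice"][0, 1] == False  # noqa: E712

    def test_ragged_participants_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b"],
                "trial_index": [0, 1, 0],
                "m_ss": [5.0] * 3,
                "m_ll": [10.0] * 3,
                "delay_days": [10.0] * 3,
                "choice_ll": [1, 0, 1],
            }
        )
        with pytest.raises(ValueError):
            block_data_from_frame(df)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            block_data_from_frame(pd.DataFrame())


@pytest.fixture(scope="module")
def ku_fit_and_truth():
    truth, data = _simulated_block(12, seed=5)
    fit = fit_block("ku", data, FitConfig(chains=4, warmup=600, samples=600, seed=9))
    return truth, data, fit


class TestFitBlock:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_block("exponential", {"m_ss": np.ones((1, 1))})

    def test_draw_shapes_and_constraints(self, ku_fit_and_truth):
        _, _, fit = ku_fit_and_truth
        draws = fit.constrained_draws
        assert draws["km"].shape == (4, 600, 12)
        assert (draws["km"] < 0).all()
        assert (draws["ku"] > 0).all()

    def test_individual_estimates_track_truth(self, ku_fit_and_truth):
        truth, _, fit = ku_fit_and_truth
        est = individual_point_estimates(fit)
        assert (est.km < 0).all() and (est.ku > 0).all()
        r = np.corrcoef(truth.km, est.km)[0, 1]
        assert r > 0.7

    def test_posterior_mean_beats_prior_mean_likelihood(self, ku_fit_and_truth):
        _, data, fit = ku_fit_and_truth
        from socialdiscounting.fitting import MODELS, _prepare_data

        prepared = _prepare_data(data)
        pointwise = MODELS["ku"]["pointwise"]
        est = individual_point_estimates(fit)
        post = {"km": est.km.to_numpy(), "ku": est.ku.to_numpy()}
        prior = {"km": constrain("km", np.zeros(12)), "ku": constrain("ku", np.zeros(12))}
        assert pointwise(post, prepared).sum() > pointwise(prior, prepared).sum()

    def test_seeded_fits_are_reproducible(self):
        _, data = _simulated_block(4, seed=2, n_trials=20)
        cfg = FitConfig(chains=2, warmup=100, samples=100, seed=33)
        a = fit_block("ku", data, cfg)
        b = fit_block("ku", data, cfg)
        np.testing.assert_array_equal(a.raw_draws["km"], b.raw_draws["km"])

    def test_single_all_patient_chooser_moves_posterior_down(self):
        # one participant who always takes the delayed offer
        offers = generative_pairs(50)
        data = {
            "m_ss": np.array([[o.m_ss for o in offers]]),
            "m_ll": np.array([[o.m_ll for o in offers]]),
            "d": np.array([[o.d for o in offers]]),
            "choice": np.ones((1, 50), dtype=bool),
        }
        fit = fit_block("ku", data, FitConfig(chains=2, warmup=400, samples=400, seed=4))
        est = individual_point_estimates(fit)
        prior_mean_km = float(constrain("km", 0.0))  # -1
        assert est.km.iloc[0] < prior_mean_km

    def test_estimates_shrink_toward_group(self, ku_fit_and_truth):
        # hierarchical posterior means are less dispersed than per-subject MLEs
        truth, data, fit = ku_fit_and_truth
        from socialdiscounting.fitting import MODELS, _prepare_data

        prepared = _prepare_data(data)
        pointwise = MODELS["ku"]["pointwise"]
        km_grid = np.linspace(-6, -0.01, 120)
        ku_grid = np.exp(np.linspace(np.log(0.05), np.log(5), 60))
        KM, KU = np.meshgrid(km_grid, ku_grid, indexing="ij")
        theta = {"km": KM.ravel()[:, None], "ku": KU.ravel()[:, None]}  # (G, 1)
        mles = []
        for i in range(12):
            sub = {k: prepared[k][i: i + 1] for k in ("m_ss", "m_ll", "d", "choice", "thresh")}
            grid_ll = pointwise(theta, sub).sum(axis=-1).ravel()  # (G,)
            mles.append(KM.ravel()[int(np.argmax(grid_ll))])
        est = individual_point_estimates(fit)
        assert np.std(est.km) < np.std(mles) + 1e-9


class TestConvergence:
    def _fake_fit(self, draws_by_chain):
        raw = {"km": draws_by_chain}
        C, S, N = draws_by_chain.shape
        return PosteriorFit(
            model="ku",
            param_names=("km",),
            raw_draws=raw,
            mu_draws=draws_by_chain.mean(axis=2, keepdims=True),
            sigma_draws=np.ones((C, S, 1)),
            log_lik=None,
            participant_ids=list(range(N)),
            data={},
            config=FitConfig(chains=C, samples=S),
        )

    def test_identical_chains_give_unit_rhat(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 400, 3))
        fit = self._fake_fit(np.repeat(one, 4, axis=0))
        report = check_convergence(fit, rhat_threshold=1.01)
        assert report.passed
        assert report.max_rhat == pytest.approx(1.0, abs=0.02)

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        fit = self._fake_fit(rng.normal(size=(4, 500, 3)))
        assert check_convergence(fit, rhat_threshold=1.02).passed

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 300, 2)) + np.arange(4)[:, None, None] * 10
        with pytest.warns(UserWarning):
            report = check_convergence(self._fake_fit(draws), rhat_threshold=1.05)
        assert not report.passed
        assert report.max_rhat > 2

    def test_single_chain_rejected(self):
        fit = self._fake_fit(np.zeros((1, 100, 2)))
        with pytest.raises(ValueError):
            check_convergence(fit)


class TestPosteriorPredictive:
    def test_rates_within_bounds_and_match_observed(self, ku_fit_and_truth):
        truth, data, fit = ku_fit_and_truth
        rates = posterior_predictive(fit, thin=25, seed=0)
        assert np.all((rates >= 0) & (rates <= 1))
        observed = data["choice"].mean(axis=1)
        lo, hi = np.percentile(rates, [0.5, 99.5], axis=0)
        inside = (observed >= lo - 0.05) & (observed <= hi + 0.05)
        assert inside.mean() > 0.8

    def test_point_mass_posterior_recovers_model_rate(self):
        offers = generative_pairs(20)
        data = {
            "m_ss": np.array([[o.m_ss for o in offers]]),
            "m_ll": np.array([[o.m_ll for o in offers]]),
            "d": np.array([[o.d for o in offers]]),
            "choice": np.zeros((1, 20), dtype=bool),
        }
        km, ku = -2.0, 0.8
        raw = {
            "km": np.full((2, 200, 1), float(unconstrain("km", km))),
            "ku": np.full((2, 200, 1), float(unconstrain("ku", ku))),
        }
        fit = PosteriorFit(
            model="ku", param_names=("km", "ku"), raw_draws=raw,
            mu_draws=np.zeros((2, 200, 2)), sigma_draws=np.ones((2, 200, 2)),
            log_lik=None, participant_ids=[0], data=data, config=FitConfig(),
        )
        rates = posterior_predictive(fit, thin=1, seed=1)
        expected = float(np.mean(choice_prob_ku(
            (data["m_ss"][0], data["m_ll"][0], data["d"][0]), (km, ku)
        )))
        assert rates.mean() == pytest.approx(expected, abs=0.02)
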