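"""Synthetic cohort: agents, learners, social shifts, full sessions."""

import numpy as np
import pytest

from socialdiscounting.cohort import (
    Agent,
    CohortConfig,
    GridBayesLearner,
    OracleLearner,
    apply_social_shift,
    generate_cohort,
    ground_truth_frame,
    make_agents,
    sessions_to_frame,
    simulate_agent_choice,
    simulate_other_block,
)
from socialdiscounting.design import generative_pairs
from socialdiscounting.models import choice_prob_kt, choice_prob_ku, indifference_k, subjective_value


class TestAgents:
    def test_plus_minus_one_rule(self):
        imp, pat = make_agents(-2.0)
        assert imp.k_agent == -1.0 and pat.k_agent == -3.0
        assert imp.label == "impulsive" and pat.label == "patient"

    def test_agents_can_leave_design_range(self):
        imp, _ = make_agents(-0.5)
        assert imp.k_agent == 0.5  # outside [-4, 0]; flagged at session level

    def test_equal_baselines_give_identical_agents(self):
        assert make_agents(-2.2) == make_agents(-2.2)

    def test_choice_is_fair_coin_at_indifference(self, rng):
        from socialdiscounting.models import Offer

        offer = Offer(5, 10, 10)  # indifference at -1
        agent = Agent("impulsive", k_agent=-1.0)
        draws = [simulate_agent_choice(agent, offer, rng) for _ in range(4000)]
        assert abs(np.mean(draws) - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_choice_rate_matches_softmax(self, rng, lattice):
        agent = Agent("patient", k_agent=-2.5)
        offer = lattice.offer(lattice.nearest(-2.0))
        p = float(choice_prob_kt(offer, (agent.k_agent, agent.t_agent)))
        n = 10**4
        rate = np.mean([simulate_agent_choice(agent, offer, rng) for _ in range(n)])
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-3

    def test_agent_mostly_agrees_with_higher_value_choice(self, design_config, rng):
        # "slightly noisy": above chance agreement on the 50-pair design
        agent = Agent("impulsive", k_agent=-1.3)
        agree = []
        for offer in generative_pairs(50, design_config):
            v_ss, v_ll = subjective_value(offer, agent.k_agent)
            if v_ll == v_ss:
                continue
            for _ in range(20):
                agree.append(simulate_agent_choice(agent, offer, rng) == (v_ll > v_ss))
        assert 0.5 < np.mean(agree) < 1.0


class TestSocialShift:
    def test_endpoints_and_midpoint(self):
        agent = Agent("patient", k_agent=-3.0)
        assert apply_social_shift(-4.0, agent, 0.0) == -4.0
        assert apply_social_shift(-4.0, agent, 1.0) == -3.0
        assert apply_social_shift(-4.0, agent, 0.5) == -3.5

    def test_negative_omega_moves_away(self):
        agent = Agent("impulsive", k_agent=-1.0)
        assert apply_social_shift(-2.0, agent, -0.5) < -2.0

    def test_omega_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_social_shift(-2.0, Agent("patient", -3.0), 1.5)


class TestOtherBlock:
    def test_learner_belief_approaches_agent(self, design_config, rng):
        offers = generative_pairs(50, design_config)
        gains = []
        for rep in range(30):
            agent = Agent("impulsive", k_agent=float(rng.uniform(-3, -0.5)))
            learner = GridBayesLearner(prior_mean=agent.k_agent - 1.0)
            before = abs(learner.estimate() - agent.k_agent)
            simulate_other_block(agent, learner, offers, rng)
            gains.append(before - abs(learner.estimate() - agent.k_agent))
        assert np.mean(gains) > 0

    def test_accuracy_rises_within_block(self, design_config, rng):
        offers = generative_pairs(50, design_config)
        first, second = [], []
        for rep in range(30):
            agent = Agent("patient", k_agent=float(rng.uniform(-3.5, -1)))
            learner = GridBayesLearner(prior_mean=agent.k_agent + 1.0)
            records = simulate_other_block(agent, learner, offers, rng)
            correct = []
            for r in records:
                v_ss, v_ll = subjective_value(r["offer"], agent.k_agent)
                if v_ll != v_ss:
                    correct.append(r["choice_ll"] == (v_ll > v_ss))
            correct = np.asarray(correct, dtype=float)
            first.append(correct[: len(correct) // 2].mean())
            second.append(correct[len(correct) // 2:].mean())
        assert np.mean(second) > np.mean(first)
        assert np.mean(second) > 0.5

    def test_oracle_learner_is_perfect_without_lapses(self, design_config, rng):
        offers = generative_pairs(50, design_config)
        agent = Agent("impulsive", k_agent=-1.5)
        learner = OracleLearner(agent.k_agent)
        records = simulate_other_block(agent, learner, offers, rng)
        for r in records:
            v_ss, v_ll = subjective_value(r["offer"], agent.k_agent)
            if v_ll != v_ss:
                assert r["choice_ll"] == (v_ll > v_ss)


class TestCohortGeneration:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = CohortConfig(n_young=4, n_older=4)
        return cfg, generate_cohort(cfg, seed=3)

    def test_session_structure(self, small_cohort):
        _, sessions = small_cohort
        assert len(sessions) == 8
        df = sessions_to_frame(sessions)
        assert len(df) == 8 * 250
        per_block = df.groupby(["participant_id", "block"]).size()
        assert (per_block == 50).all()
        assert set(df.block) == {"Self1", "Other1", "Self2", "Other2", "Self3"}
        assert (df.loc[df.role == "self", "agent_label"].isna()).all()
        assert (df.loc[df.role == "other", "agent_label"].notna()).all()

    def test_agent_order_counterbalanced(self, small_cohort):
        _, sessions = small_cohort
        orders = [s.agent_order for s in sessions if s.group == "young"]
        assert orders.count("impulsive-first") == 2

    def test_ground_truth_is_complete(self, small_cohort):
        _, sessions = small_cohort
        gt = ground_truth_frame(sessions)
        for col in ("km_self1", "km_self2", "km_self3", "ku", "omega_impulsive",
                    "omega_patient", "k_agent_impulsive", "k_agent_patient"):
            assert gt[col].notna().all()
        assert (gt.ku > 0).all()
        assert (gt.k_agent_impulsive - gt.k_agent_patient).round(9).eq(2.0).all()

    def test_reproducible_from_seed(self, small_cohort):
        cfg, sessions = small_cohort
        again = generate_cohort(cfg, seed=3)
        assert sessions_to_frame(sessions).equals(sessions_to_frame(again))

    def test_self_choice_rates_match_generative_model(self, small_cohort):
        _, sessions = small_cohort
        df = sessions_to_frame(sessions)
        for s in sessions:
            sub = df[(df.participant_id == s.participant_id) & (df.block == "Self1")]
            p = choice_prob_ku(
                (sub.m_ss.to_numpy(), sub.m_ll.to_numpy(), sub.delay_days.to_numpy()),
                (s.true_km["Self1"], s.true_ku),
            )
            se = np.sqrt(np.sum(p * (1 - p))) / len(p)
            assert abs(sub.choice_ll.mean() - p.mean()) < 4 * se + 0.02

    def test_agent_validity_flag(self):
        # a very impulsive baseline pushes the impulsive agent above 0
        cfg = CohortConfig(n_young=3, n_older=0, km_baseline_mean=-0.4,
                           km_baseline_sd=0.01)
        sessions = generate_cohort(cfg, seed=1)
        assert all(not s.valid_agents for s in sessions)
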