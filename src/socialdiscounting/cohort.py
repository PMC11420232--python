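"""Synthetic cohort generation with known ground truth.

Emulates the structure of a delegated inter-temporal choice study: each
participant completes five 50-trial blocks (Self1, Other1, Self2,
Other2, Self3). In Self blocks they choose for themselves; choices are
drawn from the preference-uncertainty generative model at the block's
effective discounting distribution. In Other blocks they predict the
choices of a simulated social agent whose log10 discount rate sits one
unit above (impulsive) or below (patient) their own baseline, receiving
the agent's (mildly noisy) actual choice as feedback.

Ground truth that downstream estimators must recover is recorded for
every session: the per-block discounting mean, the preference
uncertainty, the agents' rates, and the susceptibility weights
(``omega``) that move the mean toward an observed agent. Susceptibility
is the generator's own construct — the fraction of the distance to the
agent's rate that the participant's mean travels after observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BeliefState, DesignConfig, OfferLattice, build_self_block, generative_pairs
from .models import Offer, choice_prob_kt, choice_prob_ku, subjective_value

__all__ = [
    "Agent",
    "GridBayesLearner",
    "OracleLearner",
    "CohortConfig",
    "Session",
    "make_agents",
    "simulate_agent_choice",
    "simulate_other_block",
    "apply_social_shift",
    "generate_cohort",
    "sessions_to_frame",
    "ground_truth_frame",
]

BLOCKS = ("Self1", "Other1", "Self2", "Other2", "Self3")


@dataclass(frozen=True)
class Agent:
    """A simulated social agent: a softmax hyperbolic discounter."""

    label: str  # "impulsive" | "patient"
    k_agent: float
    t_agent: float = 1.0  # log10 inverse temperature; T = 10 is mildly noisy


def make_agents(k_baseline: float, t_agent: float = 1.0):
    """The impulsive (+1) and patient (-1) agents for a given baseline rate."""
    if not np.isfinite(k_baseline):
        raise ValueError("k_baseline must be finite")
    return (
        Agent("impulsive", k_baseline + 1.0, t_agent),
        Agent("patient", k_baseline - 1.0, t_agent),
    )


def simulate_agent_choice(agent: Agent, offer: Offer, rng: np.random.Generator) -> bool:
    """One Bernoulli draw from the agent's softmax choice probability."""
    p = choice_prob_kt(offer, (agent.k_agent, agent.t_agent))
    return bool(rng.random() < p)


class GridBayesLearner:
    """Ideal observer of an agent's discount rate.

    Holds a gridded belief over the agent's log10 rate (prior normal
    around the participant's own baseline), predicts the option the
    posterior-mean agent would prefer, and updates by Bayes' rule from
    the feedback choice using the agent's softmax likelihood.
    """

    def __init__(self, prior_mean: float, prior_sd: float = 1.0, t_agent: float = 1.0,
                 grid_lo: float = -8.0, grid_hi: float = 2.0, n_points: int = 501):
        self.grid = np.linspace(grid_lo, grid_hi, n_points)
        dens = np.exp(-0.5 * ((self.grid - prior_mean) / prior_sd) ** 2)
        self.probs = dens / dens.sum()
        self.t_agent = t_agent

    def estimate(self) -> float:
        return float(np.dot(self.grid, self.probs))

    def predict(self, offer: Offer) -> bool:
        v_ss, v_ll = subjective_value(offer, self.estimate())
        return bool(v_ll > v_ss)

    def update(self, offer: Offer, chose_ll: bool) -> None:
        p = choice_prob_kt(offer, (self.grid, self.t_agent))
        like = p if chose_ll else 1.0 - p
        post = self.probs * like
        total = post.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("degenerate learner update")
        self.probs = post / total


class OracleLearner:
    """Knows the agent's rate exactly; optionally lapses with probability epsilon."""

    def __init__(self, k_agent: float, epsilon: float = 0.0, rng: np.random.Generator | None = None):
        self.k_agent = k_agent
        self.epsilon = epsilon
        self.rng = rng or np.random.default_rng()

    def predict(self, offer: Offer) -> bool:
        v_ss, v_ll = subjective_value(offer, self.k_agent)
        choice = bool(v_ll > v_ss)
        if self.epsilon and self.rng.random() < self.epsilon:
            choice = bool(self.rng.random() < 0.5)
        return choice

    def update(self, offer: Offer, chose_ll: bool) -> None:
        pass


def simulate_other_block(agent: Agent, learner, offers, rng: np.random.Generator):
    """Run one Other block: the learner predicts, the agent's choice is the feedback.

    Returns a list of records with keys ``trial_index, method, offer,
    choice_ll`` (the learner's prediction) and ``feedback_ll`` (the
    agent's simulated choice). The learner is updated in place after
    each trial.
    """
    records = []
    for i, offer in enumerate(offers):
        pred = bool(learner.predict(offer))
        feedback = simulate_agent_choice(agent, offer, rng)
        learner.update(offer, feedback)
        records.append(
            {"trial_index": i, "method": "generative", "offer": offer,
             "choice_ll": pred, "feedback_ll": feedback}
        )
    return records


def apply_social_shift(km_before: float, agent: Agent, omega: float) -> float:
    """Move the discounting mean a fraction ``omega`` of the way to the agent's rate."""
    if abs(omega) > 1:
        raise ValueError("omega must lie in [-1, 1]")
    return km_before + omega * (agent.k_agent - km_before)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a two-group design with 76 young and 78 older
    participants.
    Baseline discounting means are drawn inside the design's sensitive
    range; preference uncertainty is log-normal around 0.7. The default
    susceptibility profile gives older adults a positive weight for both
    agents and young adults a positive weight for the patient agent
    only — the pattern the end-to-end pipeline is expected to detect.
    """

    n_young: int = 76
    n_older: int = 78
    km_baseline_mean: float = -2.0
    km_baseline_sd: float = 0.75
    ku_log_mean: float = float(np.log(0.7))
    ku_log_sd: float = 0.3
    omega_impulsive_young: float = 0.0
    omega_patient_young: float = 0.4
    omega_impulsive_older: float = 0.4
    omega_patient_older: float = 0.4
    omega_sd: float = 0.1
    agent_t: float = 1.0
    learner: str = "grid_bayes"  # grid_bayes | oracle | noisy_oracle
    learner_epsilon: float = 0.1
    design: DesignConfig = field(default_factory=DesignConfig)

    def omega_means(self, group: str):
        if group == "young":
            return self.omega_impulsive_young, self.omega_patient_young
        return self.omega_impulsive_older, self.omega_patient_older


@dataclass
class Session:
    """One participant's complete 250-trial record plus generating truth."""

    participant_id: str
    group: str
    agent_order: str  # "impulsive-first" | "patient-first"
    true_km: dict  # per Self block: {"Self1": ..., "Self2": ..., "Self3": ...}
    true_ku: float
    omega: dict  # {"impulsive": ..., "patient": ...}
    agents: dict  # {"impulsive": Agent, "patient": Agent}
    k_baseline_est: float
    valid_agents: bool
    trials: list  # records with block/trial_index/method/offer/role/agent_label/choice/feedback


def _make_learner(config: CohortConfig, agent: Agent, k_baseline_est: float,
                  rng: np.random.Generator):
    if config.learner == "grid_bayes":
        return GridBayesLearner(prior_mean=k_baseline_est, t_agent=agent.t_agent)
    if config.learner == "oracle":
        return OracleLearner(agent.k_agent)
    if config.learner == "noisy_oracle":
        return OracleLearner(agent.k_agent, epsilon=config.learner_epsilon, rng=rng)
    raise ValueError(f"unknown learner model: {config.learner}")


def _ku_responder(km: float, ku: float, rng: np.random.Generator):
    def respond(offer: Offer) -> bool:
        return bool(rng.random() < choice_prob_ku(offer, (km, ku)))

    return respond


def _simulate_session(pid: str, group: str, order: str, config: CohortConfig,
                      lattice: OfferLattice, rng: np.random.Generator) -> Session:
    km_base = rng.normal(config.km_baseline_mean, config.km_baseline_sd)
    ku = float(np.exp(rng.normal(config.ku_log_mean, config.ku_log_sd)))
    om_imp_mean, om_pat_mean = config.omega_means(group)
    omega = {
        "impulsive": float(np.clip(rng.normal(om_imp_mean, config.omega_sd), -1, 1)),
        "patient": float(np.clip(rng.normal(om_pat_mean, config.omega_sd), -1, 1)),
    }

    trials = []

    def add(block, records, role, agent_label=None):
        for r in records:
            trials.append(
                {
                    "block": block,
                    "trial_index": r["trial_index"],
                    "method": r["method"],
                    "offer": r["offer"],
                    "role": role,
                    "agent_label": agent_label,
                    "choice_ll": r["choice_ll"],
                    "feedback_ll": r.get("feedback_ll"),
                }
            )

    # Self1 at the baseline preference
    belief = BeliefState.from_prior(config.design)
    records, belief = build_self_block(
        belief, _ku_responder(km_base, ku, rng), config.design, lattice
    )
    add("Self1", records, "self")

    # agents are built from the Self1 point estimate, as an experiment would set them
    k_est = belief.mean()
    impulsive, patient = make_agents(k_est, t_agent=config.agent_t)
    agents = {"impulsive": impulsive, "patient": patient}
    valid = all(-4.0 <= a.k_agent <= 0.0 for a in agents.values())

    order_labels = ("impulsive", "patient") if order == "impulsive-first" else ("patient", "impulsive")
    km = {"Self1": km_base}
    km_current = km_base
    gen50 = generative_pairs(50, config.design, lattice)
    for other_block, self_block, label in zip(("Other1", "Other2"), ("Self2", "Self3"), order_labels):
        agent = agents[label]
        learner = _make_learner(config, agent, k_est, rng)
        add(other_block, simulate_other_block(agent, learner, gen50, rng), "other", label)

        km_current = apply_social_shift(km_current, agent, omega[label])
        km[self_block] = km_current
        belief = BeliefState.from_prior(config.design)
        records, belief = build_self_block(
            belief, _ku_responder(km_current, ku, rng), config.design, lattice
        )
        add(self_block, records, "self")

    return Session(
        participant_id=pid,
        group=group,
        agent_order=order,
        true_km=km,
        true_ku=ku,
        omega=omega,
        agents=agents,
        k_baseline_est=float(k_est),
        valid_agents=valid,
        trials=trials,
    )


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0):
    """Generate the full synthetic cohort, reproducibly from ``seed``.

    Agent order is counterbalanced within each group. Sessions whose
    agents leave the design's sensitive range [-4, 0] are flagged
    (``valid_agents=False``) but kept.
    """
    if config.n_young < 0 or config.n_older < 0:
        raise ValueError("group sizes must be nonnegative")
    lattice = OfferLattice(config.design)
    sessions = []
    ss = np.random.SeedSequence(seed)
    plan = [("young", i) for i in range(config.n_young)] + [
        ("older", i) for i in range(config.n_older)
    ]
    children = ss.spawn(len(plan))
    for (group, i), child in zip(plan, children):
        order = "impulsive-first" if i % 2 == 0 else "patient-first"
        pid = f"{group[0]}{i:03d}"
        rng = np.random.default_rng(child)
        sessions.append(_simulate_session(pid, group, order, config, lattice, rng))
    return sessions


def sessions_to_frame(sessions) -> pd.DataFrame:
    """Long trial table for a cohort (one row per trial)."""
    rows = []
    for s in sessions:
        for t in s.trials:
            o = t["offer"]
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "group": s.group,
                    "block": t["block"],
                    "trial_index": t["trial_index"],
                    "method": t["method"],
                    "m_ss": o.m_ss,
                    "m_ll": o.m_ll,
                    "delay_days": o.d,
                    "role": t["role"],
                    "agent_label": t["agent_label"],
                    "choice_ll": int(t["choice_ll"]),
                    "feedback_ll": None if t["feedback_ll"] is None else int(t["feedback_ll"]),
                }
            )
    return pd.DataFrame(rows)


def ground_truth_frame(sessions) -> pd.DataFrame:
    """Per-participant generating parameters (the recovery targets)."""
    rows = []
    for s in sessions:
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "agent_order": s.agent_order,
                "km_self1": s.true_km["Self1"],
                "km_self2": s.true_km["Self2"],
                "km_self3": s.true_km["Self3"],
                "ku": s.true_ku,
                "omega_impulsive": s.omega["impulsive"],
                "omega_patient": s.omega["patient"],
                "k_agent_impulsive": s.agents["impulsive"].k_agent,
                "k_agent_patient": s.agents["patient"].k_agent,
                "k_baseline_est": s.k_baseline_est,
                "valid_agents": s.valid_agents,
            }
        )
    return pd.DataFrame(rows)
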