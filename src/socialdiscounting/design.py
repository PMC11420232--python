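"""Choice-pair generation for the delegated inter-temporal choice task.

Two complementary methods produce trials:

* **generative** — enumerate the full lattice of amount/delay
  combinations (integer pounds 1-20, integer days 1-90, delayed amount
  strictly larger) and pick, for each of ``n`` hypothetical discount
  rates evenly spread over a target range (default [-4, 0]), the pair
  whose indifference point is closest to that rate;
* **adaptive** — maintain a gridded Bayesian belief over the
  respondent's log10 discount rate (prior N(-2, 1), softmax likelihood
  with fixed log10 inverse temperature t = 0.3), update it after every
  observed choice, and probe the posterior-mean indifference point.

Self blocks alternate the two methods trial by trial (25 + 25); Other
blocks and parameter-recovery designs use the generative method alone
with 50 targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import Offer, choice_prob_kt, indifference_k

__all__ = [
    "DesignConfig",
    "BeliefState",
    "OfferLattice",
    "generative_pairs",
    "adaptive_update",
    "adaptive_next_pair",
    "build_self_block",
    "design_to_frame",
]


@dataclass(frozen=True)
class DesignConfig:
    """Bounds and sizes of the task design."""

    amount_min: int = 1
    amount_max: int = 20
    delay_min: int = 1
    delay_max: int = 90
    n_trials_per_block: int = 50
    k_grid_lo: float = -4.0
    k_grid_hi: float = 0.0
    unique_pairs: bool = False
    #: belief grid for the adaptive method; covers the N(-2, 1) prior
    #: well beyond +-4 SD on both sides so the prior mean is unbiased
    belief_lo: float = -8.0
    belief_hi: float = 2.0
    belief_points: int = 501
    belief_prior_mean: float = -2.0
    belief_prior_sd: float = 1.0
    belief_t: float = 0.3

    def __post_init__(self) -> None:
        if self.amount_min >= self.amount_max:
            raise ValueError("amount_min must be below amount_max")
        if self.delay_min > self.delay_max:
            raise ValueError("delay_min must not exceed delay_max")
        if self.k_grid_lo >= self.k_grid_hi:
            raise ValueError("k_grid_lo must be below k_grid_hi")


class OfferLattice:
    """Every admissible (m_ss, m_ll, d) combination with its indifference point.

    Ties in closeness to a target are broken by smaller delay, then
    smaller immediate amount, so lookups are deterministic.
    """

    def __init__(self, config: DesignConfig):
        amounts = np.arange(config.amount_min, config.amount_max + 1)
        ss, ll = np.meshgrid(amounts, amounts, indexing="ij")
        keep = ll > ss
        ss, ll = ss[keep], ll[keep]
        delays = np.arange(config.delay_min, config.delay_max + 1)
        self.m_ss = np.repeat(ss, delays.size).astype(float)
        self.m_ll = np.repeat(ll, delays.size).astype(float)
        self.d = np.tile(delays, ss.size).astype(float)
        if self.m_ss.size == 0:
            raise ValueError("empty offer lattice")
        self.ik = indifference_k((self.m_ss, self.m_ll, self.d))
        # pre-sorted tie-break order: delay, then m_ss
        self._tie_order = np.lexsort((self.m_ss, self.d))

    def nearest(self, target_k: float, exclude=None) -> int:
        """Index of the lattice offer whose indifference point is closest to ``target_k``."""
        dist = np.abs(self.ik - target_k)
        if exclude:
            dist = dist.copy()
            dist[list(exclude)] = np.inf
        order = self._tie_order
        best = order[np.argmin(dist[order])]
        if not np.isfinite(dist[best]):
            raise ValueError("no admissible offer left in the lattice")
        return int(best)

    def offer(self, idx: int) -> Offer:
        return Offer(m_ss=self.m_ss[idx], m_ll=self.m_ll[idx], d=self.d[idx])


@dataclass(frozen=True)
class BeliefState:
    """Gridded posterior over a respondent's log10 discount rate."""

    grid: np.ndarray
    probs: np.ndarray
    t: float = 0.3

    def __post_init__(self) -> None:
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("belief probabilities must be nonnegative and sum to 1")

    @classmethod
    def from_prior(cls, config: DesignConfig = DesignConfig()) -> "BeliefState":
        grid = np.linspace(config.belief_lo, config.belief_hi, config.belief_points)
        dens = np.exp(-0.5 * ((grid - config.belief_prior_mean) / config.belief_prior_sd) ** 2)
        return cls(grid=grid, probs=dens / dens.sum(), t=config.belief_t)

    def mean(self) -> float:
        return float(np.dot(self.grid, self.probs))


def generative_pairs(n: int, config: DesignConfig = DesignConfig(), lattice: OfferLattice | None = None):
    """``n`` offers whose indifference points track ``n`` evenly spaced target rates.

    Deterministic given the config; duplicate pairs are allowed unless
    ``config.unique_pairs`` is set.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    lattice = lattice or OfferLattice(config)
    targets = np.linspace(config.k_grid_lo, config.k_grid_hi, n) if n > 1 else np.array(
        [(config.k_grid_lo + config.k_grid_hi) / 2.0]
    )
    offers, used = [], set()
    for tk in targets:
        idx = lattice.nearest(tk, exclude=used if config.unique_pairs else None)
        if config.unique_pairs:
            used.add(idx)
        offers.append(lattice.offer(idx))
    return offers


def adaptive_update(belief: BeliefState, offer: Offer, chose_ll) -> BeliefState:
    """Bayes update of the belief grid from one observed choice.

    The likelihood is the softmax (point-estimate) choice rule evaluated
    at every grid rate with the belief's fixed temperature.
    """
    p_ll = choice_prob_kt(offer, (belief.grid, belief.t))
    like = p_ll if chose_ll else 1.0 - p_ll
    post = belief.probs * like
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate belief update: zero posterior mass")
    return replace(belief, probs=post / total)


def adaptive_next_pair(belief: BeliefState, config: DesignConfig = DesignConfig(),
                       lattice: OfferLattice | None = None) -> Offer:
    """The lattice offer probing the current posterior-mean discount rate."""
    lattice = lattice or OfferLattice(config)
    return lattice.offer(lattice.nearest(belief.mean()))


def build_self_block(belief: BeliefState, responder, config: DesignConfig = DesignConfig(),
                     lattice: OfferLattice | None = None):
    """Run one Self block, alternating generative and adaptive trials.

    ``responder(offer) -> bool`` supplies the choice for each presented
    offer. The belief is updated after every response, and adaptive
    offers probe the running posterior mean. Returns
    ``(records, belief)`` where each record is a dict with keys
    ``trial_index, method, offer, choice_ll``.
    """
    lattice = lattice or OfferLattice(config)
    n = config.n_trials_per_block
    n_gen = n // 2
    gen_offers = iter(generative_pairs(n_gen, config, lattice))
    records = []
    for i in range(n):
        if i % 2 == 0 and i // 2 < n_gen:
            method, offer = "generative", next(gen_offers)
        else:
            method, offer = "adaptive", adaptive_next_pair(belief, config, lattice)
        choice = bool(responder(offer))
        belief = adaptive_update(belief, offer, choice)
        records.append({"trial_index": i, "method": method, "offer": offer, "choice_ll": choice})
    return records, belief


def design_to_frame(offers, block: str = "", method: str = "generative") -> pd.DataFrame:
    """Tabular export of a list of offers."""
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(offers)),
            "block": block,
            "method": method,
            "m_ss": [o.m_ss for o in offers],
            "m_ll": [o.m_ll for o in offers],
            "delay_days": [o.d for o in offers],
            "indifference_k": [float(indifference_k(o)) for o in offers],
        }
    )
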