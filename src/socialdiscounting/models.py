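"""Hyperbolic discounting choice models.

Two offers are on the table each trial: a smaller amount ``m_ss`` paid
today and a larger amount ``m_ll`` paid after a delay of ``d`` days. The
subjective value of the delayed offer follows the hyperbolic form

    V_LL = M_LL / (1 + K * D),        K = 10**k,

with the discount rate always handled on the log10 scale (``k``); more
negative ``k`` means more patient. The immediate offer is worth its face
value (delay 0).

Two decision rules are implemented:

* the point-estimate ("KT") rule: a softmax over the value difference
  with inverse temperature ``T = 10**t``;
* the preference-uncertainty ("KU") rule: the decision-maker's discount
  rate is a normal belief N(km, ku**2); a rate is sampled and the
  higher-valued offer is chosen deterministically, which makes the
  larger-later choice probability the normal CDF evaluated at the
  offer's indifference point.

Two optional noise transforms (a symmetric lapse ``xi`` and a
temperature-like compressor ``tau``) produce the noisy model variants.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "Offer",
    "KTParams",
    "DiscountingDistribution",
    "NoiseParams",
    "PROB_EPS",
    "subjective_value",
    "indifference_k",
    "choice_prob_kt",
    "choice_prob_ku",
    "apply_self_noise",
    "apply_other_noise",
    "clip_prob",
]

#: probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] before any log
PROB_EPS = 1e-12


@dataclass(frozen=True)
class Offer:
    """One trial's choice pair: ``m_ss`` paid today vs ``m_ll`` in ``d`` days."""

    m_ss: float
    m_ll: float
    d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m_ss) and np.isfinite(self.m_ll) and np.isfinite(self.d)):
            raise ValueError("offer fields must be finite")
        if self.m_ss <= 0 or self.m_ll <= 0:
            raise ValueError("amounts must be positive")
        if self.m_ll <= self.m_ss:
            raise ValueError("the delayed offer must be strictly larger (m_ll > m_ss)")
        if self.d < 1:
            raise ValueError("delay must be at least one day")


@dataclass(frozen=True)
class KTParams:
    """Point-estimate decision rule parameters: log10 rate ``k``, log10 inverse temperature ``t``."""

    k: float
    t: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and np.isfinite(self.t)):
            raise ValueError("k and t must be finite")


@dataclass(frozen=True)
class DiscountingDistribution:
    """Normal belief over the log10 discount rate: mean ``km``, SD ``ku > 0``."""

    km: float
    ku: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.km) and np.isfinite(self.ku)):
            raise ValueError("km and ku must be finite")
        if self.ku <= 0:
            raise ValueError("ku must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Lapse probability ``xi`` in [0, 1] and compressor exponent ``tau`` in (0, 10]."""

    xi: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if not 0.0 < self.tau <= 10.0:
            raise ValueError("tau must lie in (0, 10]")


def clip_prob(p):
    """Clip probabilities away from exact 0/1 for log-likelihood safety."""
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def _offer_arrays(offer):
    if isinstance(offer, Offer):
        return offer.m_ss, offer.m_ll, offer.d
    m_ss, m_ll, d = offer
    return np.asarray(m_ss, float), np.asarray(m_ll, float), np.asarray(d, float)


def subjective_value(offer, k):
    """Hyperbolic subjective values ``(v_ss, v_ll)`` of both offers.

    ``v_ss`` equals the immediate amount (its delay is zero); ``v_ll``
    is discounted by ``1 + 10**k * d``.
    """
    m_ss, m_ll, d = _offer_arrays(offer)
    k = np.asarray(k, float)
    if not np.all(np.isfinite(k)):
        raise ValueError("k must be finite")
    if np.any(np.asarray(m_ss) <= 0) or np.any(np.asarray(m_ll) <= 0):
        raise ValueError("amounts must be positive")
    v_ll = m_ll / (1.0 + np.power(10.0, k) * d)
    return m_ss + np.zeros_like(v_ll), v_ll


def indifference_k(offer):
    """The log10 discount rate at which the two offers are equally valued.

    ``log10((m_ll / m_ss - 1) / d)``: a point-estimate chooser prefers
    the delayed offer exactly when its rate is below this threshold.
    """
    m_ss, m_ll, d = _offer_arrays(offer)
    if np.any(np.asarray(m_ll) <= np.asarray(m_ss)):
        raise ValueError("indifference point undefined unless m_ll > m_ss")
    if np.any(np.asarray(d) <= 0):
        raise ValueError("indifference point undefined for non-positive delay")
    return np.log10((m_ll / m_ss - 1.0) / d)


def choice_prob_kt(offer, params):
    """Softmax probability of choosing the larger-later offer.

    ``params`` may be a :class:`KTParams` or a ``(k, t)`` tuple of
    (broadcastable) arrays; ``t`` is log10 of the inverse temperature.
    """
    if isinstance(params, KTParams):
        k, t = params.k, params.t
    else:
        k, t = params
    v_ss, v_ll = subjective_value(offer, k)
    temp = np.power(10.0, np.asarray(t, float))
    return expit(temp * (v_ll - v_ss))


def choice_prob_ku(offer, dist):
    """Larger-later choice probability under the preference-uncertainty rule.

    Equals ``NormalCDF(indifference_k(offer); km, ku**2)``: the chance
    that a rate sampled from the belief falls below the offer's
    indifference point.
    """
    if isinstance(dist, DiscountingDistribution):
        km, ku = dist.km, dist.ku
    else:
        km, ku = dist
    ku = np.asarray(ku, float)
    if np.any(ku <= 0):
        raise ValueError("ku must be positive")
    thresh = indifference_k(offer)
    return ndtr((thresh - np.asarray(km, float)) / ku)


def apply_self_noise(p, xi):
    """Mix a choice probability with a symmetric lapse: ``p*(1-xi) + xi/2``."""
    p = np.asarray(p, float)
    xi = np.asarray(xi, float)
    if np.any((xi < 0) | (xi > 1)):
        raise ValueError("xi must lie in [0, 1]")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    return p * (1.0 - xi) + xi / 2.0


def apply_other_noise(p, tau):
    """Compress a choice probability toward 0.5 by exponent ``1/tau``.

    ``p' = p**(1/tau) / (p**(1/tau) + (1-p)**(1/tau))``; identity at
    ``tau = 1``. Exact 0 and 1 are fixed points and returned unchanged.
    """
    p = np.asarray(p, float)
    tau = np.asarray(tau, float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    # work on log odds for numerical stability; 0/1 map to themselves
    with np.errstate(divide="ignore"):
        logit = np.log(p) - np.log1p(-p)
    return expit(logit / tau)
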