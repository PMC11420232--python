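"""Signed Kullback-Leibler divergence between discounting distributions.

The influence statistic compares a participant's fitted discounting
distribution (normal over the log10 rate) at the end of two consecutive
Self blocks. Its magnitude is the KL divergence of the later
distribution from the earlier one, computed in **log10 units**: the
defining integral uses a base-10 logarithm, so the closed-form normal
KL in nats is divided by ln(10). Its sign is positive when the mean
moved toward the agent observed in between (the difference
``km_other - km_base`` has the same sign as ``km_after - km_base``) and
negative when it moved away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DiscountingDistribution

__all__ = ["SignedDkl", "kl_divergence", "signed_dkl", "session_influence"]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class SignedDkl:
    """Magnitude, sign, and operands of one influence statistic."""

    magnitude: float
    sign: int
    value: float  # sign * magnitude; 0 when the mean did not move
    km_base: float
    km_after: float
    km_other: float


def _dist(d):
    if isinstance(d, DiscountingDistribution):
        return d.km, d.ku
    km, ku = d
    return float(km), float(ku)


def kl_divergence(p, q) -> float:
    """KL divergence D(P || Q) between two normal discounting beliefs, in log10 units.

    Closed form for normals, divided by ln(10); nonnegative, zero iff
    the distributions coincide.
    """
    m1, s1 = _dist(p)
    m2, s2 = _dist(q)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    nats = np.log(s2 / s1) + (s1**2 + (m1 - m2) ** 2) / (2.0 * s2**2) - 0.5
    return float(nats / _LN10)


def signed_dkl(dist_base, dist_after, km_other: float, *, tol: float = 1e-9,
               reverse: bool = False) -> SignedDkl:
    """Signed divergence of ``dist_after`` from ``dist_base``.

    The sign follows the ratio rule: positive when the shift of the
    mean from baseline points toward ``km_other``, negative when it
    points away. Mean shifts smaller than ``tol`` yield sign 0 and a
    signed value of 0 (the magnitude, which may be nonzero through a
    pure uncertainty change, is still reported). ``reverse`` flips the
    KL operand order.
    """
    km_base, _ = _dist(dist_base)
    km_after, _ = _dist(dist_after)
    mag = kl_divergence(dist_base, dist_after) if reverse else kl_divergence(dist_after, dist_base)
    d_self = km_after - km_base
    d_other = km_other - km_base
    if abs(d_self) < tol:
        sign = 0
    else:
        sign = int(np.sign(d_other * d_self))
    return SignedDkl(
        magnitude=mag,
        sign=sign,
        value=float(sign * mag),
        km_base=float(km_base),
        km_after=float(km_after),
        km_other=float(km_other),
    )


def session_influence(block_params: pd.DataFrame, agent_labels: pd.DataFrame,
                      reverse: bool = False) -> pd.DataFrame:
    """Per-participant impulsive and patient signed divergences.

    ``block_params`` is tidy with columns ``participant_id, block, km,
    ku`` holding fitted discounting parameters for the Self blocks and
    the agent-attributed ``km`` for the Other blocks. ``agent_labels``
    maps ``participant_id, block`` (Other1/Other2) to ``agent_label``
    (impulsive/patient). The first statistic compares Self1 -> Self2
    around Other1, the second Self2 -> Self3 around Other2; each is
    labelled by the agent observed in between. Missing blocks give NaN
    rather than failure.
    """
    wide = block_params.pivot_table(index="participant_id", columns="block",
                                    values=["km", "ku"], aggfunc="first")
    labels = agent_labels.pivot_table(index="participant_id", columns="block",
                                      values="agent_label", aggfunc="first")
    rows = []
    for pid in wide.index:
        out = {"participant_id": pid, "impulsive_dkl": np.nan, "patient_dkl": np.nan}
        for other_block, (blk_a, blk_b) in {"Other1": ("Self1", "Self2"),
                                            "Other2": ("Self2", "Self3")}.items():
            try:
                label = labels.loc[pid, other_block]
                km_a, ku_a = wide.loc[pid, ("km", blk_a)], wide.loc[pid, ("ku", blk_a)]
                km_b, ku_b = wide.loc[pid, ("km", blk_b)], wide.loc[pid, ("ku", blk_b)]
                km_other = wide.loc[pid, ("km", other_block)]
            except KeyError:
                continue
            vals = [label, km_a, ku_a, km_b, ku_b, km_other]
            if any(pd.isna(v) for v in vals):
                continue
            stat = signed_dkl((km_a, ku_a), (km_b, ku_b), km_other, reverse=reverse)
            out[f"{label}_dkl"] = stat.value
        rows.append(out)
    return pd.DataFrame(rows)
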