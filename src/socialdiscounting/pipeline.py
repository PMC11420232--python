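"""End-to-end analysis of a cohort: per-block fits to influence contrasts.

Given trial data in the long session format, this module fits the
preference-uncertainty model separately per group and per block (with
freshly instantiated priors each time), attributes each Other block's
agent preference to the participant from their own predictions, builds
the per-participant signed-divergence table, scores Other-block
learning accuracy, and runs the standard nonparametric contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import chance_test, contrast_groups, score_learning
from .cohort import BLOCKS
from .fitting import FitConfig, PosteriorFit, fit_block, individual_point_estimates
from .influence import session_influence

__all__ = [
    "fit_cohort_blocks",
    "block_estimates",
    "cohort_influence",
    "learning_accuracy",
    "analyse_cohort",
]


def fit_cohort_blocks(trials: pd.DataFrame, fit_config: FitConfig | None = None,
                      model: str = "ku", blocks=BLOCKS) -> dict:
    """Fit ``model`` separately for every (group, block) cell.

    Returns ``{(group, block): PosteriorFit}``. Seeds for each cell are
    derived from ``fit_config.seed`` so the whole pass is reproducible.
    """
    fit_config = fit_config or FitConfig()
    groups = list(pd.unique(trials["group"]))
    fits = {}
    base = np.random.SeedSequence(fit_config.seed)
    children = iter(base.spawn(len(groups) * len(blocks)))
    for group in groups:
        for block in blocks:
            sub = trials[(trials["group"] == group) & (trials["block"] == block)]
            if sub.empty:
                continue
            seed = int(next(children).generate_state(1)[0] % (2**31))
            cfg = FitConfig(**{**fit_config.__dict__, "seed": seed, "store_loglik": False})
            fits[(group, block)] = fit_block(model, sub, cfg, block=block, group=group)
    return fits


def block_estimates(fits: dict) -> pd.DataFrame:
    """Tidy per-participant posterior-mean (km, ku) for every fitted cell."""
    rows = []
    for (group, block), fit in fits.items():
        est = individual_point_estimates(fit)
        est["group"] = group
        est["block"] = block
        rows.append(est)
    return pd.concat(rows, ignore_index=True)


def cohort_influence(trials: pd.DataFrame, fits: dict) -> pd.DataFrame:
    """Per-participant signed divergences, labelled by observed agent."""
    params = block_estimates(fits)
    labels = (
        trials.loc[trials["role"] == "other", ["participant_id", "block", "agent_label"]]
        .drop_duplicates()
    )
    table = session_influence(params, labels)
    groups = trials[["participant_id", "group"]].drop_duplicates()
    return table.merge(groups, on="participant_id")


def learning_accuracy(trials: pd.DataFrame, agent_truth: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per participant and agent, with right-tailed chance tests.

    ``agent_truth`` has columns ``participant_id, agent_label, k_agent``
    (the true simulated rates, available for synthetic cohorts).
    """
    rows = []
    truth = agent_truth.set_index(["participant_id", "agent_label"])["k_agent"]
    for (pid, block), sub in trials[trials["role"] == "other"].groupby(
        ["participant_id", "block"], sort=False
    ):
        label = sub["agent_label"].iloc[0]
        rec = score_learning(sub, float(truth.loc[(pid, label)]),
                             participant_id=pid, agent_label=label)
        rows.append(
            {
                "participant_id": pid,
                "block": block,
                "agent_label": label,
                "accuracy": rec.accuracy,
                "n_correct": rec.n_correct,
                "n_scored": rec.n_scored,
                "n_excluded": rec.n_excluded,
                "p_chance": chance_test(rec.n_correct, rec.n_scored),
            }
        )
    return pd.DataFrame(rows)


def analyse_cohort(trials: pd.DataFrame, agent_truth: pd.DataFrame | None = None,
                   fit_config: FitConfig | None = None, seed: int = 0) -> dict:
    """Full pipeline: fits, influence table, learning table, group contrasts.

    Returns a dict with keys ``fits``, ``influence``, ``learning`` (if
    ``agent_truth`` given) and ``contrasts`` (between-group rank-sum
    tests of the impulsive and patient signed divergences, and
    one-sample tests against zero).
    """
    fits = fit_cohort_blocks(trials, fit_config)
    influence = cohort_influence(trials, fits)
    groups = list(pd.unique(trials["group"]))
    contrasts = {}
    if len(groups) == 2:
        for label in ("impulsive", "patient"):
            contrasts[f"between_{label}"] = contrast_groups(
                influence,
                {"kind": "between", "value": f"{label}_dkl", "group": "group",
                 "levels": (groups[0], groups[1])},
                seed=seed,
            )
    for label in ("impulsive", "patient"):
        contrasts[f"vs_zero_{label}"] = contrast_groups(
            influence, {"kind": "one_sample", "value": f"{label}_dkl"}, seed=seed
        )
    out = {"fits": fits, "influence": influence, "contrasts": contrasts}
    if agent_truth is not None:
        out["learning"] = learning_accuracy(trials, agent_truth)
    return out
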