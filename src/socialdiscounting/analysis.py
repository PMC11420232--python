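"""Behavioural summaries and nonparametric group statistics.

Learning accuracy in the Other blocks is scored against the objectively
better option under the observed agent's true discount rate, compared
to chance with right-tailed exact binomial tests, and contrasted across
groups and agent types with Wilcoxon rank tests (rank-sum between
groups, signed-rank within participants or against zero). Effect sizes
are reported as r = |Z| / sqrt(n) with bootstrap confidence intervals.
Trait correlations use Spearman's rho with Benjamini-Hochberg false
discovery rate adjustment, and pairs of independent correlations are
compared with Fisher-Z tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import subjective_value

__all__ = [
    "LearningRecord",
    "TestReport",
    "CorrelationReport",
    "score_learning",
    "chance_test",
    "rank_sum_test",
    "signed_rank_test",
    "contrast_groups",
    "trait_correlation",
    "fdr_adjust",
    "compare_independent_correlations",
    "synthetic_trait_scores",
]


@dataclass(frozen=True)
class LearningRecord:
    participant_id: str
    agent_label: str
    correct: np.ndarray
    n_scored: int
    n_excluded: int

    @property
    def accuracy(self) -> float:
        return float(self.correct.mean()) if self.n_scored else np.nan

    @property
    def n_correct(self) -> int:
        return int(self.correct.sum())


@dataclass(frozen=True)
class TestReport:
    kind: str
    statistic: float
    z: float
    p: float
    effect_size_r: float
    r_ci: tuple
    n: int


@dataclass(frozen=True)
class CorrelationReport:
    rho: float
    p: float
    n: int
    ci: tuple


def score_learning(trials: pd.DataFrame, agent_k: float, *, participant_id: str = "",
                   agent_label: str = "") -> LearningRecord:
    """Score Other-block predictions against the higher-valued option.

    A prediction is correct when it picks the option with the higher
    hyperbolic subjective value under the agent's true rate. Trials at
    exact indifference are excluded from scoring (their count is
    recorded).
    """
    offers = (trials["m_ss"].to_numpy(float), trials["m_ll"].to_numpy(float),
              trials["delay_days"].to_numpy(float))
    v_ss, v_ll = subjective_value(offers, agent_k)
    tied = v_ll == v_ss
    better_ll = v_ll > v_ss
    chose_ll = trials["choice_ll"].to_numpy().astype(bool)
    correct = (chose_ll == better_ll)[~tied]
    return LearningRecord(
        participant_id=participant_id,
        agent_label=agent_label,
        correct=correct,
        n_scored=int((~tied).sum()),
        n_excluded=int(tied.sum()),
    )


def chance_test(n_correct: int, n_trials: int) -> float:
    """Right-tailed exact binomial p-value against 50% accuracy."""
    return float(stats.binomtest(int(n_correct), int(n_trials), 0.5,
                                 alternative="greater").pvalue)


def _bootstrap_r(stat_fn, samples, rng, n_boot=2000):
    rs = []
    for _ in range(n_boot):
        resampled = [s[rng.integers(0, len(s), len(s))] for s in samples]
        try:
            rs.append(stat_fn(*resampled))
        except ValueError:
            continue
    if not rs:
        return (np.nan, np.nan)
    return tuple(np.percentile(rs, [2.5, 97.5]))


def _rank_sum_zr(x, y):
    n1, n2 = len(x), len(y)
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if sd == 0:
        raise ValueError("degenerate (all-tied) data")
    z = (u - n1 * n2 / 2.0) / sd
    return z, abs(z) / np.sqrt(n)


def rank_sum_test(x, y, seed: int | None = 0) -> TestReport:
    """Two-sided independent Wilcoxon rank-sum test with effect size r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    z, r = _rank_sum_zr(x, y)
    ci = _bootstrap_r(lambda a, b: _rank_sum_zr(a, b)[1], [x, y],
                      np.random.default_rng(seed))
    return TestReport("rank_sum", float(res.statistic), float(z), float(res.pvalue),
                      float(r), ci, len(x) + len(y))


def _signed_rank_zr(x):
    d = x[x != 0]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate (all-zero) differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sd2 = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if sd2 <= 0:
        raise ValueError("degenerate (all-tied) data")
    z = (w_plus - mean) / np.sqrt(sd2)
    return w_plus, z, abs(z) / np.sqrt(len(x))


def signed_rank_test(x, y=None, seed: int | None = 0) -> TestReport:
    """Two-sided Wilcoxon signed-rank test (paired, or one-sample vs 0)."""
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    if np.all(d == 0):
        raise ValueError("degenerate (all-zero) differences")
    res = stats.wilcoxon(d[d != 0])
    w, z, r = _signed_rank_zr(d)
    ci = _bootstrap_r(lambda a: _signed_rank_zr(a)[2], [d], np.random.default_rng(seed))
    return TestReport("signed_rank", float(res.statistic), float(z), float(res.pvalue),
                      float(r), ci, len(d))


def contrast_groups(table: pd.DataFrame, contrast: dict, seed: int | None = 0) -> TestReport:
    """Run one declared contrast on a per-participant results table.

    ``contrast`` kinds:

    * ``{"kind": "between", "value": col, "group": col, "levels": (a, b)}``
      — independent rank-sum of ``value`` between the two group levels;
    * ``{"kind": "within", "values": (col_a, col_b)}`` — paired
      signed-rank of the two columns;
    * ``{"kind": "one_sample", "value": col}`` — signed-rank against 0.
    """
    kind = contrast["kind"]
    if kind == "between":
        a, b = contrast["levels"]
        col, grp = contrast["value"], contrast["group"]
        x = table.loc[table[grp] == a, col].dropna().to_numpy()
        y = table.loc[table[grp] == b, col].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least two observations per cell")
        return rank_sum_test(x, y, seed=seed)
    if kind == "within":
        ca, cb = contrast["values"]
        sub = table[[ca, cb]].dropna()
        return signed_rank_test(sub[ca].to_numpy(), sub[cb].to_numpy(), seed=seed)
    if kind == "one_sample":
        x = table[contrast["value"]].dropna().to_numpy()
        return signed_rank_test(x, seed=seed)
    raise ValueError(f"unknown contrast kind: {kind}")


def trait_correlation(influence, traits) -> CorrelationReport:
    """Spearman correlation with a Fisher-Z 95% confidence interval."""
    x = np.asarray(influence, float)
    y = np.asarray(traits, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least five complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    n = len(x)
    z = np.arctanh(np.clip(res.statistic, -0.999999, 0.999999))
    half = 1.96 / np.sqrt(n - 3)
    return CorrelationReport(
        rho=float(res.statistic),
        p=float(res.pvalue),
        n=n,
        ci=(float(np.tanh(z - half)), float(np.tanh(z + half))),
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over one comparison family."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def compare_independent_correlations(r1: float, n1: int, r2: float, n2: int):
    """Fisher-Z test for the difference of two independent correlations.

    Returns ``(z, p)`` for the two-sided test.
    """
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def synthetic_trait_scores(omega, rho: float, rng) -> np.ndarray:
    """Gaussian trait scores with target correlation ``rho`` to a susceptibility vector.

    Pure test fixture: no psychometric realism is claimed.
    """
    rng = np.random.default_rng(rng)
    w = np.asarray(omega, float)
    zw = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
    return rho * zw + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(w))
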