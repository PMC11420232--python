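# Methods

This note documents the models, the synthetic-data generator, the
estimation machinery, and the numerical and design choices behind
`socialdiscounting`. Everything stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## Choice models

A trial offers `m_ss` pounds today against `m_ll > m_ss` pounds after `d ≥ 1`
days (task-conformant designs keep amounts in £1–£20 and delays in 1–90
days). Delayed value is hyperbolic, `V_LL = m_ll / (1 + 10^k · d)`, with the
discount rate stored exclusively on the log10 scale: `k` near 0 means steep
discounting (impulsive), strongly negative `k` means patience. The *indifference
point* of an offer, `log10((m_ll/m_ss − 1)/d)`, is the rate at which the two
options have equal value; it is undefined (and an error) for `m_ll ≤ m_ss`,
which a valid design never produces.

Four models map values to a larger-later choice probability:

| model | parameters | rule |
|---|---|---|
| KT | `k < 0`, `t ∈ [−1, 1]` | logistic in `T·(V_LL − V_SS)`, `T = 10^t` |
| KU | `km < 0`, `ku > 0` | normal CDF of the indifference point under `N(km, ku²)` |
| KU+ξ | + `ξ ∈ [0, 1]` | symmetric lapse `p(1−ξ) + ξ/2` |
| KU+τ | + `τ ∈ (0, 10]` | log-odds compression `logit(p)/τ` |

The KU rule is the generative account of preference uncertainty: a rate is
sampled from the belief each trial and the higher-valued option is chosen
deterministically, which integrates to the probit-like CDF form. All
probabilities are clipped to `[1e−12, 1 − 1e−12]` before any logarithm; the
τ transform treats exact 0 and 1 as fixed points.

## Trial design

**Generative method.** The offer lattice enumerates integer pounds
(1–20, delayed strictly larger) × integer days (1–90), 17 100 combinations;
integer currency granularity is a package choice — the task's display
conventions do not resolve it. For `n` trials, target rates are evenly
spaced over [−4, 0] and each target is matched to the lattice offer with
the nearest indifference point (ties broken by smaller delay, then smaller
immediate amount, so designs are fully deterministic). Note the lattice's
most patient reachable indifference point is ≈ −3.23, so the most patient
targets share it; duplicates are allowed unless `unique_pairs` is set.

**Adaptive method.** A belief over the respondent's rate is held on a
501-point grid spanning [−8, 2] (0.02 spacing), initialised to a normal
with mean −2 and SD 1 and updated by Bayes' rule after *every* choice,
using the KT likelihood with fixed `t = 0.3` (log10 scale, i.e. `T ≈ 2`).
The next adaptive offer probes the current posterior mean. The grid covers
the prior beyond ±4 SD on both sides; a one-sided grid truncated at 0 would
bias the prior mean by ≈ −0.05 and shift the first probe off its nominal
target of −2. Self blocks strictly alternate generative and adaptive trials
(25 + 25); Other blocks use 50 generative trials.

Adaptive consistency is verified by simulation: mean absolute error of the
posterior mean against a softmax simulant's true rate drops from ≈ 0.13
after 5 trials to ≈ 0.06 after 25 (100 replicates).

## Synthetic cohort

The generator emulates the two-group study structure: 76 young and 78
older participants by default, five blocks of 50 trials each. Per
participant:

- baseline discounting mean `km ~ N(−2, 0.75)` (inside the design's
  sensitive range) and preference uncertainty `ku ~ LogNormal(log 0.7, 0.3)`
  — a spread chosen to give psychometrically plausible, neither degenerate
  nor coin-flip, choice behaviour;
- Self-block choices are drawn from the KU model at the block's effective
  `(km, ku)`;
- the two agents take rates one log10 unit above and below the *estimated*
  baseline (the Self1 adaptive-belief mean, mirroring how an experiment
  would set them), with softmax noise `t = 1` read as `T = 10` — mildly
  noisy, configurable. Sessions whose agents leave [−4, 0] are flagged,
  not dropped;
- agent order (impulsive-first vs patient-first) is counterbalanced;
- Other-block behaviour needs a learner model; the default is a grid-Bayes
  ideal observer over the agent's rate (prior `N(k̂_baseline, 1)`) that
  predicts the posterior-mean agent's preferred option and updates from the
  feedback choice. Noiseless and ε-noisy oracles are available. The ideal
  observer scores ≈ 98% against the higher-value criterion — an upper
  bound, deliberately cleaner than human learning;
- **susceptibility** `ω ∈ [−1, 1]` is the generator's ground-truth
  construct: after observing an agent, the discounting mean moves
  `km → km + ω·(k_agent − km)`. Effective means chain across blocks
  (Self2 shifts from baseline toward the first agent, Self3 from Self2
  toward the second). `ku` is held constant unless configured. Group
  defaults give older adults `ω = 0.4` for both agents and young adults
  `ω = 0.4` for the patient agent only (0 for impulsive), with SD 0.1
  person-to-person jitter — a test fixture for the downstream pipeline,
  not a claim about any population.

What passing tests on this cohort do **not** show about real data: the
generator has no lapses, no reaction times, no learning dynamics in Self
blocks, no correlation between baseline preference and susceptibility, and
its learner is far more accurate than human observers; pipeline effect
sizes on real data will be smaller and noisier.

## Hierarchical Bayesian estimation

Each candidate model is fitted per block and per group, with priors freshly
instantiated every time (no information crosses blocks or groups).
Individual parameters live on an unconstrained scale mapped by smooth
bijections — negated exponential for `k`/`km`, exponential for `ku`, scaled
logistic for `t`, `ξ`, `τ` — and are exchangeable draws from a group normal
`N(μ_φ, σ_φ²)` with `μ_φ ~ N(0, s_μ)`, `σ_φ ~ half-Cauchy(0, s_σ)`;
`s_μ = 3` and `s_σ = 2` by default (matching the recovery protocol) and
configurable per fit.

Sampling is a blocked Metropolis-within-Gibbs scheme, vectorised over
chains and subjects:

1. random-walk Metropolis on each subject's raw parameter, one family at a
   time, proposal scales adapted per subject during warmup (target
   acceptance 0.44, Robbins-Monro decay `t^−0.6`, frozen afterwards);
2. a joint all-family subject proposal whose covariance is estimated from
   the warmup history (scaled by `2.38²/P`), because single-site moves
   cannot follow likelihood ridges such as the `ku`–`τ` degeneracy;
3. an exact conjugate Gibbs draw for each group mean;
4. random-walk Metropolis on each log group SD (half-Cauchy prior with the
   log-parameterisation Jacobian);
5. interweaved non-centred moves that translate or rescale a whole family
   while holding the standardised subject effects fixed — the standard
   remedy for funnel geometry when individual likelihoods are weak.

Defaults are 4 chains × 500 warmup + 500 kept sweeps (tests and simulation
studies); longer runs (2 000/2 000, matching common practice for production
fits) are a config switch. Convergence is checked by split-R̂ over all
group- and individual-level parameters via arviz; the strict default
threshold is 1.01 for `check_convergence`, while simulation harnesses that
must triage many automated fits use the classic 1.1 cutoff. Point estimates
are posterior means on the constrained scale, which inherit the transforms'
guarantees (e.g. `km < 0` in every draw). The pointwise log-likelihood
matrix is stored for model comparison; an optional 0/1 observation weight
supports exact leave-one-out refits in tests.

## Model comparison and parameter recovery

LOO-IC is `−2 ×` the PSIS-estimated expected log pointwise predictive
density (arviz), with Pareto-k diagnostics attached and a warning when more
than 10% of observations exceed k = 0.7; the lowest score wins and deltas
are reported against the winner. The PSIS estimate is validated in the test
suite against brute-force exact leave-one-out refits on a tiny instance
(3 subjects × 10 trials, 30 refits).

The recovery protocol draws group-level truth from the fitting priors
(`μ ~ N(0, 3)`, `σ ~ half-Cauchy(0, 2)`), samples individual raw
parameters, maps them through the *same* transforms used in fitting (so
truth and estimate share a scale — otherwise the correlations are
ill-defined), simulates 50 choices per subject on the fixed generative
design, refits, and Spearman-correlates true against posterior-mean
individual parameters; correlation matrices are averaged across iterations
via Fisher's Z-transformation (applied to Spearman coefficients by
protocol fidelity, although arctanh is nominally a Pearson tool).
Iterations failing the R̂ ≤ 1.1 screen are excluded with a warning; if all
fail, all are kept and flagged.

**Identifiability.** This truth distribution is heavy-tailed: half-Cauchy
scales routinely exceed 2 and `μ ~ N(0, 3)` places whole cohorts outside
the design's sensitive region, producing saturated (all larger-later) or
coin-flip (huge `ku`) choice patterns in which individual ranks are
unrecoverable by *any* estimator. A Bayes-optimal oracle (posterior mean
under the true prior on a dense grid) reaches Fisher-Z-averaged Spearman
correlations of only ≈ 0.6–0.75 under this protocol, and ≈ 0.78 for `ku`
even on well-behaved cohorts — 50 binary choices carry limited rank
information about an individual's probit slope. The hierarchical fit
attains essentially those ceilings (e.g. `km` ≈ 0.98, `ku` ≈ 0.75 on
cohorts confined to the sensitive range), so recovery quality here is an
information property of the protocol, not a sampler limitation.

Model recovery at 20 subjects × 50 trials shows the generating KU model
beating KT decisively (ΔLOO-IC ≈ 25–75) and KU+ξ consistently (≈ 1–3),
while KU+τ is a statistical near-tie: its log-odds compression yields
heavier predictive tails than the probit it wraps, which occasionally wins
a cohort by a few LOO-IC units, and its `ku·τ` ridge is the one place the
sampler's R̂ stays elevated.

## Influence statistic

The closed-form KL divergence between two normal discounting beliefs is
divided by ln 10, because the defining integral uses a base-10 logarithm —
most libraries return nats, so this unit choice is easy to miss when
comparing numbers. The signed statistic for an Other block takes magnitude
`D_KL(later Self block ‖ earlier Self block)` (a `reverse` flag flips the
operand order, which is otherwise a convention) and sign from whether the
mean shift from the earlier block points toward or away from the
agent-attributed mean — the posterior-mean `km` from fitting the KU model
to the participant's own Other-block predictions. Mean shifts below 1e−9
get sign 0 and signed value 0 (the magnitude, possibly nonzero through a
pure `ku` change, is still reported) to avoid attaching an arbitrary sign
to numerical noise. Missing block fits yield missing values, not failures.

## Group statistics

Between-group contrasts use the independent Wilcoxon rank-sum, within
contrasts the signed-rank (paired or one-sample vs zero), all two-sided,
with normal-approximation Z (tie-corrected) and effect size `r = |Z|/√n`;
95% CIs for `r` come from a seeded 2 000-resample bootstrap (the CI method
is otherwise a free choice). Learning accuracy counts a prediction correct
when it picks the option with the higher hyperbolic value under the agent's
true rate, excludes exact-indifference trials with a logged count, and is
compared to chance by right-tailed exact binomial tests. Trait correlations
are Spearman with Fisher-Z confidence intervals and Benjamini-Hochberg
adjustment over the declared family; independent correlations are compared
with Fisher-Z tests. Synthetic trait scores, when requested, are Gaussian
factors with a configurable correlation to susceptibility — a fixture with
no psychometric content. Linear mixed-effects models, Bayes factors, and
factor analysis are deliberately out of scope: the tables are exported in a
layout those standard packages consume.

## Problem sizes

The test suite runs reduced problem sizes chosen as sensible simulation
budgets: recovery at 40 subjects × 5 iterations with 4 × 500/500 chains,
model recovery at 20 subjects × 10 replicates with 4 × 800/800 chains, the
end-to-end cohort at 24 + 24 participants with 4 × 800/800 chains.
`scripts/acceptance.py` runs the full 160-subject × 20-iteration recovery
with 4 × 1000/1000 chains; the paper-scale 2 000/2 000 setting is available
via `FitConfig`.

## Known limitations

- The sampler is gradient-free; it is well-suited to these low-dimensional
  per-subject likelihoods but mixes slowly on the KU+τ ridge and on
  cohorts whose likelihood is nearly flat (those fits are flagged by R̂).
- The KU+τ and KU+ξ noise layers are applied to whichever block is being
  fitted; the package does not model Self and Other trials jointly.
- Exact-zero mean shifts are signed 0 by tolerance; analyses that need a
  sign for pure uncertainty changes must use the reported magnitude.
- The generator's susceptibility construct is linear in the agent-to-self
  distance; real preference shifts need not be.
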