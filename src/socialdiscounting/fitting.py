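"""Hierarchical Bayesian estimation of the discounting choice models.

Four candidate models are fitted to one group's trials from one block:

* ``kt``     — point rate ``k`` (< 0) and softmax temperature ``t`` in [-1, 1];
* ``ku``     — preference-uncertainty model: mean ``km`` (< 0), SD ``ku`` (> 0);
* ``ku_xi``  — ``ku`` plus a symmetric lapse ``xi`` in [0, 1];
* ``ku_tau`` — ``ku`` plus a probability compressor ``tau`` in (0, 10].

Every individual-level parameter lives on an unconstrained ("raw")
scale and is mapped to its constrained value by a smooth bijection
(negated exponential for sign constraints, scaled logistic for interval
constraints). Raw parameters are exchangeable draws from a group-level
normal, phi_i ~ N(mu, sigma^2), with weakly informative hyperpriors
mu ~ N(0, s_mu) and sigma ~ half-Cauchy(0, s_sig). Groups and blocks
are always fitted separately, with priors freshly instantiated.

Sampling is by a blocked Metropolis-within-Gibbs scheme, fully
vectorised across chains and subjects: random-walk Metropolis on each
subject's raw parameter (one family at a time, proposal scales adapted
during warmup), an exact conjugate Gibbs draw for each group mean, and
random-walk Metropolis on each log group SD. Convergence is checked
with split-R-hat via arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit, ndtr

from .models import PROB_EPS

__all__ = [
    "MODELS",
    "FitConfig",
    "PosteriorFit",
    "ConvergenceReport",
    "block_data_from_frame",
    "fit_block",
    "check_convergence",
    "individual_point_estimates",
    "posterior_predictive",
    "constrain",
    "unconstrain",
]

_RAW_CLIP = 300.0  # keeps exp() finite for pathological group SDs


def _neg_exp(raw):
    return -np.exp(np.clip(raw, -_RAW_CLIP, _RAW_CLIP))


def _pos_exp(raw):
    return np.exp(np.clip(raw, -_RAW_CLIP, _RAW_CLIP))


def _bounded_expit(raw):
    # +-40 keeps the logistic strictly inside (0, 1) in double precision
    return expit(np.clip(raw, -40.0, 40.0))


_TRANSFORMS = {
    "k": (_neg_exp, lambda c: np.log(-c)),
    "km": (_neg_exp, lambda c: np.log(-c)),
    "ku": (_pos_exp, np.log),
    "t": (lambda r: -1.0 + 2.0 * _bounded_expit(r), lambda c: np.log((c + 1.0) / (1.0 - c))),
    "xi": (_bounded_expit, lambda c: np.log(c / (1.0 - c))),
    "tau": (lambda r: 10.0 * _bounded_expit(r), lambda c: np.log(c / (10.0 - c))),
}


def constrain(name: str, raw):
    """Map an unconstrained value to the constrained scale of parameter ``name``."""
    return _TRANSFORMS[name][0](np.asarray(raw, float))


def unconstrain(name: str, value):
    """Inverse of :func:`constrain`."""
    return _TRANSFORMS[name][1](np.asarray(value, float))


def _pointwise_kt(theta, data):
    v_ll = data["m_ll"] / (1.0 + np.power(10.0, theta["k"][..., None]) * data["d"])
    p = expit(np.power(10.0, theta["t"][..., None]) * (v_ll - data["m_ss"]))
    return _bernoulli(p, data["choice"])


def _ku_base_prob(theta, data):
    return ndtr((data["thresh"] - theta["km"][..., None]) / theta["ku"][..., None])


def _pointwise_ku(theta, data):
    return _bernoulli(_ku_base_prob(theta, data), data["choice"])


def _pointwise_ku_xi(theta, data):
    p = _ku_base_prob(theta, data)
    xi = theta["xi"][..., None]
    return _bernoulli(p * (1.0 - xi) + xi / 2.0, data["choice"])


def _pointwise_ku_tau(theta, data):
    p = np.clip(_ku_base_prob(theta, data), PROB_EPS, 1.0 - PROB_EPS)
    logit = np.log(p) - np.log1p(-p)
    return _bernoulli(expit(logit / theta["tau"][..., None]), data["choice"])


def _bernoulli(p, choice):
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return np.where(choice, np.log(p), np.log1p(-p))


#: model registry: parameter family names and pointwise log-likelihood
MODELS = {
    "kt": {"params": ("k", "t"), "pointwise": _pointwise_kt},
    "ku": {"params": ("km", "ku"), "pointwise": _pointwise_ku},
    "ku_xi": {"params": ("km", "ku", "xi"), "pointwise": _pointwise_ku_xi},
    "ku_tau": {"params": ("km", "ku", "tau"), "pointwise": _pointwise_ku_tau},
}


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings; the reduced defaults suit tests and simulation studies."""

    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int | None = None
    s_mu: float = 3.0  # prior SD of group means
    s_sig: float = 2.0  # half-Cauchy scale of group SDs
    store_loglik: bool = True
    target_accept: float = 0.44
    sigma_prop_scale: float = 0.4


@dataclass
class ConvergenceReport:
    passed: bool
    max_rhat: float
    rhat: pd.Series
    threshold: float


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics from one hierarchical fit."""

    model: str
    param_names: tuple
    raw_draws: dict  # name -> (chains, samples, subjects)
    mu_draws: np.ndarray  # (chains, samples, n_params)
    sigma_draws: np.ndarray  # (chains, samples, n_params)
    log_lik: np.ndarray | None  # (chains, samples, subjects * trials)
    participant_ids: list
    data: dict  # m_ss, m_ll, d, choice arrays of shape (subjects, trials)
    config: FitConfig
    block: str = ""
    group: str = ""

    @property
    def constrained_draws(self) -> dict:
        return {p: constrain(p, self.raw_draws[p]) for p in self.param_names}

    def to_inference_data(self) -> az.InferenceData:
        post = {}
        for j, p in enumerate(self.param_names):
            post[f"mu_{p}"] = (("chain", "draw"), self.mu_draws[:, :, j])
            post[f"sigma_{p}"] = (("chain", "draw"), self.sigma_draws[:, :, j])
            post[p] = (("chain", "draw", "subject"), constrain(p, self.raw_draws[p]))
        groups = {"posterior": xr.Dataset(post)}
        if self.log_lik is not None:
            groups["log_likelihood"] = xr.Dataset(
                {"choice": (("chain", "draw", "obs"), self.log_lik)}
            )
        return az.InferenceData(**groups)


def block_data_from_frame(df: pd.DataFrame):
    """Pivot a long trial table into rectangular (subject, trial) arrays.

    Expects columns ``participant_id, m_ss, m_ll, delay_days,
    choice_ll``; all participants must contribute the same number of
    trials.
    """
    if df.empty:
        raise ValueError("no trials supplied")
    ids = list(pd.unique(df["participant_id"]))
    counts = df.groupby("participant_id", sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("all participants must contribute the same number of trials")
    n, t = len(ids), int(counts.iloc[0])
    order = df.sort_values(["participant_id", "trial_index"], kind="stable") if "trial_index" in df else df
    order = order.set_index("participant_id").loc[ids].reset_index()
    shape = (n, t)
    data = {
        "m_ss": order["m_ss"].to_numpy(float).reshape(shape),
        "m_ll": order["m_ll"].to_numpy(float).reshape(shape),
        "d": order["delay_days"].to_numpy(float).reshape(shape),
        "choice": order["choice_ll"].to_numpy().astype(bool).reshape(shape),
    }
    return data, ids


def _prepare_data(data):
    data = dict(data)
    with np.errstate(divide="ignore"):
        data["thresh"] = np.log10((data["m_ll"] / data["m_ss"] - 1.0) / data["d"])
    return data


def _log_half_cauchy(sigma, scale):
    return np.where(sigma > 0, -np.log1p((sigma / scale) ** 2), -np.inf)


def fit_block(model: str, data, config: FitConfig = FitConfig(), *,
              participant_ids=None, block: str = "", group: str = "") -> PosteriorFit:
    """Fit one candidate model to one group's trials from one block.

    ``data`` is either a long-format DataFrame (see
    :func:`block_data_from_frame`) or a dict of rectangular arrays with
    keys ``m_ss, m_ll, d, choice`` of shape ``(subjects, trials)``. An
    optional 0/1 ``weight`` array of the same shape drops individual
    observations from the likelihood (used e.g. for exact leave-one-out
    refits); the stored pointwise log-likelihood matrix is unweighted.
    Returns a :class:`PosteriorFit` with draws on both scales and, by
    default, the pointwise log-likelihood matrix needed for
    leave-one-out model comparison.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}'; choose from {sorted(MODELS)}")
    if isinstance(data, pd.DataFrame):
        data, ids = block_data_from_frame(data)
        participant_ids = participant_ids or ids
    data = _prepare_data(data)
    n_sub, n_tr = data["choice"].shape
    if n_sub == 0 or n_tr == 0:
        raise ValueError("empty data")
    if participant_ids is None:
        participant_ids = list(range(n_sub))

    params = MODELS[model]["params"]
    pointwise = MODELS[model]["pointwise"]
    P, C = len(params), config.chains
    rng = np.random.default_rng(config.seed)

    # state, vectorised over chains
    raw = {p: rng.normal(0.0, 1.0, size=(C, n_sub)) for p in params}
    mu = np.zeros((C, P))
    sigma = np.ones((C, P))
    step = {p: np.full((C, n_sub), 0.5) for p in params}
    sig_step = np.full((C, P), config.sigma_prop_scale)
    nc_step_mu = np.full((C, P), config.sigma_prop_scale)
    nc_step_sig = np.full((C, P), config.sigma_prop_scale)
    joint_scale = 0.5
    if P > 1:
        cov_n = 0
        cov_mean = np.zeros((C, n_sub, P))
        cov_m2 = np.zeros((C, n_sub, P, P))
        chol = np.broadcast_to(0.3 * np.eye(P), (C, n_sub, P, P)).copy()

    weight = data.get("weight")

    def loglik(raw_state):
        theta = {p: constrain(p, raw_state[p]) for p in params}
        return pointwise(theta, data)  # (C, n_sub, n_tr)

    def subject_sum(ll_pointwise):
        if weight is None:
            return ll_pointwise.sum(axis=2)
        return (ll_pointwise * weight).sum(axis=2)

    ll_point = loglik(raw)
    ll_sub = subject_sum(ll_point)  # (C, n_sub)

    total = config.warmup + config.samples
    keep_raw = {p: np.empty((C, config.samples, n_sub)) for p in params}
    keep_mu = np.empty((C, config.samples, P))
    keep_sigma = np.empty((C, config.samples, P))
    keep_ll = (
        np.empty((C, config.samples, n_sub * n_tr)) if config.store_loglik else None
    )

    for it in range(total):
        adapting = it < config.warmup
        gamma = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0

        for j, p in enumerate(params):
            prop = raw[p] + step[p] * rng.standard_normal((C, n_sub))
            raw_prop = dict(raw)
            raw_prop[p] = prop
            ll_prop_point = loglik(raw_prop)
            ll_prop = subject_sum(ll_prop_point)
            mu_j = mu[:, j][:, None]
            sg_j = sigma[:, j][:, None]
            lp_cur = -0.5 * ((raw[p] - mu_j) / sg_j) ** 2
            lp_prop = -0.5 * ((prop - mu_j) / sg_j) ** 2
            log_alpha = (ll_prop - ll_sub) + (lp_prop - lp_cur)
            accept = np.log(rng.random((C, n_sub))) < log_alpha
            raw[p] = np.where(accept, prop, raw[p])
            ll_sub = np.where(accept, ll_prop, ll_sub)
            ll_point = np.where(accept[..., None], ll_prop_point, ll_point)
            if adapting:
                step[p] *= np.exp(gamma * (accept.astype(float) - config.target_accept))
                np.clip(step[p], 1e-3, 10.0, out=step[p])

        # joint subject-level proposal across all families with a
        # covariance adapted during warmup: single-site moves cannot
        # follow likelihood ridges between parameters (e.g. preference
        # uncertainty vs a temperature-like noise)
        if P > 1:
            x = np.stack([raw[p] for p in params], axis=-1)  # (C, n_sub, P)
            if adapting:
                cov_n += 1
                delta = x - cov_mean
                cov_mean += delta / cov_n
                cov_m2 += delta[..., :, None] * (x - cov_mean)[..., None, :]
                if cov_n >= 100 and it % 25 == 0:
                    cov = cov_m2 / (cov_n - 1) * (2.38**2 / P)
                    cov += 1e-6 * np.eye(P)
                    chol = np.linalg.cholesky(cov)
            eps = rng.standard_normal((C, n_sub, P, 1))
            x_prop = x + joint_scale * (chol @ eps)[..., 0]
            prop_all = {p: x_prop[..., j] for j, p in enumerate(params)}
            ll_prop_point = loglik(prop_all)
            ll_prop = subject_sum(ll_prop_point)
            lp = np.zeros((C, n_sub))
            for j, p in enumerate(params):
                mu_j = mu[:, j][:, None]
                sg_j = sigma[:, j][:, None]
                lp += -0.5 * ((prop_all[p] - mu_j) / sg_j) ** 2
                lp -= -0.5 * ((raw[p] - mu_j) / sg_j) ** 2
            accept = np.log(rng.random((C, n_sub))) < (ll_prop - ll_sub) + lp
            for p in params:
                raw[p] = np.where(accept, prop_all[p], raw[p])
            ll_sub = np.where(accept, ll_prop, ll_sub)
            ll_point = np.where(accept[..., None], ll_prop_point, ll_point)
            if adapting:
                joint_scale *= float(np.exp(gamma * (accept.mean() - 0.25)))
                joint_scale = float(np.clip(joint_scale, 0.05, 3.0))

        # group-level updates per parameter family
        for j, p in enumerate(params):
            r = raw[p]  # (C, n_sub)
            # conjugate Gibbs for the group mean
            prec = n_sub / sigma[:, j] ** 2 + 1.0 / config.s_mu**2
            mean = (r.sum(axis=1) / sigma[:, j] ** 2) / prec
            mu[:, j] = mean + rng.standard_normal(C) / np.sqrt(prec)
            # random-walk MH on log sigma (half-Cauchy prior + Jacobian)
            log_sig = np.log(sigma[:, j])
            prop_ls = log_sig + sig_step[:, j] * rng.standard_normal(C)
            dev = r - mu[:, j][:, None]

            def _sig_logpost(ls):
                s = np.exp(ls)
                ll = -n_sub * ls - 0.5 * (dev**2).sum(axis=1) / s**2
                return ll + _log_half_cauchy(s, config.s_sig) + ls

            log_alpha = _sig_logpost(prop_ls) - _sig_logpost(log_sig)
            acc = np.log(rng.random(C)) < log_alpha
            sigma[:, j] = np.exp(np.where(acc, prop_ls, log_sig))
            if adapting:
                sig_step[:, j] *= np.exp(gamma * (acc.astype(float) - 0.3))
                np.clip(sig_step[:, j], 1e-3, 5.0, out=sig_step[:, j])

        # interweaved non-centred updates: move (mu, sigma) holding the
        # standardised subject effects fixed, so weakly informed subjects
        # do not pin the group parameters (funnel remedy)
        for j, p in enumerate(params):
            mu_j = mu[:, j][:, None]
            sg_j = sigma[:, j][:, None]
            z = (raw[p] - mu_j) / sg_j
            # translate the whole family
            prop_mu = mu[:, j] + nc_step_mu[:, j] * rng.standard_normal(C)
            raw_prop = dict(raw)
            raw_prop[p] = prop_mu[:, None] + sg_j * z
            ll_prop_point = loglik(raw_prop)
            ll_prop = subject_sum(ll_prop_point)
            log_alpha = (ll_prop.sum(axis=1) - ll_sub.sum(axis=1)) - 0.5 * (
                prop_mu**2 - mu[:, j] ** 2
            ) / config.s_mu**2
            acc = np.log(rng.random(C)) < log_alpha
            mu[:, j] = np.where(acc, prop_mu, mu[:, j])
            raw[p] = np.where(acc[:, None], raw_prop[p], raw[p])
            ll_sub = np.where(acc[:, None], ll_prop, ll_sub)
            ll_point = np.where(acc[:, None, None], ll_prop_point, ll_point)
            if adapting:
                nc_step_mu[:, j] *= np.exp(gamma * (acc.astype(float) - 0.3))
                np.clip(nc_step_mu[:, j], 1e-3, 5.0, out=nc_step_mu[:, j])
            # rescale the whole family about the mean
            mu_j = mu[:, j][:, None]
            z = (raw[p] - mu_j) / sigma[:, j][:, None]
            log_sig = np.log(sigma[:, j])
            prop_ls = log_sig + nc_step_sig[:, j] * rng.standard_normal(C)
            raw_prop = dict(raw)
            raw_prop[p] = mu_j + np.exp(prop_ls)[:, None] * z
            ll_prop_point = loglik(raw_prop)
            ll_prop = subject_sum(ll_prop_point)
            prior_term = (
                _log_half_cauchy(np.exp(prop_ls), config.s_sig) + prop_ls
                - _log_half_cauchy(np.exp(log_sig), config.s_sig) - log_sig
            )
            log_alpha = (ll_prop.sum(axis=1) - ll_sub.sum(axis=1)) + prior_term
            acc = np.log(rng.random(C)) < log_alpha
            sigma[:, j] = np.exp(np.where(acc, prop_ls, log_sig))
            raw[p] = np.where(acc[:, None], raw_prop[p], raw[p])
            ll_sub = np.where(acc[:, None], ll_prop, ll_sub)
            ll_point = np.where(acc[:, None, None], ll_prop_point, ll_point)
            if adapting:
                nc_step_sig[:, j] *= np.exp(gamma * (acc.astype(float) - 0.3))
                np.clip(nc_step_sig[:, j], 1e-3, 5.0, out=nc_step_sig[:, j])

        if not adapting:
            s = it - config.warmup
            for p in params:
                keep_raw[p][:, s, :] = raw[p]
            keep_mu[:, s, :] = mu
            keep_sigma[:, s, :] = sigma
            if keep_ll is not None:
                keep_ll[:, s, :] = ll_point.reshape(C, -1)

    return PosteriorFit(
        model=model,
        param_names=params,
        raw_draws=keep_raw,
        mu_draws=keep_mu,
        sigma_draws=keep_sigma,
        log_lik=keep_ll,
        participant_ids=list(participant_ids),
        data=data,
        config=config,
        block=block,
        group=group,
    )


def check_convergence(fit: PosteriorFit, rhat_threshold: float = 1.01) -> ConvergenceReport:
    """Split-R-hat over all group- and individual-level parameters."""
    if fit.mu_draws.shape[0] < 2:
        raise ValueError("convergence diagnostics need at least two chains")
    idata = fit.to_inference_data()
    rhat = az.rhat(idata.posterior)
    rows = {}
    for name, da in rhat.items():
        if da.ndim == 0:
            rows[name] = float(da)
        else:
            for i, v in enumerate(np.asarray(da).ravel()):
                rows[f"{name}[{i}]"] = float(v)
    series = pd.Series(rows)
    max_rhat = float(series.max())
    passed = bool(max_rhat <= rhat_threshold)
    if not passed:
        warnings.warn(
            f"fit of '{fit.model}' has max R-hat {max_rhat:.3f} > {rhat_threshold}",
            stacklevel=2,
        )
    return ConvergenceReport(passed=passed, max_rhat=max_rhat, rhat=series,
                             threshold=rhat_threshold)


def individual_point_estimates(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior-mean individual parameters on the constrained scale."""
    cols = {"participant_id": fit.participant_ids}
    for p in fit.param_names:
        cols[p] = constrain(p, fit.raw_draws[p]).mean(axis=(0, 1))
    return pd.DataFrame(cols)


def posterior_predictive(fit: PosteriorFit, data=None, thin: int = 10,
                         seed: int | None = None) -> np.ndarray:
    """Simulate choices from thinned posterior draws.

    Returns the per-draw larger-later choice rate for each participant,
    shape ``(n_kept_draws, n_subjects)``, on the fitted trials by
    default or on alternative design arrays given as ``data``.
    """
    data = _prepare_data(data if data is not None else fit.data)
    rng = np.random.default_rng(seed)
    pointwise = MODELS[fit.model]["pointwise"]
    # re-use the likelihood machinery: probability of LL is exp(loglik of LL=1)
    fake = dict(data)
    fake["choice"] = np.ones_like(data["choice"], dtype=bool)
    rates = []
    for c in range(fit.mu_draws.shape[0]):
        for s in range(0, fit.mu_draws.shape[1], thin):
            theta = {p: constrain(p, fit.raw_draws[p][c, s]) for p in fit.param_names}
            p_ll = np.exp(pointwise(theta, fake))
            draws = rng.random(p_ll.shape) < p_ll
            rates.append(draws.mean(axis=1))
    return np.asarray(rates)
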