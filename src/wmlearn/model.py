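"""Nonlinear mixed-effects model of trial-by-trial span accuracy.

Each response click is a Bernoulli outcome whose probability follows an
exponential approach from a starting accuracy S toward an asymptote A over
trials:

    p(t) = A + (S - A) * 2^(-(t - 1) / tau),        tau = 2^rho + 2

S and A are inverse-logit transforms of linear predictors (so predicted
accuracies stay in (0, 1) for unbounded parameters), and the rate is a
50%-of-change time constant on a binary-log scale with an additive offset
of 2 that keeps tau > 2 trials and helps convergence.  The linear
predictors for start and asymptote carry a mean-centred set-size slope
(centred at 6.5, giving participant-level psychometric structure) and
fixed effects of feedback condition and task order; participants get
random intercepts on all three parameters (start, rate, asymptote).

Two fitting modes share one joint log posterior:

``map-fast``
    L-BFGS maximization of the penalized joint posterior with analytic
    gradients; population-effect standard errors from a Laplace
    approximation conditional on the modal random effects.
``full-bayes``
    Affine-invariant ensemble MCMC (emcee) initialized at the MAP mode;
    walkers are split into chains for split-R-hat and effective-sample-size
    diagnostics (arviz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .exceptions import ConfigError, DomainError, FitError, SaturationError
from .schedule import SET_SIZE_CENTER

logger = logging.getLogger(__name__)

#: linear predictors are clipped here before the inverse logit so the
#: likelihood never sees an exact 0 or 1 probability
LINPRED_CLIP = 35.0

_FEEDBACK_CODE = {"present": 0.5, "absent": -0.5}
_ORDER_CODE = {"wm_first": 0.5, "gf_first": -0.5}

TRIAL_COLUMNS = ["participant_id", "trial_index", "set_size", "click_correct"]


# ---------------------------------------------------------------------------
# elementary curve operations
# ---------------------------------------------------------------------------

def inv_logit(x):
    """Logistic function 1 / (1 + exp(-x)); stable for |x| up to ~700."""
    return expit(x)


def time_constant(rho):
    """Map the binary-log rate parameter to the 50%-of-change time constant
    tau = 2^rho + 2 (trials); the +2 offset bounds tau above 2."""
    return np.exp2(rho) + 2.0


@dataclass(frozen=True)
class LearningCurveParams:
    """Curve parameters for one participant, on link scales.

    ``sigma0``/``alpha0`` are start/asymptote linear-predictor intercepts
    (logit scale) at the centred set size; ``rho`` is the rate on the
    binary-log scale.  The ``*_slope`` fields are logit units per centred
    set-size unit; the ``*_offset`` fields carry already-summed condition
    terms (fixed effects times condition codes).
    """

    sigma0: float
    alpha0: float
    rho: float
    sigma_slope: float = 0.0
    alpha_slope: float = 0.0
    sigma_offset: float = 0.0
    alpha_offset: float = 0.0
    rho_offset: float = 0.0


def predict_accuracy(trial_index, set_size, params: LearningCurveParams):
    """Predicted per-click accuracy at a trial/set-size combination.

    Accepts scalars or arrays for ``trial_index`` and ``set_size``.  The
    curve starts exactly at S on trial 1 and has moved half of the way to
    the asymptote A at trial 1 + tau.
    """
    t = np.asarray(trial_index, dtype=float)
    if np.any(t < 1):
        raise DomainError("trial_index must be >= 1 (trials are 1-based)")
    cs = np.asarray(set_size, dtype=float) - SET_SIZE_CENTER
    s = inv_logit(params.sigma0 + params.sigma_slope * cs + params.sigma_offset)
    a = inv_logit(params.alpha0 + params.alpha_slope * cs + params.alpha_offset)
    tau = time_constant(params.rho + params.rho_offset)
    p = a + (s - a) * np.exp2(-(t - 1.0) / tau)
    if p.ndim == 0:
        return float(p)
    return p


def log_likelihood(data: pd.DataFrame,
                   params: Mapping[object, LearningCurveParams]) -> float:
    """Bernoulli log likelihood of click-level data under per-participant
    curve parameters: sum of y*log(p) + (1-y)*log(1-p) over clicks.

    Raises :class:`SaturationError` if any click's predicted probability is
    an exact 0 or 1 while the observed outcome disagrees (a silent -inf
    would otherwise hide the degeneracy).
    """
    if len(data) == 0:
        return 0.0
    total = 0.0
    for pid, rows in data.groupby("participant_id", sort=False):
        if pid not in params:
            raise KeyError(f"no parameters supplied for participant {pid!r}")
        p = predict_accuracy(rows["trial_index"].to_numpy(),
                             rows["set_size"].to_numpy(), params[pid])
        p = np.atleast_1d(np.asarray(p, dtype=float))
        y = rows["click_correct"].to_numpy(dtype=float)
        bad = ((p <= 0.0) & (y == 1.0)) | ((p >= 1.0) & (y == 0.0))
        if np.any(bad):
            raise SaturationError(
                f"participant {pid!r}: {int(bad.sum())} click(s) have saturated "
                "predicted probability discordant with the observed outcome"
            )
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
        total += float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    return total


# ---------------------------------------------------------------------------
# fit configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative default priors on the population level.

    Normal(0, sd) on means, slopes and condition effects; half-normal on
    the three random-effect SDs.  All on link scales.
    """

    mean_sd: float = 5.0
    slope_sd: float = 2.0
    condition_sd: float = 2.0
    re_sd_scale: float = 1.0

    def validate(self) -> None:
        for name in ("mean_sd", "slope_sd", "condition_sd", "re_sd_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"prior {name} must be positive")


@dataclass(frozen=True)
class FitConfig:
    """Sampler/optimizer settings.

    The full-Bayes defaults follow the reference budget of 4 chains with
    5000 iterations each, the first 3000 discarded as warm-up.  ``map-fast``
    ignores the chain settings.
    """

    mode: str = "map-fast"
    chains: int = 4
    iterations: int = 5000
    warmup: int = 3000
    seed: int = 0
    include_catch: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)
    max_opt_iter: int = 2000
    n_walkers: int | None = None   # full-bayes only; default 2*ndim + 2

    def validate(self) -> None:
        if self.mode not in ("map-fast", "full-bayes"):
            raise ConfigError(f"unknown fit mode {self.mode!r}")
        if self.chains < 1:
            raise ConfigError("chains must be >= 1")
        if self.iterations <= self.warmup:
            raise ConfigError("iterations must exceed warmup")
        self.priors.validate()


_POP_NAMES = [
    "mu_start", "mu_asym", "mu_rate",
    "slope_start", "slope_asym",
    "feedback_start", "feedback_asym", "feedback_rate",
    "order_start", "order_asym", "order_rate",
    "log_sd_start", "log_sd_asym", "log_sd_rate",
]
_N_POP = len(_POP_NAMES)


@dataclass
class ModelFit:
    """Fitted hierarchical model.

    ``population`` has one row per population effect (estimate, sd, 95% CI);
    ``participants`` has one row per participant with posterior summaries of
    the three participant-level parameters (columns ``start``, ``asym``,
    ``rate`` and ``*_sd``); ``diagnostics`` holds split-R-hat / ESS for
    full-bayes fits.
    """

    population: pd.DataFrame
    participants: pd.DataFrame
    diagnostics: dict
    config: FitConfig
    converged: bool
    log_posterior: float
    n_clicks: int

    def summary(self) -> str:
        lines = [
            f"mode={self.config.mode}  seed={self.config.seed}  "
            f"clicks={self.n_clicks}  participants={len(self.participants)}",
            f"log posterior = {self.log_posterior:.2f}  converged={self.converged}",
            "", "Population effects:", self.population.to_string(),
        ]
        if self.diagnostics:
            lines += ["", "Diagnostics: " + ", ".join(
                f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                for k, v in self.diagnostics.items())]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internal design representation
# ---------------------------------------------------------------------------

class _Design:
    """Click-level arrays plus participant indexing for fast likelihoods."""

    def __init__(self, data: pd.DataFrame, include_catch: bool):
        if not include_catch:
            data = data[data["set_size"] != 3]
        if len(data) == 0:
            raise ConfigError("no observations to fit")
        pids = pd.unique(data["participant_id"])
        self.pids = list(pids)
        self.n = len(self.pids)
        if self.n < 2:
            raise ConfigError(
                "hierarchical fitting needs >= 2 participants (got "
                f"{self.n}); shrinkage is undefined for a single participant"
            )
        codes = pd.Categorical(data["participant_id"],
                               categories=pids).codes.astype(np.intp)
        self.i = codes
        self.cs = data["set_size"].to_numpy(dtype=float) - SET_SIZE_CENTER
        self.tm1 = data["trial_index"].to_numpy(dtype=float) - 1.0
        if np.any(self.tm1 < 0):
            raise DomainError("trial_index must be >= 1")
        self.y = data["click_correct"].to_numpy(dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ConfigError("click_correct must be 0 or 1")
        if "feedback" in data.columns:
            self.fb = data["feedback"].map(_FEEDBACK_CODE).to_numpy(dtype=float)
            if np.isnan(self.fb).any():
                raise ConfigError("feedback must be 'present' or 'absent'")
        else:
            self.fb = np.zeros(len(data))
        if "order" in data.columns:
            self.od = data["order"].map(_ORDER_CODE).to_numpy(dtype=float)
            if np.isnan(self.od).any():
                raise ConfigError("order must be 'wm_first' or 'gf_first'")
        else:
            self.od = np.zeros(len(data))
        self.n_clicks = len(data)


def _unpack(theta: np.ndarray, n: int):
    """Split the raw vector into population effects and participant
    deviations on the natural (centred) scale.

    The random-effect block is stored non-centred (standardized deviations
    z with u = sd * z): the joint posterior density is unbounded at sd = 0
    in the centred parameterization, so its mode only exists in the
    non-centred one.
    """
    pop = theta[:_N_POP]
    z = theta[_N_POP:].reshape(3, n)
    sds = np.exp(pop[11:14])
    return pop, sds[0] * z[0], sds[1] * z[1], sds[2] * z[2]


def _log_posterior_and_grad(theta: np.ndarray, d: _Design, pri: PriorConfig,
                            want_grad: bool = True):
    """Joint log posterior (likelihood + random-effect and population priors)
    and, optionally, its analytic gradient.

    Parameterization: population effects, log random-effect SDs, and
    standardized participant deviations z (non-centred; u = sd * z).
    """
    pop = theta[:_N_POP]
    z = theta[_N_POP:].reshape(3, d.n)
    z_s, z_a, z_r = z[0], z[1], z[2]
    (mu_s, mu_a, mu_r, sl_s, sl_a,
     bf_s, bf_a, bf_r, bo_s, bo_a, bo_r, ls_s, ls_a, ls_r) = pop
    sd_s, sd_a, sd_r = math.exp(ls_s), math.exp(ls_a), math.exp(ls_r)
    u_s, u_a, u_r = sd_s * z_s, sd_a * z_a, sd_r * z_r

    eta_s = mu_s + sl_s * d.cs + bf_s * d.fb + bo_s * d.od + u_s[d.i]
    eta_a = mu_a + sl_a * d.cs + bf_a * d.fb + bo_a * d.od + u_a[d.i]
    eta_r = mu_r + bf_r * d.fb + bo_r * d.od + u_r[d.i]

    clipped = (np.abs(eta_s) > LINPRED_CLIP) | (np.abs(eta_a) > LINPRED_CLIP)
    if clipped.any():
        logger.debug("clipping %d linear predictors at +/-%g",
                     int(clipped.sum()), LINPRED_CLIP)
    eta_s = np.clip(eta_s, -LINPRED_CLIP, LINPRED_CLIP)
    eta_a = np.clip(eta_a, -LINPRED_CLIP, LINPRED_CLIP)
    eta_r = np.clip(eta_r, -LINPRED_CLIP, LINPRED_CLIP)

    s = expit(eta_s)
    a = expit(eta_a)
    tau = np.exp2(eta_r) + 2.0
    g = np.exp2(-d.tm1 / tau)
    p = a + (s - a) * g
    p = np.clip(p, 1e-12, 1.0 - 1e-12)

    ll = float(np.sum(d.y * np.log(p) + (1.0 - d.y) * np.log1p(-p)))

    lp = ll
    # standardized deviations ~ Normal(0, 1)
    lp += -0.5 * ((z_s @ z_s) + (z_a @ z_a) + (z_r @ z_r))
    # half-normal on SDs (plus log-Jacobian of the log parameterization)
    lp += -(sd_s**2 + sd_a**2 + sd_r**2) / (2 * pri.re_sd_scale**2)
    lp += ls_s + ls_a + ls_r
    # weak normals on population effects
    lp += -0.5 * (mu_s**2 + mu_a**2 + mu_r**2) / pri.mean_sd**2
    lp += -0.5 * (sl_s**2 + sl_a**2) / pri.slope_sd**2
    lp += -0.5 * (bf_s**2 + bf_a**2 + bf_r**2
                  + bo_s**2 + bo_a**2 + bo_r**2) / pri.condition_sd**2

    if not want_grad:
        return lp

    dldp = d.y / p - (1.0 - d.y) / (1.0 - p)
    gs = dldp * g * s * (1.0 - s)
    ga = dldp * (1.0 - g) * a * (1.0 - a)
    # d p / d eta_r  =  (s - a) * g * ln2 * tm1 / tau^2  *  ln2 * 2^eta_r
    gr = dldp * (s - a) * g * (math.log(2.0) ** 2) * d.tm1 / tau**2 * np.exp2(eta_r)

    grad = np.zeros_like(theta)
    grad[0] = gs.sum() - mu_s / pri.mean_sd**2
    grad[1] = ga.sum() - mu_a / pri.mean_sd**2
    grad[2] = gr.sum() - mu_r / pri.mean_sd**2
    grad[3] = gs @ d.cs - sl_s / pri.slope_sd**2
    grad[4] = ga @ d.cs - sl_a / pri.slope_sd**2
    grad[5] = gs @ d.fb - bf_s / pri.condition_sd**2
    grad[6] = ga @ d.fb - bf_a / pri.condition_sd**2
    grad[7] = gr @ d.fb - bf_r / pri.condition_sd**2
    grad[8] = gs @ d.od - bo_s / pri.condition_sd**2
    grad[9] = ga @ d.od - bo_a / pri.condition_sd**2
    grad[10] = gr @ d.od - bo_r / pri.condition_sd**2
    n = d.n
    acc_s = np.bincount(d.i, gs, n)   # d ll / d u for each participant
    acc_a = np.bincount(d.i, ga, n)
    acc_r = np.bincount(d.i, gr, n)
    # du/dls = sd * z = u, so the ls gradient routes through the deviations
    grad[11] = acc_s @ u_s - sd_s**2 / pri.re_sd_scale**2 + 1.0
    grad[12] = acc_a @ u_a - sd_a**2 / pri.re_sd_scale**2 + 1.0
    grad[13] = acc_r @ u_r - sd_r**2 / pri.re_sd_scale**2 + 1.0
    grad[_N_POP:_N_POP + n] = sd_s * acc_s - z_s
    grad[_N_POP + n:_N_POP + 2 * n] = sd_a * acc_a - z_a
    grad[_N_POP + 2 * n:] = sd_r * acc_r - z_r
    return lp, grad


def _initial_theta(d: _Design) -> np.ndarray:
    acc = float(np.mean(d.y))
    acc = min(max(acc, 0.02), 0.98)
    base = math.log(acc / (1.0 - acc))
    theta = np.zeros(_N_POP + 3 * d.n)
    theta[0] = base - 0.3          # start a little below the overall level
    theta[1] = base + 0.3
    theta[2] = 2.5                 # tau ~ 7.7 trials
    theta[3] = theta[4] = -0.2
    theta[11] = theta[12] = theta[13] = math.log(0.5)
    return theta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(data: pd.DataFrame, config: FitConfig) -> ModelFit:
    """Fit the hierarchical trajectory model to click-level data.

    ``data`` needs columns ``participant_id``, ``trial_index``, ``set_size``,
    ``click_correct`` and optionally ``feedback``/``order`` condition labels.
    """
    config.validate()
    d = _Design(data, config.include_catch)
    if config.mode == "map-fast":
        return _fit_map(d, config)
    return _fit_bayes(d, config)


def _fisher_blocks(theta: np.ndarray, d: _Design) -> np.ndarray:
    """Per-participant 3x3 expected (Fisher) information of the log
    likelihood with respect to the (start, asym, rate) deviations."""
    pop, u_s, u_a, u_r = _unpack(theta, d.n)
    (mu_s, mu_a, mu_r, sl_s, sl_a,
     bf_s, bf_a, bf_r, bo_s, bo_a, bo_r, *_rest) = pop
    eta_s = np.clip(mu_s + sl_s * d.cs + bf_s * d.fb + bo_s * d.od + u_s[d.i],
                    -LINPRED_CLIP, LINPRED_CLIP)
    eta_a = np.clip(mu_a + sl_a * d.cs + bf_a * d.fb + bo_a * d.od + u_a[d.i],
                    -LINPRED_CLIP, LINPRED_CLIP)
    eta_r = np.clip(mu_r + bf_r * d.fb + bo_r * d.od + u_r[d.i],
                    -LINPRED_CLIP, LINPRED_CLIP)
    s = expit(eta_s)
    a = expit(eta_a)
    tau = np.exp2(eta_r) + 2.0
    g = np.exp2(-d.tm1 / tau)
    p = np.clip(a + (s - a) * g, 1e-12, 1 - 1e-12)
    w = 1.0 / (p * (1.0 - p))
    j1 = g * s * (1.0 - s)
    j2 = (1.0 - g) * a * (1.0 - a)
    j3 = (s - a) * g * (math.log(2.0) ** 2) * d.tm1 / tau**2 * np.exp2(eta_r)
    blocks = np.empty((d.n, 3, 3))
    pairs = {(0, 0): j1 * j1, (0, 1): j1 * j2, (0, 2): j1 * j3,
             (1, 1): j2 * j2, (1, 2): j2 * j3, (2, 2): j3 * j3}
    for (r, c), v in pairs.items():
        acc = np.bincount(d.i, v * w, d.n)
        blocks[:, r, c] = acc
        blocks[:, c, r] = acc
    return blocks


def _run_map(d: _Design, config: FitConfig):
    """Laplace-EM estimation of the penalized model.

    A joint mode over deviations *and* their SDs is degenerate, so the SDs
    are estimated by EM: the inner step maximizes the penalized posterior
    with the SDs held fixed (L-BFGS, analytic gradients); the outer step
    updates each SD from the fitted deviations plus their Laplace posterior
    variances, solved jointly with the half-normal hyperprior.
    """
    theta = _initial_theta(d)
    ndim = len(theta)
    scale2 = config.priors.re_sd_scale ** 2
    res = None
    for em_iter in range(40):
        ls = theta[11:14].copy()
        bounds = [(None, None)] * ndim
        for k in range(3):
            bounds[11 + k] = (ls[k], ls[k])

        def objective(th):
            lp, grad = _log_posterior_and_grad(th, d, config.priors)
            return -lp, -grad

        res = optimize.minimize(objective, theta, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": config.max_opt_iter,
                                         "maxfun": 4 * config.max_opt_iter})
        if not np.isfinite(res.fun):
            raise FitError(f"inner MAP optimization diverged: {res.message}")
        theta = res.x

        # EM update of the SDs: E[u^2] ~ uhat^2 + Laplace posterior variance
        _, u_s, u_a, u_r = _unpack(theta, d.n)
        sds = np.exp(theta[11:14])
        info = _fisher_blocks(theta, d)
        info[:, 0, 0] += 1.0 / sds[0] ** 2
        info[:, 1, 1] += 1.0 / sds[1] ** 2
        info[:, 2, 2] += 1.0 / sds[2] ** 2
        cov = np.linalg.inv(info)
        ssq = np.array([
            float(u_s @ u_s + cov[:, 0, 0].sum()),
            float(u_a @ u_a + cov[:, 1, 1].sum()),
            float(u_r @ u_r + cov[:, 2, 2].sum()),
        ])
        # maximize -n*log(sd) - ssq/(2 sd^2) - sd^2/(2 scale^2) in sd^2
        n = d.n
        new_var = (-n + np.sqrt(n * n + 4.0 * ssq / scale2)) * scale2 / 2.0
        new_ls = 0.5 * np.log(np.maximum(new_var, 1e-12))
        # deviations are standardized: rescale z so u is unchanged
        ratio = np.exp(theta[11:14] - new_ls)
        theta[_N_POP:_N_POP + n] *= ratio[0]
        theta[_N_POP + n:_N_POP + 2 * n] *= ratio[1]
        theta[_N_POP + 2 * n:] *= ratio[2]
        delta = float(np.max(np.abs(new_ls - theta[11:14])))
        theta[11:14] = new_ls
        if delta < 1e-3:
            break
    logger.debug("Laplace-EM finished after %d iterations (last SD change "
                 "%.2g)", em_iter + 1, delta)
    res.x = theta
    return res


def _pop_table(est: np.ndarray, sd: np.ndarray | None) -> pd.DataFrame:
    tab = pd.DataFrame({"estimate": est}, index=_POP_NAMES)
    if sd is None:
        sd = np.full(len(est), np.nan)
    tab["sd"] = sd
    tab["ci_low"] = tab["estimate"] - 1.96 * tab["sd"]
    tab["ci_high"] = tab["estimate"] + 1.96 * tab["sd"]
    return tab


def _fit_map(d: _Design, config: FitConfig) -> ModelFit:
    res = _run_map(d, config)
    theta = res.x
    pop, u_s, u_a, u_r = _unpack(theta, d.n)

    # Laplace SEs for the population block, conditional on modal random
    # effects (finite differences of the analytic gradient)
    eps = 1e-5
    hess = np.empty((_N_POP, _N_POP))
    for j in range(_N_POP):
        tp = theta.copy()
        tp[j] += eps
        _, gp = _log_posterior_and_grad(tp, d, config.priors)
        tm = theta.copy()
        tm[j] -= eps
        _, gm = _log_posterior_and_grad(tm, d, config.priors)
        hess[j] = -(gp[:_N_POP] - gm[:_N_POP]) / (2 * eps)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:   # pragma: no cover - degenerate designs
        sds = np.full(_N_POP, np.nan)

    participants = pd.DataFrame({
        "participant_id": d.pids,
        "start": pop[0] + u_s,
        "asym": pop[1] + u_a,
        "rate": pop[2] + u_r,
        "start_sd": np.nan, "asym_sd": np.nan, "rate_sd": np.nan,
    }).set_index("participant_id")

    converged = bool(res.success) or res.status == 1  # 1 = hit maxiter
    if not res.success:
        logger.warning("MAP optimizer stopped early: %s", res.message)
    return ModelFit(
        population=_pop_table(pop, sds),
        participants=participants,
        diagnostics={},
        config=config,
        converged=converged,
        log_posterior=float(-res.fun),
        n_clicks=d.n_clicks,
    )


def _fit_bayes(d: _Design, config: FitConfig) -> ModelFit:
    import arviz as az
    import emcee

    ndim = _N_POP + 3 * d.n
    nwalkers = config.n_walkers or (2 * ndim + 2)
    if nwalkers < 2 * ndim:
        raise ConfigError(f"full-bayes needs >= {2 * ndim} walkers for {ndim} "
                          "parameters")
    if nwalkers % config.chains:
        nwalkers += config.chains - nwalkers % config.chains

    map_res = _run_map(d, replace(config, max_opt_iter=min(config.max_opt_iter, 600)))
    rng = np.random.default_rng(config.seed)
    scale = np.full(ndim, 0.02)
    scale[_N_POP:] = 0.05
    p0 = map_res.x + scale * rng.standard_normal((nwalkers, ndim))

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim,
        lambda th: _log_posterior_and_grad(th, d, config.priors, want_grad=False),
    )
    state = sampler.run_mcmc(p0, config.iterations, progress=False,
                             skip_initial_state_check=True)
    if state is None:  # pragma: no cover
        raise FitError("ensemble sampler returned no final state")

    chain = sampler.get_chain(discard=config.warmup)     # (draws, walkers, dim)
    draws, walkers, _ = chain.shape
    per = walkers // config.chains
    # walkers grouped into pseudo-chains for split-R-hat
    grouped = chain[:, :per * config.chains, :].reshape(draws, config.chains,
                                                        per, ndim)
    posterior = grouped.transpose(1, 0, 2, 3).reshape(config.chains,
                                                      draws * per, ndim)
    idata = az.from_dict(posterior={"theta": posterior})
    rhat = az.rhat(idata)["theta"].to_numpy()
    ess = az.ess(idata)["theta"].to_numpy()

    flat = posterior.reshape(-1, ndim)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)

    pop_tab = _pop_table(mean[:_N_POP], sd[:_N_POP])
    pop_tab["ci_low"] = lo[:_N_POP]
    pop_tab["ci_high"] = hi[:_N_POP]

    n = d.n
    # deviations are stored standardized; scale by each draw's SD
    start_draws = flat[:, 0:1] + np.exp(flat[:, 11:12]) * flat[:, _N_POP:_N_POP + n]
    asym_draws = flat[:, 1:2] + np.exp(flat[:, 12:13]) * flat[:, _N_POP + n:_N_POP + 2 * n]
    rate_draws = flat[:, 2:3] + np.exp(flat[:, 13:14]) * flat[:, _N_POP + 2 * n:]
    participants = pd.DataFrame({
        "participant_id": d.pids,
        "start": start_draws.mean(axis=0),
        "asym": asym_draws.mean(axis=0),
        "rate": rate_draws.mean(axis=0),
        "start_sd": start_draws.std(axis=0, ddof=1),
        "asym_sd": asym_draws.std(axis=0, ddof=1),
        "rate_sd": rate_draws.std(axis=0, ddof=1),
    }).set_index("participant_id")

    max_rhat = float(np.nanmax(rhat))
    min_ess = float(np.nanmin(ess))
    converged = max_rhat <= 1.05
    if not converged:
        logger.warning("full-bayes fit not converged: max split-R-hat %.3f "
                       "(threshold 1.05)", max_rhat)
    lp_mean = float(np.mean(sampler.get_log_prob(discard=config.warmup)))
    return ModelFit(
        population=pop_tab,
        participants=participants,
        diagnostics={"max_rhat": max_rhat, "min_ess": min_ess,
                     "n_walkers": nwalkers, "acceptance_fraction":
                     float(np.mean(sampler.acceptance_fraction))},
        config=config,
        converged=converged,
        log_posterior=lp_mean,
        n_clicks=d.n_clicks,
    )


# ---------------------------------------------------------------------------
# point-estimate extraction
# ---------------------------------------------------------------------------

def extract_estimates(fit: ModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """Per-participant point estimates on interpretable scales.

    ``initial_accuracy``/``final_accuracy`` are the inverse-logit of the
    participant's start/asymptote predictor at the centred set size;
    ``rate_estimate`` is the participant's rate on the binary-log scale
    (monotone in the time constant: larger = slower change);
    ``overall_accuracy`` is the participant's raw click-level mean, the
    field's conventional aggregate measure.
    """
    observed = pd.Index(pd.unique(data["participant_id"]))
    missing = observed.difference(fit.participants.index)
    if len(missing):
        raise ConfigError(
            f"participants missing from the fit: {list(missing)[:5]}"
        )
    overall = data.groupby("participant_id", sort=False)["click_correct"].mean()
    out = pd.DataFrame({
        "initial_accuracy": inv_logit(fit.participants["start"]),
        "rate_estimate": fit.participants["rate"],
        "final_accuracy": inv_logit(fit.participants["asym"]),
    })
    out["overall_accuracy"] = overall.reindex(out.index)
    return out.loc[observed]
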