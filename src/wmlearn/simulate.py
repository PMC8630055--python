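"""Synthetic cohorts with the generative structure the analysis assumes.

Participants get latent learning-curve parameters (start and asymptote
logits, binary-log rate) drawn from independent normals; every scheduled
trial yields ``set_size`` conditionally independent Bernoulli clicks at the
curve's predicted accuracy; and a fluid-intelligence (Gf) score is built on
the latent scales with loadings on the asymptote and the rate only — the
start parameter has no direct path to Gf, mirroring the dissociation the
analysis is designed to detect.

The default Gf loadings are solved in closed form so that, with unit
residual noise and independent latents, the population correlations are
r(asymptote, Gf) = +0.33 and r(rate, Gf) = -0.30:

    beta_asym = 0.33 * D,  beta_rate = -0.30 * D,
    D = 1 / sqrt(1 - (0.33^2 + 0.30^2))
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .model import LearningCurveParams, predict_accuracy
from .schedule import TrialSchedule, build_schedule

_D = 1.0 / np.sqrt(1.0 - (0.33**2 + 0.30**2))
DEFAULT_BETA_ASYM = float(0.33 * _D)     # ~ 0.36870
DEFAULT_BETA_RATE = float(-0.30 * _D)    # ~ -0.33518


@dataclass(frozen=True)
class PopulationConfig:
    """Generative population for a synthetic cohort.

    Means/SDs are on link scales: logits for start and asymptote, the
    binary-log rate scale for ``rate`` (mean 2.5 puts the median time
    constant near 2^2.5 + 2 ~ 7.7 trials: half the start-to-asymptote
    change is done after ~8 trials and the curve is near its asymptote
    over the back half of the 68-trial session).  Set-size slopes are
    logit units per set-size unit and negative (longer sequences are
    harder).  Condition effects default to zero but keep the fixed-effect
    machinery exercised when set.
    """

    n_participants: int = 87
    mean_start: float = -0.9
    sd_start: float = 0.7
    mean_asym: float = 1.6
    sd_asym: float = 0.9
    mean_rate: float = 2.5
    sd_rate: float = 1.2
    start_slope: float = -0.30
    asym_slope: float = -0.35
    feedback_effect_start: float = 0.0
    feedback_effect_asym: float = 0.0
    feedback_effect_rate: float = 0.0
    order_effect_start: float = 0.0
    order_effect_asym: float = 0.0
    order_effect_rate: float = 0.0
    beta_asym: float = DEFAULT_BETA_ASYM
    beta_rate: float = DEFAULT_BETA_RATE
    gf_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for name in ("sd_start", "sd_asym", "sd_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.gf_noise_sd < 0:
            raise ConfigError("gf_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """One simulated study: latent truth, Gf scores and click-level trials."""

    config: PopulationConfig
    true_params: pd.DataFrame   # participant_id, sigma0, rho, alpha0, feedback, order
    gf_scores: pd.DataFrame     # participant_id, gf
    trials: pd.DataFrame        # one row per click
    schedule: TrialSchedule = field(repr=False, default=None)


_FEEDBACK_CODE = {"present": 0.5, "absent": -0.5}
_ORDER_CODE = {"wm_first": 0.5, "gf_first": -0.5}


def sample_population_params(config: PopulationConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-participant latent parameters and assign condition labels.

    Independent normal draws on the link scales; feedback alternates
    participant by participant and task order alternates in pairs, so the
    two factors are (near-)balanced and crossed.
    """
    config.validate()
    n = config.n_participants
    ids = [f"P{i + 1:03d}" for i in range(n)]
    idx = np.arange(n)
    return pd.DataFrame({
        "participant_id": ids,
        "sigma0": rng.normal(config.mean_start, config.sd_start, n),
        "rho": rng.normal(config.mean_rate, config.sd_rate, n),
        "alpha0": rng.normal(config.mean_asym, config.sd_asym, n),
        "feedback": np.where(idx % 2 == 0, "present", "absent"),
        "order": np.where((idx // 2) % 2 == 0, "wm_first", "gf_first"),
    })


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def generate_gf(params: pd.DataFrame, config: PopulationConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Gf as a standardized composite loaded on the asymptote and rate
    latents (z-scored within cohort) plus normal noise; no start term."""
    if len(params) == 0:
        raise ConfigError("parameter table is empty")
    raw = (config.beta_asym * _zscore(params["alpha0"].to_numpy())
           + config.beta_rate * _zscore(params["rho"].to_numpy())
           + rng.normal(0.0, config.gf_noise_sd, len(params)))
    if raw.std(ddof=1) > 0:
        raw = _zscore(raw)
    return pd.DataFrame({"participant_id": params["participant_id"],
                         "gf": raw})


def simulate_dataset(config: PopulationConfig,
                     rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Simulate a full cohort over the fixed 68-trial schedule.

    Reproducible: with ``rng=None`` a fresh generator is seeded from
    ``config.seed``, so two calls with the same config are identical.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    schedule = build_schedule()
    sched = schedule.to_frame()
    params = sample_population_params(config, rng)
    gf = generate_gf(params, config, rng)

    trial_idx = sched["trial_index"].to_numpy()
    set_size = sched["set_size"].to_numpy()
    is_catch = sched["is_catch"].to_numpy()
    clicks_per_trial = set_size
    total_clicks = int(clicks_per_trial.sum())

    frames = []
    for row in params.itertuples(index=False):
        fb = _FEEDBACK_CODE[row.feedback]
        od = _ORDER_CODE[row.order]
        p = predict_accuracy(
            trial_idx, set_size,
            LearningCurveParams(
                sigma0=row.sigma0, alpha0=row.alpha0, rho=row.rho,
                sigma_slope=config.start_slope,
                alpha_slope=config.asym_slope,
                sigma_offset=(config.feedback_effect_start * fb
                              + config.order_effect_start * od),
                alpha_offset=(config.feedback_effect_asym * fb
                              + config.order_effect_asym * od),
                rho_offset=(config.feedback_effect_rate * fb
                            + config.order_effect_rate * od),
            ))
        p_click = np.repeat(p, clicks_per_trial)
        correct = (rng.random(total_clicks) < p_click).astype(np.int64)
        frames.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "trial_index": np.repeat(trial_idx, clicks_per_trial),
            "set_size": np.repeat(set_size, clicks_per_trial),
            "is_catch": np.repeat(is_catch, clicks_per_trial),
            "click_index": np.concatenate([np.arange(1, s + 1) for s in set_size]),
            "click_correct": correct,
            "feedback": row.feedback,
            "order": row.order,
        }))
    trials = pd.concat(frames, ignore_index=True)
    return SyntheticCohort(config=config, true_params=params, gf_scores=gf,
                           trials=trials, schedule=schedule)


def catch_accuracy(trials: pd.DataFrame) -> pd.Series:
    """Per-participant mean click accuracy on catch trials (set size 3)."""
    catch = trials[trials["set_size"] == 3]
    return catch.groupby("participant_id", sort=False)["click_correct"].mean()
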