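"""Chance-performance screening.

Matrix-reasoning scores are screened with an exact one-tailed binomial test
against a 12.5% guessing rate: a participant whose score is not
significantly above chance is excluded.  Spatial-span catch trials (set
size 3) are screened against a 50% accuracy criterion; accuracy exactly at
the criterion is retained (the lenient boundary, since the criterion
excluded nobody in practice and the boundary is therefore unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .exceptions import ConfigError

GUESS_RATE = 0.125
CATCH_CRITERION = 0.5


@dataclass(frozen=True)
class ExclusionDecision:
    participant_id: object
    rule: str              # 'matrix-chance:<task>' or 'catch-chance'
    score: float           # observed count (matrix) or accuracy (catch)
    threshold: float       # maximal chance-consistent count, or the criterion
    excluded: bool


@dataclass(frozen=True)
class ScreenConfig:
    """Item counts per matrix task plus test settings."""

    n_items: dict[str, int]
    guess_rate: float = GUESS_RATE
    alpha: float = 0.05
    catch_criterion: float = CATCH_CRITERION

    def validate(self) -> None:
        if not (0 < self.guess_rate < 1):
            raise ConfigError("guess_rate must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        for task, n in self.n_items.items():
            if n < 1:
                raise ConfigError(f"n_items for {task!r} must be >= 1")


def binomial_chance_threshold(n_items: int, guess_rate: float = GUESS_RATE,
                              alpha: float = 0.05) -> int:
    """Largest score k still consistent with guessing.

    k is the largest integer with upper-tail probability
    P(X >= k | n, guess_rate) >= alpha under the exact binomial null;
    scores <= k are "not significantly above chance" and fail the screen.
    """
    if n_items < 1:
        raise ConfigError("n_items must be >= 1")
    if not (0 < guess_rate < 1):
        raise ConfigError("guess_rate must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    # P(X >= k) = sf(k - 1); scan downward from n_items
    for k in range(n_items, 0, -1):
        if stats.binom.sf(k - 1, n_items, guess_rate) >= alpha:
            return k
    return 0


def screen_cohort(matrix_scores: pd.DataFrame, catch_accuracy: pd.Series,
                  config: ScreenConfig) -> list[ExclusionDecision]:
    """Apply every chance rule; one decision per participant per rule.

    ``matrix_scores`` has a ``participant_id`` column plus one integer
    column per task named in ``config.n_items``; ``catch_accuracy`` maps
    participant to mean catch-trial accuracy in [0, 1].
    """
    config.validate()
    decisions: list[ExclusionDecision] = []
    for task in matrix_scores.columns.drop("participant_id"):
        if task not in config.n_items:
            raise ConfigError(f"no item count configured for task {task!r}")
        thr = binomial_chance_threshold(config.n_items[task],
                                        config.guess_rate, config.alpha)
        for pid, score in zip(matrix_scores["participant_id"],
                              matrix_scores[task]):
            if score < 0 or score != int(score):
                raise ConfigError(
                    f"matrix score for {pid!r} on {task!r} must be a "
                    f"nonnegative integer, got {score!r}")
            decisions.append(ExclusionDecision(
                pid, f"matrix-chance:{task}", int(score), thr,
                excluded=score <= thr))
    for pid, acc in catch_accuracy.items():
        if not (0.0 <= acc <= 1.0):
            raise ConfigError(f"catch accuracy for {pid!r} out of [0, 1]")
        decisions.append(ExclusionDecision(
            pid, "catch-chance", float(acc), config.catch_criterion,
            excluded=acc < config.catch_criterion))
    return decisions


def excluded_ids(decisions: list[ExclusionDecision]) -> set:
    """Participants excluded by any rule."""
    return {d.participant_id for d in decisions if d.excluded}


def decisions_frame(decisions: list[ExclusionDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in decisions])
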