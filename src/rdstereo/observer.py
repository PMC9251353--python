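"""Simulated subjects with known stereoacuity.

Human validation of a stereotest needs observers whose ground truth is
known; in software that role is played by psychometric response models.
Two modes are provided:

* deterministic — correct if and only if the presented disparity is at
  least the observer's threshold (the boundary disparity counts as
  visible).  Useful for exercising the protocol logic exactly.
* stochastic — a standard four-parameter psychometric function on
  log-disparity with a cumulative-normal link,

      p(d) = gamma + (1 - gamma - lapse) * Phi(beta * (ln d - ln theta)),

  where gamma is the guessing floor (1/k for a k-figure answer set),
  lapse the rate of misses independent of stimulus strength, and beta
  the slope in log units.

Wrong answers are drawn uniformly from the remaining figures, which is
what forced-choice naming with no bias looks like; a hint restricting
the answer set simply shrinks ``options``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .protocol import LevelSchedule, run_quantitative

__all__ = ["SimulatedObserver", "p_correct", "respond", "recover_stereoacuity"]


@dataclass
class SimulatedObserver:
    """A responder with threshold ``threshold_arcsec`` (theta).

    guess_rate (gamma) defaults to 1/10 for the ten-figure bank;
    lapse_rate (lambda) and slope (beta, per log-disparity unit) only
    matter in stochastic mode.  Seed-deterministic: the same seed and
    trial sequence reproduce the same answers.
    """

    threshold_arcsec: float
    guess_rate: float = 0.1
    lapse_rate: float = 0.0
    slope: float = 8.0
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_arcsec <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold_arcsec}")
        if not 0.0 <= self.guess_rate < 1.0 or not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("guess_rate and lapse_rate must lie in [0, 1)")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"mode must be deterministic|stochastic, got {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def respond(
        self, shape_id: str, disparity_arcsec: float, options: Sequence[str]
    ) -> str | None:
        return respond(self, shape_id, disparity_arcsec, options)


def p_correct(observer: SimulatedObserver, disparity_arcsec: float) -> float:
    """Closed-form probability of a correct answer at a disparity."""
    if disparity_arcsec <= 0:
        return observer.guess_rate
    z = observer.slope * (math.log(disparity_arcsec) - math.log(observer.threshold_arcsec))
    return observer.guess_rate + (1.0 - observer.guess_rate - observer.lapse_rate) * norm.cdf(z)


def respond(
    observer: SimulatedObserver,
    shape_id: str,
    disparity_arcsec: float,
    options: Sequence[str],
) -> str | None:
    """One forced-choice answer; wrong answers uniform over the rest."""
    rng = observer._rng
    if observer.mode == "deterministic":
        correct = disparity_arcsec >= observer.threshold_arcsec
    else:
        correct = rng.random() < p_correct(observer, disparity_arcsec)
    if correct:
        return shape_id
    wrong = [s for s in options if s != shape_id]
    if not wrong:
        return None
    return wrong[rng.integers(len(wrong))]


def recover_stereoacuity(
    observer: SimulatedObserver,
    schedule: LevelSchedule = LevelSchedule(),
    n_sessions: int = 100,
    seed: int = 0,
) -> dict[float | None, int]:
    """Empirical distribution of recorded levels over repeated sessions.

    Each session gets an independently seeded copy of the observer and
    an independent presentation order; the returned mapping counts
    recorded stereoacuity values (None = failed the coarsest level).
    """
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    session_seeds = np.random.SeedSequence(seed).generate_state(2 * n_sessions) >> 1
    counts: dict[float | None, int] = {}
    for k in range(n_sessions):
        obs = replace(observer, seed=int(session_seeds[2 * k]))
        result = run_quantitative(obs, schedule, seed=int(session_seeds[2 * k + 1]))
        key = result.stereoacuity_arcsec
        counts[key] = counts.get(key, 0) + 1
    return counts
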