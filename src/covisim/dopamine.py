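"""Reward, predicted reward, reward-prediction error, and dopamine release.

The procedural learner's training signal is phasic dopamine, modeled as a
piecewise-linear function of the reward-prediction error (RPE):

    RPE = R - P
    D(RPE) = 1            if RPE > 1
           = 0.8*RPE+0.2  if -0.25 <= RPE <= 1
           = 0            if RPE < -0.25

so baseline dopamine is 0.2 (at RPE = 0) with a floor of 0 and a ceiling
of 1.  Predicted reward P tracks obtained reward with the single-operator
rule P_n = P_{n-1} + alpha_pr (R_{n-1} - P_{n-1}), which converges
exponentially to the mean reward at rate (1 - alpha_pr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "D_BASE",
    "DopamineState",
    "obtained_reward",
    "update_predicted_reward",
    "rpe",
    "dopamine_release",
]

#: Baseline dopamine level, the release at RPE = 0.
D_BASE = 0.2

_REWARDS = {"correct": 1.0, "error": -1.0, "absent": 0.0}


def obtained_reward(feedback: str) -> float:
    """Map a feedback event to reward: correct -> +1, error -> -1, absent -> 0."""
    try:
        return _REWARDS[feedback]
    except KeyError:
        raise ValueError(f"unknown feedback kind: {feedback!r}") from None


def update_predicted_reward(p: float, r: float, alpha_pr: float) -> float:
    """Single-operator tracking update toward the last obtained reward."""
    if not 0.0 < alpha_pr <= 1.0:
        raise ValueError("alpha_pr must be in (0, 1]")
    return p + alpha_pr * (r - p)


def rpe(r, p):
    """Reward-prediction error: obtained minus predicted reward."""
    return np.asarray(r, dtype=float) - np.asarray(p, dtype=float)


def dopamine_release(rpe_value):
    """Piecewise-linear dopamine release with floor 0 and ceiling 1."""
    x = np.asarray(rpe_value, dtype=float)
    d = np.where(x > 1.0, 1.0, np.where(x < -0.25, 0.0, 0.8 * x + D_BASE))
    return float(d) if d.ndim == 0 else d


@dataclass
class DopamineState:
    """Per-model dopamine bookkeeping.

    Predicted reward starts at 0 (neutral prior), so the first trial's RPE
    equals the first reward.  ``step`` consumes this trial's reward *after*
    the trial's RPE/dopamine were computed, matching the one-trial lag in
    the predicted-reward recursion.
    """

    alpha_pr: float
    p: float = 0.0
    d_base: float = D_BASE

    def release_for(self, r: float) -> tuple[float, float]:
        """Return (RPE, D) for this trial's reward under the current P."""
        e = r - self.p
        return e, dopamine_release(e)

    def step(self, r: float) -> None:
        self.p = update_predicted_reward(self.p, r, self.alpha_pr)
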