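"""The procedural (striatal, reinforcement-learning) system.

A two-layer network: 625 radial-basis sensory units on a 25x25 grid feed
two striatal units (one per response).  Sensory activation is

    I_K = exp(-d(K, stimulus)^2 / sigma_R)

with d the Euclidean distance in grid units between unit K's preferred
point and the stimulus.  Striatal activation is the plain weighted sum
S_J = sum_K w_KJ I_K (no squashing); the response is A iff S_A > S_B
(ties respond B) and |h_P| = |S_A - S_B| is the system's confidence.

Learning is a three-factor rule gated by pre-synaptic activation,
post-synaptic activation relative to the NMDA/AMPA receptor thresholds,
and dopamine relative to baseline:

    dw_K = + alpha I_K [S_J - th_NMDA]+ [D - D_base]+ (w_max - w_K)
           - beta  I_K [S_J - th_NMDA]+ [D_base - D]+ w_K
           - gamma I_K [th_NMDA - S_J]+ [S_J - th_AMPA]+ w_K

applied, under a strong lateral-inhibition simplification, only to the
column of the striatal unit that carried the procedural response on that
trial.  Synapses therefore strengthen when the post-synaptic unit is
NMDA-active and dopamine is above baseline, weaken when it is NMDA-active
and dopamine is below baseline, and (with gamma > 0) weaken in the
AMPA-only band; below the AMPA threshold nothing changes.

Bootstrapping (:func:`inject_bootstrap`) adds the explicit system's
confidence |h_E| to the striatal unit matching the explicit response on
explicit-controlled trials, before feedback, so the weight update is
biased toward the explicit system's choice without overwriting a
procedural preference that is already stronger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import GRID_SIZE, rbf_centers, to_grid_coords
from .dopamine import D_BASE

__all__ = [
    "N_UNITS",
    "LearningParams",
    "ProceduralState",
    "init_weights",
    "sensory_activation",
    "sensory_activation_matrix",
    "striatal_activation",
    "procedural_respond",
    "procedural_confidence",
    "inject_bootstrap",
    "update_weights",
]

N_UNITS = GRID_SIZE * GRID_SIZE  # 625


@dataclass(frozen=True)
class LearningParams:
    """Three-factor-rule constants.

    Defaults are the fixed values used across all simulations
    (sigma_r = 4.5, th_ampa = 0.01, th_nmda = 0.1); the learning rates are
    the quantities a parameter-space search varies.  gamma defaults to 0 —
    with the thresholds this low the AMPA-only band is never visited in
    practice, but the term is kept in the update for completeness.
    w_max = 1 is the natural ceiling given dopamine in [0, 1].
    """

    alpha: float = 0.03
    beta: float = 0.03
    gamma: float = 0.0
    theta_nmda: float = 0.1
    theta_ampa: float = 0.01
    w_max: float = 1.0
    sigma_r: float = 4.5

    def __post_init__(self):
        if self.theta_nmda <= self.theta_ampa:
            raise ValueError("theta_nmda must exceed theta_ampa")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("learning rates must be >= 0")
        if self.w_max <= 0 or self.sigma_r <= 0:
            raise ValueError("w_max and sigma_r must be positive")


@dataclass
class ProceduralState:
    """Cortical-striatal synapse matrix, one column per striatal unit."""

    weights: np.ndarray  # (625, 2)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_UNITS, 2):
            raise ValueError(f"weights must be ({N_UNITS}, 2)")


def init_weights(seed=0, low: float = 0.001, high: float = 0.2,
                 w_max: float = 1.0) -> ProceduralState:
    """Independent uniform initial weights on [low, high].

    The defaults keep initial striatal activation comfortably above the
    NMDA threshold (so learning can engage from trial one) and far from
    the w_max ceiling.
    """
    if not 0 <= low < high <= w_max:
        raise ValueError("require 0 <= low < high <= w_max")
    rng = np.random.default_rng(seed)
    return ProceduralState(weights=rng.uniform(low, high, size=(N_UNITS, 2)))


def sensory_activation(stimulus, sigma_r: float = 4.5) -> np.ndarray:
    """Radial-basis activation of all 625 sensory units for one stimulus."""
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    g = to_grid_coords(np.asarray(stimulus, dtype=float))
    d2 = ((rbf_centers() - g) ** 2).sum(axis=1)
    return np.exp(-d2 / sigma_r)


def sensory_activation_matrix(stimuli, sigma_r: float = 4.5) -> np.ndarray:
    """(n, 625) activation matrix for a batch of stimuli."""
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    g = to_grid_coords(np.atleast_2d(np.asarray(stimuli, dtype=float)))
    centers = rbf_centers()
    d2 = ((g[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / sigma_r)


def striatal_activation(state: ProceduralState, i_vec: np.ndarray):
    """Weighted-sum activation (S_A, S_B) of the two striatal units."""
    s = state.weights.T @ np.asarray(i_vec, dtype=float)
    return float(s[0]), float(s[1])


def procedural_respond(s_a: float, s_b: float) -> int:
    """0 (A) iff S_A > S_B, else 1 (B); ties respond B."""
    return 0 if s_a > s_b else 1


def procedural_confidence(s_a: float, s_b: float) -> float:
    """|h_P| = |S_A - S_B|."""
    return abs(s_a - s_b)


def inject_bootstrap(s: tuple[float, float], h_e_abs: float,
                     explicit_label: int) -> tuple[float, float]:
    """Add |h_E| to the striatal unit matching the explicit response.

    The other unit is untouched, so a well-trained procedural preference
    for the opposite response can survive the injection.
    """
    s_a, s_b = s
    if explicit_label == 0:
        return s_a + h_e_abs, s_b
    return s_a, s_b + h_e_abs


def update_weights(state: ProceduralState, i_vec: np.ndarray, s_j: float,
                   responded_unit: int, d: float,
                   params: LearningParams, d_base: float = D_BASE,
                   ) -> ProceduralState:
    """Apply the three-factor update to the responded unit's column.

    ``s_j`` is the (post-injection, if bootstrapping) activation of the
    responded unit.  Only that column changes; the result is clamped to
    [0, w_max] as a safety net against overshoot at extreme rates.
    Returns the same state, mutated in place.
    """
    w = state.weights[:, responded_unit]
    i_vec = np.asarray(i_vec, dtype=float)
    nmda = max(s_j - params.theta_nmda, 0.0)
    ampa_band = max(params.theta_nmda - s_j, 0.0) * max(s_j - params.theta_ampa, 0.0)
    dw = (params.alpha * i_vec * nmda * max(d - d_base, 0.0) * (params.w_max - w)
          - params.beta * i_vec * nmda * max(d_base - d, 0.0) * w
          - params.gamma * i_vec * ampa_band * w)
    np.clip(w + dw, 0.0, params.w_max, out=w)
    return state
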