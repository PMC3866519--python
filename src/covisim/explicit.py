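"""The simplified explicit (rule-based, declarative) system.

Instead of the full hypothesis-testing machinery, the explicit system is
hard-coded to the most accurate single-dimension criterion rule for the
category structure from the first trial on, with zero criterial noise, so
it has no free parameters.  Its discriminant on a stimulus is the signed
distance (in grid units) from the stimulus to the decision criterion,

    h_E = sign * (x_d - C_d),

and the response rule is "A if h_E < 0, otherwise B".  |h_E| doubles as
the system's confidence for arbitration: the further a stimulus is from
the criterion, the more the explicit system trusts its own answer.

A stochastically degraded responder (:func:`degrade_to_accuracy`) is also
provided: it emits the true category label with a fixed probability and
the wrong label otherwise, while keeping the rule's |h_E| confidences.
It models an explicit system pinned at a chosen accuracy level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import GRID_SCALE, StimulusSet, to_grid_coords

__all__ = [
    "ExplicitRule",
    "DegradedExplicit",
    "fit_optimal_1d_rule",
    "explicit_discriminant",
    "explicit_response",
    "degrade_to_accuracy",
]

DIM_NAMES = ("x", "y")


@dataclass(frozen=True)
class ExplicitRule:
    """A one-dimensional criterion rule.

    ``dimension`` indexes the stimulus dimension (0 = x, 1 = y),
    ``criterion`` is in grid units, and ``sign`` (+1 or -1) selects which
    side of the criterion is category A (A where ``sign*(x_d - C_d) < 0``).
    ``sigma2_e`` is the criterial-noise variance, fixed to zero here so the
    rule is deterministic.  ``accuracy`` records the training accuracy
    achieved on the set the rule was fitted to.
    """

    dimension: int
    criterion: float
    sign: float = 1.0
    sigma2_e: float = 0.0
    accuracy: float = float("nan")

    def __post_init__(self):
        if self.dimension not in (0, 1):
            raise ValueError("dimension must be 0 (x) or 1 (y)")
        if self.sign not in (1.0, -1.0):
            raise ValueError("sign must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "dimension": DIM_NAMES[self.dimension],
            "criterion": self.criterion,
            "sign": self.sign,
            "accuracy": self.accuracy,
        }


def fit_optimal_1d_rule(stimulus_set: StimulusSet) -> ExplicitRule:
    """Exhaustively find the best single-dimension criterion rule.

    Candidate criteria are the midpoints between adjacent sorted coordinate
    values on each dimension (plus the two extremes), for both response
    polarities; the exact optimum on a finite sample lies at one of these.
    Ties break toward dimension x, then positive sign, then the smallest
    criterion, so fitting is deterministic.
    """
    n = stimulus_set.n
    if n == 0:
        raise ValueError("empty stimulus set")
    labels = stimulus_set.labels
    best = None  # (acc, dim, sign, criterion_stimulus_units)
    for dim in (0, 1):
        vals = stimulus_set.stimuli[:, dim]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sl = labels[order]
        # Candidate criteria: below all points, midpoints, above all points.
        mids = np.concatenate([[sv[0] - 1.0], (sv[:-1] + sv[1:]) / 2.0,
                               [sv[-1] + 1.0]])
        # n_a_below[i] = number of A among the first i sorted points.
        n_a_below = np.concatenate([[0], np.cumsum(sl == 0)])
        n_b_below = np.arange(n + 1) - n_a_below
        n_a = int((labels == 0).sum())
        n_b = n - n_a
        # sign=+1: respond A where value < criterion.
        acc_pos = (n_a_below + (n_b - n_b_below)) / n
        # sign=-1: respond A where value > criterion.
        acc_neg = ((n_a - n_a_below) + n_b_below) / n
        for sign, acc in ((1.0, acc_pos), (-1.0, acc_neg)):
            i = int(np.argmax(acc))
            cand = (acc[i], dim, sign, mids[i])
            if best is None or cand[0] > best[0] + 1e-12:
                best = cand
    acc, dim, sign, crit = best
    return ExplicitRule(dimension=dim, criterion=crit / GRID_SCALE, sign=sign,
                        accuracy=float(acc))


def explicit_discriminant(rule: ExplicitRule, stimulus) -> float:
    """Signed discriminant h_E in grid units for one stimulus (x, y)."""
    g = to_grid_coords(np.asarray(stimulus, dtype=float))
    return float(rule.sign * (g[rule.dimension] - rule.criterion))


def explicit_response(rule: ExplicitRule, stimuli: np.ndarray):
    """Vectorized rule application.

    Returns ``(labels, h_abs)``: integer labels (0=A where h_E < 0, else
    1=B — equality responds B) and confidences |h_E|, both length n.
    """
    g = to_grid_coords(np.atleast_2d(np.asarray(stimuli, dtype=float)))
    h = rule.sign * (g[:, rule.dimension] - rule.criterion)
    labels = np.where(h < 0, 0, 1).astype(np.int64)
    return labels, np.abs(h)


@dataclass(frozen=True)
class DegradedExplicit:
    """Explicit responder pinned to a fixed accuracy.

    On each trial it emits the true label with probability ``target_acc``
    and the wrong label otherwise, independently per trial; confidences
    |h_E| still come from the underlying rule.
    """

    rule: ExplicitRule
    target_acc: float
    seed: object

    def draws(self, n_trials: int) -> np.ndarray:
        """The uniform [0,1) stream deciding correctness per trial."""
        return np.random.default_rng(self.seed).random(n_trials)

    def responses(self, true_labels: np.ndarray) -> np.ndarray:
        true_labels = np.asarray(true_labels)
        u = self.draws(len(true_labels))
        return np.where(u < self.target_acc, true_labels, 1 - true_labels)


def degrade_to_accuracy(rule: ExplicitRule, target_acc: float,
                        seed=0) -> DegradedExplicit:
    if not 0.5 <= target_acc <= 1.0:
        raise ValueError("target accuracy must be in [0.5, 1]")
    return DegradedExplicit(rule=rule, target_acc=float(target_acc), seed=seed)
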