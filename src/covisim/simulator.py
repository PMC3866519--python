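"""Trial loop, training/test phases, seed-bank batches, RB takeover.

A *run* is one training pass of a model configuration through a stimulus
set followed by a frozen-weight test phase.  Everything random in a run
(initial weights, stimulus ordering, and — when the explicit system is
degraded — its per-trial errors) derives from a single run seed via
independent spawned streams, so runs are bit-reproducible and a batch
over a seed bank is exactly the set of single runs with those seeds.

:func:`run_training` is the readable reference loop producing a full
per-trial log; :func:`run_batch` drives the vectorized engine for the
thousands of runs a parameter-space partitioning needs.  The two paths
are cross-checked in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import dopamine as dm
from .arbitration import ModelConfig, select_response, route_feedback
from .categories import StimulusSet, TrialSequence, make_trial_sequence
from .engine import BatchResult, run_many
from .explicit import ExplicitRule, explicit_response, fit_optimal_1d_rule
from .procedural import (N_UNITS, init_weights, inject_bootstrap,
                         procedural_confidence, procedural_respond,
                         sensory_activation_matrix, update_weights)

__all__ = [
    "SEED_BANK_19",
    "SimulationResult",
    "BatchSummary",
    "run_training",
    "run_test",
    "run_batch",
    "rb_takeover_experiment",
    "random_seed_bank",
]

logger = logging.getLogger("covisim")

#: The fixed 19-seed initialization bank used for deterministic
#: parameter-space partitioning: every grid point is evaluated on the same
#: 19 stimulus orderings and weight initializations.
SEED_BANK_19 = tuple(range(1, 20))


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an integer (or SeedSequence) to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _run_streams(seed):
    """Independent (weights, ordering, explicit-degrade) streams for one run."""
    return as_seed_sequence(seed).spawn(3)


def random_seed_bank(n: int, seed=0) -> list:
    """``n`` fresh independent run seeds derived from ``seed``."""
    return list(as_seed_sequence(seed).spawn(n))


@dataclass
class SimulationResult:
    """One run: per-trial log, final weights, summary accuracies."""

    trial_log: pd.DataFrame
    final_weights: np.ndarray  # (625, 2)
    training_accuracy: float
    test_accuracy: float
    proc_control_prop: float
    rule: ExplicitRule


@dataclass
class BatchSummary:
    """Seed-bank batch: per-run summaries plus their aggregates."""

    seeds: list
    test_accuracy: np.ndarray
    train_accuracy: np.ndarray
    proc_control_prop: np.ndarray
    mean_test_accuracy: float
    sd_test_accuracy: float
    mean_proc_control: float
    final_weights: np.ndarray | None = None  # (R, 625, 2)
    rule: ExplicitRule | None = None


def _explicit_for(config: ModelConfig, stimulus_set: StimulusSet):
    """Fitted rule plus per-stimulus explicit labels/confidences."""
    rule = fit_optimal_1d_rule(stimulus_set)
    labels, h_abs = explicit_response(rule, stimulus_set.stimuli)
    return rule, labels, h_abs


def run_training(config: ModelConfig, stimulus_set: StimulusSet, seed=0,
                 seq: TrialSequence | None = None) -> SimulationResult:
    """Train one model instance and test it with frozen weights.

    ``seed`` drives the initial weights, the stimulus ordering (unless an
    explicit ``seq`` is supplied) and, for a degraded explicit system, its
    error trials.
    """
    w_ss, order_ss, degrade_ss = _run_streams(seed)
    if seq is None:
        seq = make_trial_sequence(stimulus_set, config.epochs, order_ss)
    ordering = np.asarray(seq.ordering)
    if ordering.size == 0 or ordering.max() >= stimulus_set.n:
        raise ValueError("trial sequence inconsistent with stimulus set")
    n_trials = len(ordering)

    rule, exp_labels, h_e_abs = _explicit_for(config, stimulus_set)
    if config.explicit_accuracy is not None:
        u = np.random.default_rng(degrade_ss).random(n_trials)
    state = init_weights(w_ss, config.init_low, config.init_high,
                         config.learning.w_max)
    i_all = sensory_activation_matrix(stimulus_set.stimuli,
                                      config.learning.sigma_r)
    dop = dm.DopamineState(alpha_pr=config.alpha_pr, d_base=config.d_base)
    theta_e = config.theta_e_init
    truth = stimulus_set.labels

    rows = []
    for t in range(n_trials):
        s = int(ordering[t])
        i_vec = i_all[s]
        s_a, s_b = state.weights.T @ i_vec
        if config.explicit_accuracy is None:
            e_lab = int(exp_labels[s])
        else:
            e_lab = int(truth[s]) if u[t] < config.explicit_accuracy \
                else 1 - int(truth[s])
        h_e = float(h_e_abs[s])
        p_lab = procedural_respond(s_a, s_b)
        h_p = procedural_confidence(s_a, s_b)
        if config.soft:
            controller, emitted = select_response(theta_e, h_e, e_lab,
                                                  1.0 - theta_e, h_p, p_lab)
        else:
            controller, emitted = "explicit", e_lab
        if config.bootstrap and controller == "explicit":
            s_a, s_b = inject_bootstrap((s_a, s_b), h_e, e_lab)
        responded = procedural_respond(s_a, s_b)
        correct = emitted == truth[s]
        event = route_feedback(config.feedback_mode, controller, bool(correct),
                               bool(p_lab == truth[s]))
        r_n = dm.obtained_reward(event)
        err, d_rel = dop.release_for(r_n)
        update_weights(state, i_vec, (s_a, s_b)[responded], responded, d_rel,
                       config.learning, config.d_base)
        p_used = dop.p
        dop.step(r_n)
        rows.append((t, stimulus_set.stimuli[s, 0], stimulus_set.stimuli[s, 1],
                     int(truth[s]), e_lab, p_lab, controller, emitted,
                     bool(correct), r_n, p_used, err, d_rel, theta_e))
        if e_lab == truth[s]:
            theta_e = theta_e + config.delta_oc * (1.0 - theta_e)
        else:
            theta_e = theta_e - config.delta_oe * theta_e

    log = pd.DataFrame(rows, columns=[
        "trial", "x", "y", "true_label", "explicit_label", "procedural_label",
        "controller", "emitted_label", "correct", "R", "P", "RPE", "D",
        "theta_E"])
    return SimulationResult(
        trial_log=log,
        final_weights=state.weights,
        training_accuracy=float(log["correct"].mean()),
        test_accuracy=run_test(state.weights, stimulus_set,
                               config.learning.sigma_r),
        proc_control_prop=float((log["controller"] == "procedural").mean()),
        rule=rule,
    )


def run_test(weights: np.ndarray, stimulus_set: StimulusSet,
             sigma_r: float = 4.5) -> float:
    """Frozen-weight procedural accuracy: classify every stimulus once."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (N_UNITS, 2):
        raise ValueError(f"weights must be ({N_UNITS}, 2)")
    i_all = sensory_activation_matrix(stimulus_set.stimuli, sigma_r)
    s = i_all @ weights  # (n, 2)
    pred = (s[:, 0] <= s[:, 1]).astype(np.int64)  # ties respond B
    return float((pred == stimulus_set.labels).mean())


def _batch_inputs(config: ModelConfig, stimulus_set: StimulusSet, seeds):
    """Per-run orderings/weights/degrade-draws for the engine."""
    n_trials = config.epochs * stimulus_set.n
    orderings = np.empty((len(seeds), n_trials), dtype=np.int64)
    w0 = np.empty((len(seeds), N_UNITS, 2))
    draws = np.empty((len(seeds), n_trials)) \
        if config.explicit_accuracy is not None else None
    for i, seed in enumerate(seeds):
        w_ss, order_ss, degrade_ss = _run_streams(seed)
        orderings[i] = make_trial_sequence(stimulus_set, config.epochs,
                                           order_ss).ordering
        w0[i] = init_weights(w_ss, config.init_low, config.init_high,
                             config.learning.w_max).weights
        if draws is not None:
            draws[i] = np.random.default_rng(degrade_ss).random(n_trials)
    return orderings, w0, draws


def run_batch(config: ModelConfig, stimulus_set: StimulusSet,
              seeds=SEED_BANK_19, return_weights: bool = False,
              backend: str = "auto") -> BatchSummary:
    """Run the configuration once per seed and aggregate the summaries."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed required")
    rule, exp_labels, h_e_abs = _explicit_for(config, stimulus_set)
    i_all = sensory_activation_matrix(stimulus_set.stimuli,
                                      config.learning.sigma_r)
    orderings, w0, draws = _batch_inputs(config, stimulus_set, seeds)
    res: BatchResult = run_many(
        i_all, stimulus_set.labels, exp_labels, h_e_abs, orderings, w0,
        alpha=config.learning.alpha, beta=config.learning.beta,
        gamma=config.learning.gamma, alpha_pr=config.alpha_pr,
        delta_oc=config.delta_oc, delta_oe=config.delta_oe,
        feedback_independent=(config.feedback_mode == "independent"),
        soft_switch=config.soft, bootstrap=config.bootstrap,
        theta_e_init=config.theta_e_init, d_base=config.d_base,
        theta_nmda=config.learning.theta_nmda,
        theta_ampa=config.learning.theta_ampa, w_max=config.learning.w_max,
        degrade_draws=draws, degrade_acc=config.explicit_accuracy,
        return_weights=return_weights, backend=backend)
    logger.info("%s batch on %s: %d seeds, mean test accuracy %.3f, "
                "procedural control %.3f", config.name,
                stimulus_set.structure_kind, len(seeds),
                float(res.test_accuracy.mean()),
                float(res.proc_control_prop.mean()))
    return BatchSummary(
        seeds=seeds,
        test_accuracy=res.test_accuracy,
        train_accuracy=res.train_accuracy,
        proc_control_prop=res.proc_control_prop,
        mean_test_accuracy=float(res.test_accuracy.mean()),
        sd_test_accuracy=float(res.test_accuracy.std(ddof=0)),
        mean_proc_control=float(res.proc_control_prop.mean()),
        final_weights=res.final_weights,
        rule=rule,
    )


def rb_takeover_experiment(config: ModelConfig, stimulus_set: StimulusSet,
                           accuracies=(0.90, 0.95, 0.99, 1.00),
                           n_sims: int = 200, seed=0,
                           backend: str = "auto") -> dict[float, float]:
    """Procedural takeover of rule-based categories vs. explicit accuracy.

    For each hard-coded explicit accuracy level, runs ``n_sims`` fresh
    simulations of the soft-switching single-feedback model on the RB
    structure and returns the mean proportion of trials on which the
    procedural system controlled the response.
    """
    if not (config.soft and config.feedback_mode == "single"):
        raise ValueError("takeover experiment requires the soft-switching, "
                         "single-feedback architecture")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    roots = as_seed_sequence(seed).spawn(len(accuracies))
    out = {}
    for acc, root in zip(accuracies, roots):
        cfg = replace(config, explicit_accuracy=float(acc))
        summary = run_batch(cfg, stimulus_set, seeds=root.spawn(n_sims),
                            backend=backend)
        out[float(acc)] = summary.mean_proc_control
    return out
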