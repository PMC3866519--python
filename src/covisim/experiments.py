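"""Pre-configured simulation studies at their standard conditions.

Each function runs one complete study — category generation, training,
evaluation — and returns its headline numbers, so the full battery can
be reproduced from a single seed.  Problem sizes follow the standard
protocol throughout: 300 stimuli per category, the fixed 19-seed
initialization bank for deterministic parameter-space partitioning,
32 training passes through the sample (the training length at which
procedural accuracy has reached asymptote across the search ranges and
structures; see docs/methods.md), and 200 fresh random initializations
for robustness
checks.  The five-axis soft-switch space uses a 7-seed subset of the
bank and 5 lattice points per axis to keep its 3125-point grid at desk
scale.
"""

from __future__ import annotations

import math

import numpy as np

from .analysis import accuracy_takeover_correlation
from .arbitration import ModelConfig
from .categories import (II_PARAMS, gen_hybrid_categories, gen_ii_categories,
                         gen_rb_categories)
from .explicit import ExplicitRule, explicit_response, fit_optimal_1d_rule
from .psp import (PSPResult, config_with_params, grid_partition,
                  robustness_stage)
from .simulator import SEED_BANK_19, as_seed_sequence, run_batch

__all__ = [
    "REDUCED_BANK",
    "explicit_ceiling_ii",
    "model0_high_accuracy_volume",
    "model1_failure_robustness",
    "bootstrapped_model1_grid",
    "model2_low_accuracy_volume",
    "takeover_correlations",
    "rb_takeover_perfect_explicit",
    "run_replication_battery",
]

#: Seed-bank subset used on the five-axis space (3125 lattice points).
REDUCED_BANK = SEED_BANK_19[:7]


def _structure(kind: str, seed, n_per_cat: int = 300):
    if kind == "II":
        return gen_ii_categories(II_PARAMS, n_per_cat, seed)
    if kind == "HYBRID":
        return gen_hybrid_categories(n_per_cat, seed)
    if kind == "RB":
        return gen_rb_categories(II_PARAMS, n_per_cat, seed)
    raise ValueError(f"unknown structure kind: {kind!r}")


def explicit_ceiling_ii(seed=0, n_seeds: int = 50,
                        n_per_cat: int = 300) -> dict:
    """Explicit-system accuracy ceiling on II samples.

    Draws ``n_seeds`` fresh 300+300 samples from the II category
    distributions and scores the one-dimensional bound at its optimal
    (population) position — the vertical criterion through the midline,
    which is where the simulations' hard-coded rule sits — on each
    sample.  The population ceiling has the closed form Phi(10 / sigma).
    The in-sample maximum of a full criterion sweep is reported alongside;
    it runs ~1.5 points higher from optimizing on the evaluation sample.
    """
    optimal = ExplicitRule(dimension=0, criterion=50.0 / 4.0, sign=1.0)
    ceiling, swept = [], []
    for child in as_seed_sequence(seed).spawn(n_seeds):
        sample = gen_ii_categories(II_PARAMS, n_per_cat, child)
        labels, _ = explicit_response(optimal, sample.stimuli)
        ceiling.append(float((labels == sample.labels).mean()))
        swept.append(fit_optimal_1d_rule(sample).accuracy)
    pop = 0.5 * (1.0 + math.erf((10.0 / math.sqrt(II_PARAMS.variance))
                                / math.sqrt(2.0)))
    return {
        "mean_accuracy_pct": 100.0 * float(np.mean(ceiling)),
        "sd_accuracy_pct": 100.0 * float(np.std(ceiling)),
        "fitted_max_accuracy_pct": 100.0 * float(np.mean(swept)),
        "population_accuracy_pct": 100.0 * pop,
        "n_seeds": n_seeds,
    }


def model0_high_accuracy_volume(structure: str = "II", seed=0,
                                points_per_axis: int = 8,
                                seed_bank=SEED_BANK_19) -> dict:
    """Independent-feedback soft-switch model: share of the three-axis
    parameter-space volume reaching at least 90% test accuracy."""
    stimuli = _structure(structure, seed)
    config = ModelConfig.model0()
    result = grid_partition(config, points_per_axis=points_per_axis,
                            stimulus_set=stimuli, seed_bank=seed_bank)
    ge90 = float((result.points["accuracy"] >= 0.90)
                 .mul(result.points["volume_weight"]).sum())
    return {
        "volume_pct_ge_90": 100.0 * ge90,
        "min_accuracy": float(result.points["accuracy"].min()),
        "partition": result,
    }


def model1_failure_robustness(seed=0, points_per_axis: int = 8,
                              seed_bank=SEED_BANK_19,
                              n_random: int = 200) -> dict:
    """Single-feedback never-switching model: the fixed-bank partition
    suggests some learning, but re-testing every discovered pattern's
    representative parameters on fresh initializations exposes it as an
    ordering artifact.  Returns the worst (highest) random-bank accuracy."""
    root = as_seed_sequence(seed)
    stim_seed, robust_seed = root.spawn(2)
    stimuli = _structure("II", stim_seed)
    config = ModelConfig.model1()
    result = grid_partition(config, points_per_axis=points_per_axis,
                            stimulus_set=stimuli, seed_bank=seed_bank,
                            scheme="deciles_split_60s")
    table = robustness_stage(result, config, stimuli, n_random=n_random,
                             seed=robust_seed)
    return {
        "max_random_accuracy_pct": 100.0 * float(
            table["random_accuracy"].max()),
        "robustness": table,
        "partition": result,
    }


def bootstrapped_model1_grid(seed=0, points_per_axis: int = 8,
                             seed_bank=SEED_BANK_19) -> dict:
    """Never-switching model with explicit-response injection: test
    accuracy across the whole three-axis grid on II categories."""
    stimuli = _structure("II", seed)
    config = ModelConfig.model1(bootstrap=True)
    result = grid_partition(config, points_per_axis=points_per_axis,
                            stimulus_set=stimuli, seed_bank=seed_bank)
    acc = result.points["accuracy"]
    return {
        "mean_accuracy_pct": 100.0 * float(acc.mean()),
        "min_accuracy_pct": 100.0 * float(acc.min()),
        "frac_points_ge_90": float((acc >= 0.90).mean()),
        "partition": result,
    }


def model2_low_accuracy_volume(seed=0, points_per_axis: int = 5,
                               seed_bank=REDUCED_BANK,
                               structure: str = "II") -> dict:
    """Single-feedback soft-switch model: share of the five-axis volume
    with test accuracy below 70% (learning confined to parameterizations
    where the procedural system dominates responding)."""
    stimuli = _structure(structure, seed)
    config = ModelConfig.model2()
    result = grid_partition(config, points_per_axis=points_per_axis,
                            stimulus_set=stimuli, seed_bank=seed_bank)
    below = float((result.points["accuracy"] < 0.70)
                  .mul(result.points["volume_weight"]).sum())
    return {
        "volume_pct_below_70": 100.0 * below,
        "partition": result,
        "stimuli": stimuli,
    }


def _rep_summary_pairs(partition: PSPResult, config: ModelConfig, stimuli,
                       seeds) -> list[tuple[float, float]]:
    """(test accuracy, n procedural-controlled trials) per representative."""
    pairs = []
    n_trials = config.epochs * stimuli.n
    for _, rep in partition.volumes.iterrows():
        cfg = config_with_params(config,
                                 {n: rep[n] for n in partition.space.names})
        summary = run_batch(cfg, stimuli, seeds=seeds)
        pairs.append((summary.mean_test_accuracy,
                      summary.mean_proc_control * n_trials))
    return pairs


def takeover_correlations(seed=0, ii_partition: PSPResult | None = None,
                          ii_stimuli=None,
                          hybrid_partition: PSPResult | None = None,
                          hybrid_stimuli=None,
                          points_per_axis_hybrid: int = 4,
                          n_random: int = 200) -> dict:
    """Accuracy vs. procedural takeover for the soft-switch single-feedback
    model.

    For each discovered pattern's representative parameters (on II and
    hybrid structures), correlates mean test accuracy with the mean
    number of procedural-controlled training responses, on the fixed
    19-seed bank and on ``n_random`` fresh initializations.
    Representatives are re-run on the same stimulus sample their
    partition was computed on.  Returns the four correlations and their
    minimum.
    """
    root = as_seed_sequence(seed)
    ii_seed, hy_seed, rand_seed = root.spawn(3)
    config = ModelConfig.model2()
    if ii_partition is None:
        ii_study = model2_low_accuracy_volume(seed=ii_seed)
        ii_partition, ii_stimuli = ii_study["partition"], ii_study["stimuli"]
    if ii_stimuli is None:
        raise ValueError("ii_stimuli required with a precomputed ii_partition")
    if hybrid_partition is None:
        hybrid_stimuli = _structure("HYBRID", hy_seed)
        hybrid_partition = grid_partition(
            config, points_per_axis=points_per_axis_hybrid,
            stimulus_set=hybrid_stimuli, seed_bank=REDUCED_BANK)
    if hybrid_stimuli is None:
        raise ValueError("hybrid_stimuli required with a precomputed "
                         "hybrid_partition")
    random_seeds = as_seed_sequence(rand_seed).spawn(n_random)
    out = {}
    for kind, partition, stimuli in (("II", ii_partition, ii_stimuli),
                                     ("HYBRID", hybrid_partition,
                                      hybrid_stimuli)):
        for bank_name, seeds in (("fixed", list(SEED_BANK_19)),
                                 ("random", random_seeds)):
            pairs = _rep_summary_pairs(partition, config, stimuli, seeds)
            out[f"r_{kind.lower()}_{bank_name}"] = \
                accuracy_takeover_correlation(pairs)
    out["min_r"] = min(v for k, v in out.items() if k.startswith("r_"))
    return out


def rb_takeover_perfect_explicit(seed=0, best_params: dict | None = None,
                                 n_sims: int = 200,
                                 accuracies=(0.90, 0.95, 0.99, 1.00)) -> dict:
    """Soft-switch single-feedback model on rule-based categories with the
    explicit system pinned at fixed accuracy levels.

    ``best_params`` are the parameters that produced the best II learning
    (the representative of the highest discovered accuracy pattern); if
    omitted they are found by partitioning first.  Returns the mean
    proportion of procedural-controlled trials per accuracy level.
    """
    from .simulator import rb_takeover_experiment

    root = as_seed_sequence(seed)
    rb_seed, psp_seed, sim_seed = root.spawn(3)
    if best_params is None:
        partition = model2_low_accuracy_volume(seed=psp_seed)["partition"]
        best_params = partition.representative(
            partition.volumes.iloc[-1]["pattern"])
    config = config_with_params(ModelConfig.model2(), best_params)
    stimuli = _structure("RB", rb_seed)
    props = rb_takeover_experiment(config, stimuli, accuracies=accuracies,
                                   n_sims=n_sims, seed=sim_seed)
    return {
        "proportions": props,
        "prop_at_100": props[1.00],
        "best_params": best_params,
    }


def run_replication_battery(seed: int = 0) -> dict:
    """Run every study once, sharing the expensive partitions.

    Returns a flat dict of headline numbers plus the per-study payloads.
    """
    root = as_seed_sequence(seed)
    (s_ceiling, s_m0ii, s_m0hy, s_m1, s_m1b, s_m2, s_corr, s_rb) = \
        root.spawn(8)
    out = {}
    out["explicit_ceiling"] = explicit_ceiling_ii(seed=s_ceiling)
    out["model0_ii"] = model0_high_accuracy_volume("II", seed=s_m0ii)
    out["model0_hybrid"] = model0_high_accuracy_volume("HYBRID", seed=s_m0hy)
    out["model1"] = model1_failure_robustness(seed=s_m1)
    out["model1_bootstrap"] = bootstrapped_model1_grid(seed=s_m1b)
    out["model2"] = model2_low_accuracy_volume(seed=s_m2)
    out["takeover"] = takeover_correlations(
        seed=s_corr, ii_partition=out["model2"]["partition"],
        ii_stimuli=out["model2"]["stimuli"])
    best = out["model2"]["partition"]
    out["rb_takeover"] = rb_takeover_perfect_explicit(
        seed=s_rb,
        best_params=best.representative(best.volumes.iloc[-1]["pattern"]))
    return out
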