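"""Parameter-space partitioning (PSP).

PSP asks a global question about a model: over the whole space of its
free parameters, which qualitatively distinct behaviors (*data patterns*)
can it produce, and what fraction of the space's volume produces each?
Here the data pattern of a parameter point is the decile of the
procedural system's frozen-weight test accuracy, averaged over the fixed
19-seed initialization bank so the map is deterministic.

Two search strategies are provided:

* :func:`grid_partition` — the primary, deterministic strategy: evaluate
  every point of a log-spaced lattice over the search ranges and estimate
  each pattern's volume as its fraction of lattice points (equal cell
  weights in log space).
* :func:`mcmc_partition` — a light region-growing Monte-Carlo search that
  jitters around discovered points, useful for spot-checking the grid on
  small spaces; its volume estimates are sample fractions and are cruder.

A second, *robustness* stage (:func:`robustness_stage`) re-tests each
discovered pattern's representative parameters on fresh random orderings
and initializations: a pattern that only appears on the fixed bank is an
artifact of those particular orderings, not a behavior of the model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arbitration import ModelConfig
from .categories import StimulusSet
from .engine import run_many
from .procedural import sensory_activation_matrix
from .simulator import (SEED_BANK_19, _batch_inputs, _explicit_for,
                        as_seed_sequence, run_batch)

__all__ = [
    "TABLE3_RANGES",
    "DECILE_LABELS",
    "ParameterSpace",
    "PSPResult",
    "accuracy_to_pattern",
    "pattern_labels",
    "grid_partition",
    "mcmc_partition",
    "robustness_stage",
    "config_with_params",
]

logger = logging.getLogger("covisim")

#: Search range per free parameter.
TABLE3_RANGES = {
    "alpha_pr": (0.005, 1.0),
    "alpha": (0.001, 1.0),
    "beta": (0.001, 1.0),
    "delta_oc": (0.001, 0.2),
    "delta_oe": (0.001, 0.2),
}

DECILE_LABELS = ("0-9", "10-19", "20-29", "30-39", "40-49",
                 "50-59", "60-69", "70-79", "80-89", "90-100")


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered named axes with (low, high) ranges."""

    axes: tuple[tuple[str, tuple[float, float]], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @classmethod
    def for_config(cls, config: ModelConfig) -> "ParameterSpace":
        """Three learning axes; plus the two trust-rate axes for the
        soft-switching single-feedback architecture, whose behavior they
        directly shape (independent-feedback learning ignores them)."""
        names = ["alpha_pr", "alpha", "beta"]
        if config.soft and config.feedback_mode == "single":
            names += ["delta_oc", "delta_oe"]
        return cls(axes=tuple((n, TABLE3_RANGES[n]) for n in names))

    def grid_axes(self, points_per_axis: int) -> list[np.ndarray]:
        if points_per_axis < 2:
            raise ValueError("points_per_axis must be >= 2")
        return [np.geomspace(lo, hi, points_per_axis)
                for _, (lo, hi) in self.axes]


def pattern_labels(scheme: str = "deciles") -> tuple[str, ...]:
    if scheme == "deciles":
        return DECILE_LABELS
    if scheme == "deciles_split_60s":
        out = []
        for lab in DECILE_LABELS:
            out.extend(("60-64", "65-69") if lab == "60-69" else (lab,))
        return tuple(out)
    raise ValueError(f"unknown pattern scheme: {scheme!r}")


def accuracy_to_pattern(acc: float, scheme: str = "deciles") -> str:
    """Decile pattern of an accuracy in [0, 1].

    Deciles are left-closed/right-open with the top decile closed at 100%
    (0.90 maps to "90-100").  The ``deciles_split_60s`` scheme subdivides
    the 60s decile into 60-64 and 65-69 for a finer partitioning.
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    idx = min(int(acc * 10.0), 9)
    lab = DECILE_LABELS[idx]
    if scheme == "deciles_split_60s" and lab == "60-69":
        return "60-64" if acc < 0.65 else "65-69"
    if scheme not in ("deciles", "deciles_split_60s"):
        raise ValueError(f"unknown pattern scheme: {scheme!r}")
    return lab


@dataclass
class PSPResult:
    """Mapping from parameter points to patterns, with volume estimates."""

    points: pd.DataFrame  # one row per evaluated point
    volumes: pd.DataFrame  # one row per discovered pattern
    space: ParameterSpace
    scheme: str
    seed_bank: tuple
    method: str
    points_per_axis: int | None = None

    def representative(self, pattern: str) -> dict[str, float]:
        row = self.volumes.set_index("pattern").loc[pattern]
        return {n: float(row[n]) for n in self.space.names}


def config_with_params(config: ModelConfig,
                       params: dict[str, float]) -> ModelConfig:
    """Copy of ``config`` with the named free parameters substituted."""
    learning = config.learning
    lp = {k: params[k] for k in ("alpha", "beta", "gamma") if k in params}
    if lp:
        learning = replace(learning, **lp)
    other = {k: params[k] for k in ("alpha_pr", "delta_oc", "delta_oe")
             if k in params}
    return replace(config, learning=learning, **other)


def _make_evaluator(config: ModelConfig, space: ParameterSpace,
                    stimulus_set: StimulusSet, seed_bank, backend: str,
                    chunk_runs: int = 8192):
    """Build evaluate(points) -> (mean accuracy, mean proc-control) arrays.

    Points within a chunk are run in one engine call of
    ``n_points_in_chunk * len(seed_bank)`` simulations.
    """
    seeds = list(seed_bank)
    n_seeds = len(seeds)
    rule, exp_labels, h_e = _explicit_for(config, stimulus_set)
    i_all = sensory_activation_matrix(stimulus_set.stimuli,
                                      config.learning.sigma_r)
    orderings, w0, draws = _batch_inputs(config, stimulus_set, seeds)
    names = space.names
    base = {"alpha": config.learning.alpha, "beta": config.learning.beta,
            "gamma": config.learning.gamma, "alpha_pr": config.alpha_pr,
            "delta_oc": config.delta_oc, "delta_oe": config.delta_oe}
    chunk_points = max(1, chunk_runs // n_seeds)

    def evaluate(points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        accs, procs = [], []
        for lo in range(0, len(points), chunk_points):
            chunk = points[lo:lo + chunk_points]
            n = len(chunk)
            per_run = dict(base)
            for j, name in enumerate(names):
                per_run[name] = np.repeat(chunk[:, j], n_seeds)
            res = run_many(
                i_all, stimulus_set.labels, exp_labels, h_e,
                np.tile(orderings, (n, 1)), np.tile(w0, (n, 1, 1)),
                alpha=per_run["alpha"], beta=per_run["beta"],
                gamma=per_run["gamma"], alpha_pr=per_run["alpha_pr"],
                delta_oc=per_run["delta_oc"], delta_oe=per_run["delta_oe"],
                feedback_independent=(config.feedback_mode == "independent"),
                soft_switch=config.soft, bootstrap=config.bootstrap,
                theta_e_init=config.theta_e_init, d_base=config.d_base,
                theta_nmda=config.learning.theta_nmda,
                theta_ampa=config.learning.theta_ampa,
                w_max=config.learning.w_max,
                degrade_draws=None if draws is None else np.tile(draws, (n, 1)),
                degrade_acc=config.explicit_accuracy, backend=backend)
            accs.append(res.test_accuracy.reshape(n, n_seeds).mean(axis=1))
            procs.append(res.proc_control_prop.reshape(n, n_seeds).mean(axis=1))
        return np.concatenate(accs), np.concatenate(procs)

    return evaluate


def _assemble_result(points: np.ndarray, acc: np.ndarray, proc: np.ndarray,
                     space: ParameterSpace, scheme: str, seed_bank, method: str,
                     points_per_axis=None, weights=None) -> PSPResult:
    df = pd.DataFrame(points, columns=list(space.names))
    df["accuracy"] = acc
    df["proc_control"] = proc
    df["pattern"] = [accuracy_to_pattern(a, scheme) for a in acc]
    if weights is None:
        weights = np.full(len(df), 1.0 / len(df))
    df["volume_weight"] = weights

    vol_rows = []
    for pattern in pattern_labels(scheme):
        sub = df[df["pattern"] == pattern]
        if sub.empty:
            continue
        # Representative point: the member closest (in log parameter space)
        # to the pattern region's centroid — a geometric notion of "most
        # typical of the region", robust to outcome outliers at the
        # region's corners.
        logp = np.log10(sub[list(space.names)].to_numpy())
        rep = sub.iloc[int(np.argmin(((logp - logp.mean(axis=0)) ** 2)
                                     .sum(axis=1)))]
        row = {"pattern": pattern,
               "volume_fraction": float(sub["volume_weight"].sum()),
               "n_points": len(sub),
               "accuracy": float(rep["accuracy"]),
               "proc_control": float(rep["proc_control"])}
        row.update({n: float(rep[n]) for n in space.names})
        vol_rows.append(row)
    volumes = pd.DataFrame(vol_rows)
    return PSPResult(points=df, volumes=volumes, space=space, scheme=scheme,
                     seed_bank=tuple(seed_bank), method=method,
                     points_per_axis=points_per_axis)


def grid_partition(config: ModelConfig, space: ParameterSpace | None = None,
                   points_per_axis: int = 8,
                   stimulus_set: StimulusSet | None = None,
                   seed_bank=SEED_BANK_19, scheme: str = "deciles",
                   evaluate=None, backend: str = "auto") -> PSPResult:
    """Deterministic lattice partitioning of the parameter space.

    Every point of the log-spaced lattice is evaluated on the fixed seed
    bank; a pattern's volume fraction is its share of lattice points.
    ``evaluate`` may be injected (mainly for testing) as a callable
    mapping an (n, ndim) point array to (accuracy, proc_control) arrays.
    """
    if space is None:
        space = ParameterSpace.for_config(config)
    grid = space.grid_axes(points_per_axis)
    points = np.array(list(itertools.product(*grid)))
    if evaluate is None:
        if stimulus_set is None:
            raise ValueError("stimulus_set required unless evaluate is given")
        evaluate = _make_evaluator(config, space, stimulus_set, seed_bank,
                                   backend)
    logger.info("%s grid partition: %d points (%d/axis, %d-dim), bank of %d",
                config.name, len(points), points_per_axis, space.ndim,
                len(tuple(seed_bank)))
    acc, proc = evaluate(points)
    return _assemble_result(points, np.asarray(acc), np.asarray(proc), space,
                            scheme, seed_bank, "grid", points_per_axis)


def mcmc_partition(config: ModelConfig, space: ParameterSpace | None = None,
                   n_cycles: int = 6, seed=0,
                   stimulus_set: StimulusSet | None = None,
                   seed_bank=SEED_BANK_19, scheme: str = "deciles",
                   steps_per_chain: int = 10, evaluate=None,
                   backend: str = "auto") -> PSPResult:
    """Region-growing Monte-Carlo partitioning.

    Maintains one chain per discovered pattern.  Each cycle proposes
    log-space Gaussian jitters around every chain's current point; a
    proposal matching the chain's pattern advances the chain, otherwise it
    seeds (or feeds) the chain of the pattern it produced.  Volumes are
    the fractions of all evaluated samples per pattern — a cruder estimate
    than the lattice one, suitable for cross-checks on small spaces.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if space is None:
        space = ParameterSpace.for_config(config)
    if evaluate is None:
        if stimulus_set is None:
            raise ValueError("stimulus_set required unless evaluate is given")
        evaluate = _make_evaluator(config, space, stimulus_set, seed_bank,
                                   backend)
    rng = np.random.default_rng(seed)
    lo = np.log10([r[0] for _, r in space.axes])
    hi = np.log10([r[1] for _, r in space.axes])
    scale = (hi - lo) / 8.0

    def eval_points(log_pts):
        acc, proc = evaluate(10.0 ** np.atleast_2d(log_pts))
        return np.asarray(acc), np.asarray(proc)

    start = (lo + hi) / 2.0
    acc0, proc0 = eval_points(start)
    chains = {accuracy_to_pattern(acc0[0], scheme): start}
    log_pts = [start]
    accs = [acc0[0]]
    procs = [proc0[0]]
    for _ in range(n_cycles):
        for _ in range(steps_per_chain):
            current = list(chains.items())
            proposals = np.clip(
                np.array([pt for _, pt in current])
                + rng.normal(0.0, scale, size=(len(current), space.ndim)),
                lo, hi)
            acc, proc = eval_points(proposals)
            for (pattern, _), prop, a, p in zip(current, proposals, acc, proc):
                new_pattern = accuracy_to_pattern(a, scheme)
                chains[new_pattern] = prop
                log_pts.append(prop)
                accs.append(a)
                procs.append(p)
    points = 10.0 ** np.array(log_pts)
    return _assemble_result(points, np.array(accs), np.array(procs), space,
                            scheme, seed_bank, "mcmc")


def robustness_stage(result: PSPResult, config: ModelConfig,
                     stimulus_set: StimulusSet, n_random: int = 200, seed=0,
                     backend: str = "auto") -> pd.DataFrame:
    """Re-test each pattern's representative parameters on fresh seeds.

    Returns one row per discovered pattern with the fixed-bank accuracy
    alongside the mean over ``n_random`` random orderings and weight
    initializations (and the corresponding procedural-control shares).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if result.volumes.empty:
        raise ValueError("partition discovered no patterns")
    roots = as_seed_sequence(seed).spawn(len(result.volumes))
    rows = []
    for (_, rep), root in zip(result.volumes.iterrows(), roots):
        params = {n: rep[n] for n in result.space.names}
        cfg = config_with_params(config, params)
        summary = run_batch(cfg, stimulus_set, seeds=root.spawn(n_random),
                            backend=backend)
        row = {"pattern": rep["pattern"],
               "fixed_accuracy": rep["accuracy"],
               "fixed_proc_control": rep["proc_control"],
               "random_accuracy": summary.mean_test_accuracy,
               "random_proc_control": summary.mean_proc_control,
               "n_random": n_random}
        row.update(params)
        rows.append(row)
    return pd.DataFrame(rows)
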