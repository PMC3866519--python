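"""Post-hoc analyses and shared serialization.

Weight maps visualize what the striatal units learned: each unit's 625
synapses are laid out on the 25x25 sensory lattice and averaged across
simulations.  Ratio maps (A/B and B/A) highlight regions where one
unit's weights were driven toward zero — the signature left by an
explicit rule training the procedural system through its errors.  The
accuracy-takeover correlation quantifies how tightly a model's test
accuracy tracks how often its procedural system controlled responding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import GRID_SCALE, GRID_SIZE, rbf_centers
from .procedural import N_UNITS

__all__ = [
    "WeightMap",
    "RatioMap",
    "average_weight_maps",
    "weight_ratio_map",
    "accuracy_takeover_correlation",
    "unit_stimulus_coords",
    "write_weight_map_csv",
    "read_weight_map_csv",
    "write_json",
    "load_config_file",
]

logger = logging.getLogger("covisim")


def _to_grid(column: np.ndarray) -> np.ndarray:
    """625-vector -> (25, 25) array indexed [x_index, y_index] (lattice
    points 1..25 per axis, matching the sensory-unit ordering)."""
    return np.asarray(column, dtype=float).reshape(GRID_SIZE, GRID_SIZE)


def unit_stimulus_coords() -> np.ndarray:
    """(625, 2) preferred stimuli of the sensory units in stimulus units."""
    return rbf_centers() * GRID_SCALE


@dataclass
class WeightMap:
    """Per-unit 25x25 weight grids, averaged over simulations."""

    w_a: np.ndarray  # (25, 25)
    w_b: np.ndarray  # (25, 25)
    n_simulations: int = 1


@dataclass
class RatioMap:
    """Guarded element-wise weight ratios between the two units."""

    a_over_b: np.ndarray
    b_over_a: np.ndarray
    flagged_a_over_b: np.ndarray  # bool: denominator fell below the guard
    flagged_b_over_a: np.ndarray
    guard: float


def average_weight_maps(weight_arrays) -> WeightMap:
    """Element-wise mean of (625, 2) weight matrices across simulations.

    Accepts a list of matrices or a single (n_sims, 625, 2) stack.
    """
    arr = np.asarray(list(weight_arrays) if not isinstance(weight_arrays,
                                                           np.ndarray)
                     else weight_arrays, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (N_UNITS, 2):
        raise ValueError(f"expected (n, {N_UNITS}, 2) weight arrays")
    mean = arr.mean(axis=0)
    return WeightMap(w_a=_to_grid(mean[:, 0]), w_b=_to_grid(mean[:, 1]),
                     n_simulations=arr.shape[0])


def weight_ratio_map(weight_map: WeightMap, guard: float = 1e-3) -> RatioMap:
    """A/B and B/A ratio grids with a small-denominator guard.

    Denominators below ``guard`` are replaced by it (so ratios stay
    finite and serializable) and the affected cells are flagged.
    """
    if guard <= 0:
        raise ValueError("guard must be positive")
    flag_ab = weight_map.w_b < guard
    flag_ba = weight_map.w_a < guard
    return RatioMap(
        a_over_b=weight_map.w_a / np.maximum(weight_map.w_b, guard),
        b_over_a=weight_map.w_b / np.maximum(weight_map.w_a, guard),
        flagged_a_over_b=flag_ab,
        flagged_b_over_a=flag_ba,
        guard=guard,
    )


def accuracy_takeover_correlation(runs) -> float:
    """Pearson correlation between test accuracy and the number (or
    proportion) of procedural-system-controlled responses across runs.

    ``runs`` is an iterable of (accuracy, n_procedural_controlled) pairs;
    at least three runs with variance in both variables are required.
    """
    arr = np.asarray(list(runs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("runs must be (accuracy, takeover) pairs")
    if len(arr) < 3:
        raise ValueError("need at least 3 runs")
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])


def write_weight_map_csv(weight_map: WeightMap, path) -> None:
    """Write the two 25x25 grids as long-format CSV (one row per cell)."""
    xs, ys = np.meshgrid(np.arange(1, GRID_SIZE + 1),
                         np.arange(1, GRID_SIZE + 1), indexing="ij")
    df = pd.DataFrame({
        "grid_x": np.tile(xs.ravel(), 2),
        "grid_y": np.tile(ys.ravel(), 2),
        "unit": np.repeat(["A", "B"], N_UNITS),
        "weight": np.concatenate([weight_map.w_a.ravel(),
                                  weight_map.w_b.ravel()]),
    })
    df.to_csv(path, index=False)


def read_weight_map_csv(path) -> WeightMap:
    df = pd.read_csv(path)
    grids = {}
    for unit, sub in df.groupby("unit"):
        sub = sub.sort_values(["grid_x", "grid_y"])
        grids[unit] = sub["weight"].to_numpy().reshape(GRID_SIZE, GRID_SIZE)
    return WeightMap(w_a=grids["A"], w_b=grids["B"])


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config_file(path) -> dict:
    """Load an experiment configuration from a JSON or YAML file."""
    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
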