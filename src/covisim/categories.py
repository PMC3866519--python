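"""Category-structure generators and stimulus bookkeeping.

Stimuli are points in a two-dimensional continuous space with arbitrary
units on ``[0, 100]`` per dimension (think sine-wave disks varying in bar
orientation and spatial frequency).  Three structures are provided:

* **II** (information-integration): two overlapping bivariate normal
  categories whose optimal bound is the main diagonal, so accurate
  responding requires pre-decisional integration of both dimensions.
* **RB** (rule-based): the II sample rotated 45 degrees counter-clockwise
  about the center of the space, which makes the optimal bound a vertical
  line (a verbalizable single-dimension rule).
* **Hybrid**: a piecewise bound — a vertical criterion on the upper half
  of the space and the main diagonal on the lower half — so neither a 1D
  rule nor a single linear integration strategy is optimal everywhere.

The procedural network's sensory layer lives on a 25x25 grid, so stimulus
coordinates are mapped to "grid units" by dividing by 4 (:func:`to_grid_coords`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GRID_SIZE",
    "STIM_MAX",
    "GRID_SCALE",
    "LABEL_NAMES",
    "CategoryParams",
    "StimulusSet",
    "TrialSequence",
    "II_PARAMS",
    "gen_ii_categories",
    "gen_rb_categories",
    "gen_hybrid_categories",
    "hybrid_label",
    "hybrid_rule_accuracy_uniform",
    "rotate_about_center",
    "make_trial_sequence",
    "to_grid_coords",
    "rbf_centers",
    "write_stimulus_csv",
    "read_stimulus_csv",
]

GRID_SIZE = 25
STIM_MAX = 100.0
#: stimulus units per grid unit (100 / 25)
GRID_SCALE = STIM_MAX / GRID_SIZE

LABEL_NAMES = ("A", "B")


@dataclass(frozen=True)
class CategoryParams:
    """Bivariate-normal parameters for one pair of categories.

    Both categories share the same (isotropic-variance) covariance matrix;
    only the means differ.
    """

    mean_a: tuple[float, float]
    mean_b: tuple[float, float]
    variance: float
    covariance: float

    def __post_init__(self) -> None:
        det = self.variance * self.variance - self.covariance**2
        if det <= 0:
            raise ValueError(
                f"covariance matrix not positive definite "
                f"(sigma^2={self.variance}, cov={self.covariance})"
            )

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.array(
            [[self.variance, self.covariance], [self.covariance, self.variance]]
        )


#: Default II category parameters: A centered at (40, 60), B at (60, 40),
#: common variance 167.59 and covariance 151.26, so the categories stretch
#: along the main diagonal and the optimal bound is y = x.
II_PARAMS = CategoryParams(mean_a=(40.0, 60.0), mean_b=(60.0, 40.0),
                           variance=167.59, covariance=151.26)


@dataclass
class StimulusSet:
    """Labeled 2-D stimuli for one category structure.

    ``labels`` are integer codes (0 = "A", 1 = "B"); ``LABEL_NAMES`` maps
    codes to names.  Stimuli are stored category-A block first.
    """

    stimuli: np.ndarray  # (n, 2) float
    labels: np.ndarray  # (n,) int in {0, 1}
    structure_kind: str  # "II" | "RB" | "HYBRID"
    bound_spec: str
    n_per_category: int

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.stimuli.ndim != 2 or self.stimuli.shape[1] != 2:
            raise ValueError("stimuli must be an (n, 2) array")
        if len(self.labels) != len(self.stimuli):
            raise ValueError("labels and stimuli length mismatch")
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] != self.n_per_category or counts[1] != self.n_per_category:
            raise ValueError("labels not balanced at n_per_category each")
        if not np.isfinite(self.stimuli).all():
            raise ValueError("non-finite stimulus coordinates")
        if self.stimuli.min() < 0 or self.stimuli.max() > STIM_MAX:
            raise ValueError("stimulus coordinates outside [0, 100]")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def label_names(self) -> np.ndarray:
        return np.asarray(LABEL_NAMES)[self.labels]


@dataclass(frozen=True)
class TrialSequence:
    """Concatenation of per-epoch permutations of all stimulus indices."""

    ordering: np.ndarray  # (epochs * n,) int
    seed: object
    epochs: int = 1

    def __len__(self) -> int:
        return len(self.ordering)


def _sample_in_square(rng: np.random.Generator, mean, cov, n: int,
                      transform=None) -> np.ndarray:
    """Rejection-sample ``n`` bivariate-normal points that land in [0,100]^2.

    ``transform`` (optional) is applied to candidate points and the
    *transformed* points must also be in range; the transformed points are
    returned.  Out-of-range candidates are resampled, not clipped, so the
    in-square distribution keeps the stated normal shape.
    """
    out = np.empty((n, 2))
    got = 0
    while got < n:
        batch = rng.multivariate_normal(mean, cov, size=max(2 * (n - got), 16),
                                        method="cholesky")
        ok = ((batch >= 0) & (batch <= STIM_MAX)).all(axis=1)
        cand = batch
        if transform is not None:
            cand = transform(batch)
            ok &= ((cand >= 0) & (cand <= STIM_MAX)).all(axis=1)
        cand = cand[ok]
        take = min(len(cand), n - got)
        out[got:got + take] = cand[:take]
        got += take
    return out


def gen_ii_categories(params: CategoryParams = II_PARAMS, n_per_cat: int = 300,
                      seed=0) -> StimulusSet:
    """Draw ``n_per_cat`` stimuli per category from the two bivariate normals."""
    if n_per_cat < 1:
        raise ValueError("n_per_cat must be >= 1")
    rng = np.random.default_rng(seed)
    a = _sample_in_square(rng, params.mean_a, params.cov_matrix, n_per_cat)
    b = _sample_in_square(rng, params.mean_b, params.cov_matrix, n_per_cat)
    return StimulusSet(
        stimuli=np.vstack([a, b]),
        labels=np.repeat([0, 1], n_per_cat),
        structure_kind="II",
        bound_spec="optimal linear bound y = x (diagonal)",
        n_per_category=n_per_cat,
    )


def rotate_about_center(points: np.ndarray, degrees: float = 45.0) -> np.ndarray:
    """Rotate points counter-clockwise about the center of the space (50, 50)."""
    theta = np.deg2rad(degrees)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    center = np.array([STIM_MAX / 2, STIM_MAX / 2])
    return (np.asarray(points, dtype=float) - center) @ rot.T + center


def gen_rb_categories(params: CategoryParams = II_PARAMS, n_per_cat: int = 300,
                      seed=0) -> StimulusSet:
    """II sample rotated 45 degrees counter-clockwise about (50, 50).

    The rotation turns the diagonal optimal bound into the vertical line
    x = 50, i.e. a one-dimensional rule.  Candidate draws whose original or
    rotated coordinates fall outside the stimulus square are resampled.
    """
    if n_per_cat < 1:
        raise ValueError("n_per_cat must be >= 1")
    rng = np.random.default_rng(seed)
    a = _sample_in_square(rng, params.mean_a, params.cov_matrix, n_per_cat,
                          transform=rotate_about_center)
    b = _sample_in_square(rng, params.mean_b, params.cov_matrix, n_per_cat,
                          transform=rotate_about_center)
    return StimulusSet(
        stimuli=np.vstack([a, b]),
        labels=np.repeat([0, 1], n_per_cat),
        structure_kind="RB",
        bound_spec="optimal vertical bound x = 50 (rotated II)",
        n_per_category=n_per_cat,
    )


def hybrid_label(x, y):
    """Label points against the piecewise hybrid bound.

    The bound is the vertical segment x = 50 for y >= 50 and the diagonal
    y = x for y < 50.  Category A is the left/upper region.  Returns 0 (A),
    1 (B), or -1 for points exactly on the bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    upper = y >= 50.0
    side = np.where(upper, x - 50.0, x - y)  # negative -> A side
    lab = np.where(side < 0, 0, np.where(side > 0, 1, -1))
    if lab.ndim == 0:
        return int(lab)
    return lab


def gen_hybrid_categories(n_per_cat: int = 300, seed=0) -> StimulusSet:
    """Uniform samples from each side of the piecewise hybrid bound.

    Each category's stimuli are uniform over that category's region of the
    square (rejection-sampled); points exactly on the bound are resampled,
    so every stimulus lies strictly on its own side.
    """
    if n_per_cat < 1:
        raise ValueError("n_per_cat must be >= 1")
    rng = np.random.default_rng(seed)

    def sample_region(want_label: int) -> np.ndarray:
        out = np.empty((n_per_cat, 2))
        got = 0
        while got < n_per_cat:
            cand = rng.uniform(0.0, STIM_MAX, size=(4 * (n_per_cat - got), 2))
            lab = hybrid_label(cand[:, 0], cand[:, 1])
            cand = cand[lab == want_label]
            take = min(len(cand), n_per_cat - got)
            out[got:got + take] = cand[:take]
            got += take
        return out

    return StimulusSet(
        stimuli=np.vstack([sample_region(0), sample_region(1)]),
        labels=np.repeat([0, 1], n_per_cat),
        structure_kind="HYBRID",
        bound_spec="piecewise: x = 50 for y >= 50, y = x for y < 50; A left/upper",
        n_per_category=n_per_cat,
    )


def hybrid_rule_accuracy_uniform(criterion: float = 50.0) -> float:
    """Accuracy of the 1D rule ``respond A iff x < criterion`` under the
    uniform measure on the whole square (closed-form area computation).

    Note the category *regions* have unequal area (A: 3750, B: 6250 of
    10000), so this population figure differs from the accuracy of the same
    rule on a balanced per-category sample.  At criterion 50 the value is
    0.875.
    """
    c = float(criterion)
    if not 0.0 <= c <= STIM_MAX:
        raise ValueError("criterion outside stimulus range")
    cl = min(c, 50.0)
    # A = {y >= 50, x < 50} u {y < 50, x < y}; area(A) = 2500 + 1250 = 3750.
    # area(A and x < c): upper rectangle part + lower triangle part.
    a_upper = 50.0 * cl
    a_lower = 1250.0 if c >= 50.0 else 50.0 * c - 0.5 * c**2
    a_correct = a_upper + a_lower
    # B is the complement; area(B) = 6250.  area(B and x < c):
    b_upper = 50.0 * max(c - 50.0, 0.0)
    b_lower = 0.5 * cl**2 + 50.0 * max(c - 50.0, 0.0)
    b_correct = 6250.0 - (b_upper + b_lower)
    return (a_correct + b_correct) / STIM_MAX**2


def make_trial_sequence(stimulus_set: StimulusSet, epochs: int = 1,
                        seed=0) -> TrialSequence:
    """Concatenate ``epochs`` independent random permutations of the set."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n = stimulus_set.n
    if n == 0:
        raise ValueError("empty stimulus set")
    rng = np.random.default_rng(seed)
    ordering = np.concatenate([rng.permutation(n) for _ in range(epochs)])
    return TrialSequence(ordering=ordering, seed=seed, epochs=epochs)


def to_grid_coords(points):
    """Map stimulus coordinates in [0, 100] to grid units in [0, 25].

    The sensory layer's radial-basis distances are measured in these units.
    """
    pts = np.asarray(points, dtype=float)
    if pts.min() < 0 or pts.max() > STIM_MAX:
        raise ValueError("stimulus coordinates outside [0, 100]")
    return pts / GRID_SCALE


def rbf_centers() -> np.ndarray:
    """Preferred stimuli of the 625 sensory units: the integer lattice
    1..25 x 1..25 in grid units, x-major (unit K = ix * 25 + iy for
    0-based ix, iy)."""
    axis = np.arange(1, GRID_SIZE + 1, dtype=float)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def write_stimulus_csv(stimulus_set: StimulusSet, path) -> None:
    df = pd.DataFrame({
        "x": stimulus_set.stimuli[:, 0],
        "y": stimulus_set.stimuli[:, 1],
        "category": stimulus_set.label_names,
    })
    df.to_csv(path, index=False)


def read_stimulus_csv(path, structure_kind: str = "II",
                      bound_spec: str = "") -> StimulusSet:
    df = pd.read_csv(path)
    labels = np.where(df["category"].to_numpy() == "A", 0, 1)
    n_a = int((labels == 0).sum())
    return StimulusSet(
        stimuli=df[["x", "y"]].to_numpy(),
        labels=labels,
        structure_kind=structure_kind,
        bound_spec=bound_spec,
        n_per_category=n_a,
    )
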