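import numpy as np
import pandas as pd
import pytest

from covisim.arbitration import ModelConfig
from covisim.procedural import LearningParams
from covisim.psp import (DECILE_LABELS, ParameterSpace, accuracy_to_pattern,
                         config_with_params, grid_partition, mcmc_partition,
                         pattern_labels, robustness_stage)


class TestPatternAssignment:
    @pytest.mark.parametrize("acc,expect", [
        (0.95, "90-100"), (0.90, "90-100"), (1.0, "90-100"),
        (0.899999, "80-89"), (0.0, "0-9"), (0.45, "40-49")])
    def test_decile_boundaries(self, acc, expect):
        assert accuracy_to_pattern(acc) == expect

    def test_top_decile_is_the_tenth_pattern(self):
        assert DECILE_LABELS.index(accuracy_to_pattern(0.95)) == 9

    @pytest.mark.parametrize("acc,expect", [
        (0.63, "60-64"), (0.65, "65-69"), (0.6, "60-64"), (0.70, "70-79")])
    def test_split_sixties_scheme(self, acc, expect):
        assert accuracy_to_pattern(acc, "deciles_split_60s") == expect

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            accuracy_to_pattern(1.2)
        with pytest.raises(ValueError):
            accuracy_to_pattern(0.5, "quartiles")
        with pytest.raises(ValueError):
            pattern_labels("quartiles")


class TestParameterSpace:
    def test_three_axes_for_independent_and_hard_switch_models(self):
        assert ParameterSpace.for_config(ModelConfig.model0()).names == \
            ("alpha_pr", "alpha", "beta")
        assert ParameterSpace.for_config(ModelConfig.model1()).ndim == 3

    def test_five_axes_for_soft_switch_single_feedback(self):
        space = ParameterSpace.for_config(ModelConfig.model2())
        assert space.names == ("alpha_pr", "alpha", "beta", "delta_oc",
                               "delta_oe")

    def test_grid_axes_are_log_spaced_over_the_search_ranges(self):
        space = ParameterSpace.for_config(ModelConfig.model0())
        axes = space.grid_axes(8)
        assert axes[0][0] == pytest.approx(0.005)
        assert axes[0][-1] == pytest.approx(1.0)
        ratios = axes[1][1:] / axes[1][:-1]
        assert np.allclose(ratios, ratios[0])

    def test_config_with_params_substitutes_free_parameters(self):
        cfg = config_with_params(ModelConfig.model2(),
                                 {"alpha": 0.5, "beta": 0.25,
                                  "alpha_pr": 0.1, "delta_oc": 0.002,
                                  "delta_oe": 0.15})
        assert cfg.learning.alpha == 0.5
        assert cfg.learning.beta == 0.25
        assert cfg.alpha_pr == 0.1
        assert cfg.delta_oc == 0.002
        assert cfg.delta_oe == 0.15


def _surface(points: np.ndarray):
    """Synthetic accuracy surface: rises with log(alpha), independent of
    the other axes; no takeover."""
    acc = 0.45 + 0.5 * (np.log10(points[:, 1]) + 3) / 3
    return np.clip(acc, 0.0, 1.0), np.zeros(len(points))


class TestGridPartition:
    def test_partition_is_disjoint_and_volumes_sum_to_one(self):
        res = grid_partition(ModelConfig.model0(), points_per_axis=6,
                             evaluate=_surface)
        assert len(res.points) == 6**3
        assert res.volumes["volume_fraction"].sum() == pytest.approx(1.0)
        assert res.points["pattern"].notna().all()
        # every point maps to exactly one pattern and the volume table
        # matches the point counts
        counts = res.points["pattern"].value_counts()
        for _, row in res.volumes.iterrows():
            assert counts[row["pattern"]] == row["n_points"]

    def test_representative_belongs_to_its_pattern(self):
        res = grid_partition(ModelConfig.model0(), points_per_axis=5,
                             evaluate=_surface)
        for _, row in res.volumes.iterrows():
            rep = res.representative(row["pattern"])
            acc, _ = _surface(np.array([[rep[n] for n in res.space.names]]))
            assert accuracy_to_pattern(acc[0]) == row["pattern"]

    def test_real_simulation_slice_near_zero_rates_never_learns(self, ii_set):
        """With both learning rates pinned at their floor the procedural
        system cannot reach high accuracy anywhere on the alpha_pr axis."""
        space = ParameterSpace(axes=(("alpha_pr", (0.005, 1.0)),))
        cfg = ModelConfig.model0(
            learning=LearningParams(alpha=0.001, beta=0.001), epochs=1)
        res = grid_partition(cfg, space=space, points_per_axis=4,
                             stimulus_set=ii_set, seed_bank=(1, 2, 3))
        assert (res.points["accuracy"] < 0.9).all()


class TestMCMCPartition:
    def test_constant_surface_yields_single_full_volume_pattern(self):
        res = mcmc_partition(ModelConfig.model0(), n_cycles=2, seed=0,
                             evaluate=lambda p: (np.full(len(np.atleast_2d(p)),
                                                         0.95),
                                                 np.zeros(len(np.atleast_2d(p)))))
        assert len(res.volumes) == 1
        assert res.volumes.iloc[0]["pattern"] == "90-100"
        assert res.volumes.iloc[0]["volume_fraction"] == pytest.approx(1.0)

    def test_same_seed_reproduces_the_search(self):
        r1 = mcmc_partition(ModelConfig.model0(), n_cycles=3, seed=5,
                            evaluate=_surface)
        r2 = mcmc_partition(ModelConfig.model0(), n_cycles=3, seed=5,
                            evaluate=_surface)
        assert r1.points.equals(r2.points)

    def test_agrees_with_grid_on_a_two_axis_slice(self):
        space = ParameterSpace(axes=(("alpha_pr", (0.005, 1.0)),
                                     ("alpha", (0.001, 1.0))))
        grid = grid_partition(ModelConfig.model0(), space=space,
                              points_per_axis=12, evaluate=_surface)
        mc = mcmc_partition(ModelConfig.model0(), space=space, n_cycles=6,
                            steps_per_chain=40, seed=1, evaluate=_surface)
        gv = grid.volumes.set_index("pattern")["volume_fraction"]
        mv = mc.volumes.set_index("pattern")["volume_fraction"]
        for pattern in gv.index:
            assert abs(gv[pattern] - mv.get(pattern, 0.0)) < 0.15

    def test_invalid_cycle_count_rejected(self):
        with pytest.raises(ValueError):
            mcmc_partition(ModelConfig.model0(), n_cycles=0,
                           evaluate=_surface)


class TestRobustnessStage:
    def test_zero_random_runs_rejected(self, ii_set):
        res = grid_partition(ModelConfig.model0(), points_per_axis=4,
                             evaluate=_surface)
        with pytest.raises(ValueError):
            robustness_stage(res, ModelConfig.model0(), ii_set, n_random=0)

    def test_model0_patterns_replicate_on_fresh_seeds(self, ii_set):
        """Independent-feedback learning is robust: random-bank accuracy
        for the high pattern matches the fixed-bank value."""
        space = ParameterSpace(axes=(("alpha", (0.01, 0.5)),))
        cfg = ModelConfig.model0(epochs=2)
        res = grid_partition(cfg, space=space, points_per_axis=3,
                             stimulus_set=ii_set, seed_bank=(1, 2, 3, 4, 5))
        table = robustness_stage(res, cfg, ii_set, n_random=20, seed=0)
        top = table.iloc[-1]
        assert top["fixed_accuracy"] >= 0.9
        assert abs(top["random_accuracy"] - top["fixed_accuracy"]) < 0.04
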