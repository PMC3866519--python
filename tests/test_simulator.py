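import dataclasses

import numpy as np
import pytest

from covisim.analysis import unit_stimulus_coords
from covisim.arbitration import ModelConfig
from covisim.categories import StimulusSet
from covisim.engine import HAVE_NUMBA
from covisim.explicit import explicit_response
from covisim.procedural import N_UNITS, LearningParams
from covisim.simulator import (SEED_BANK_19, rb_takeover_experiment,
                               run_batch, run_test, run_training)

FAST = dict(epochs=1)


class TestRunTraining:
    def test_reproducible_trial_logs(self, ii_set):
        cfg = ModelConfig.model0(**FAST)
        r1 = run_training(cfg, ii_set, seed=5)
        r2 = run_training(cfg, ii_set, seed=5)
        assert r1.trial_log.equals(r2.trial_log)
        assert np.array_equal(r1.final_weights, r2.final_weights)

    def test_correct_flag_matches_emitted_vs_truth(self, ii_set):
        log = run_training(ModelConfig.model0(**FAST), ii_set, seed=1
                           ).trial_log
        assert (log["correct"] ==
                (log["emitted_label"] == log["true_label"])).all()

    def test_no_learning_null_with_zero_rates(self, ii_set):
        cfg = ModelConfig.model0(
            learning=LearningParams(alpha=0.0, beta=0.0, gamma=0.0), **FAST)
        res = run_training(cfg, ii_set, seed=2)
        from covisim.simulator import _run_streams
        from covisim.procedural import init_weights

        w_ss, _, _ = _run_streams(2)
        assert np.array_equal(res.final_weights, init_weights(w_ss).weights)
        assert res.test_accuracy == run_test(res.final_weights, ii_set)

    def test_hard_mode_emits_explicit_response_every_trial(self, ii_set):
        cfg = ModelConfig.model1(**FAST)
        log = run_training(cfg, ii_set, seed=3).trial_log
        assert (log["controller"] == "explicit").all()
        assert (log["emitted_label"] == log["explicit_label"]).all()

    def test_dopamine_and_trust_columns_stay_in_range(self, ii_set):
        log = run_training(ModelConfig.model2(**FAST), ii_set, seed=4
                           ).trial_log
        assert log["D"].between(0, 1).all()
        assert log["theta_E"].between(0, 1).all()
        assert np.allclose(log["RPE"], log["R"] - log["P"])


class TestEngineAgreement:
    @pytest.mark.parametrize("make_cfg", [
        lambda: ModelConfig.model0(epochs=2),
        lambda: ModelConfig.model1(epochs=2),
        lambda: ModelConfig.model2(epochs=2, delta_oe=0.1),
        lambda: ModelConfig.model1(bootstrap=True, epochs=2),
        lambda: ModelConfig.model2(bootstrap=True, epochs=2),
        lambda: ModelConfig.model2(epochs=2, explicit_accuracy=0.9),
    ])
    def test_batch_engine_reproduces_reference_loop(self, ii_set, make_cfg):
        """The vectorized engine and the readable per-trial loop implement
        the same model: same seed, same final weights and summaries."""
        cfg = make_cfg()
        single = run_training(cfg, ii_set, seed=7)
        batch = run_batch(cfg, ii_set, seeds=[7], return_weights=True,
                          backend="numpy")
        assert batch.test_accuracy[0] == pytest.approx(single.test_accuracy)
        assert batch.train_accuracy[0] == pytest.approx(
            single.training_accuracy)
        assert batch.proc_control_prop[0] == pytest.approx(
            single.proc_control_prop)
        assert np.allclose(batch.final_weights[0], single.final_weights,
                           atol=1e-10)

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_backends_agree(self, ii_set):
        cfg = ModelConfig.model2(epochs=2, bootstrap=True)
        a = run_batch(cfg, ii_set, seeds=[1, 2, 3], return_weights=True,
                      backend="numpy")
        b = run_batch(cfg, ii_set, seeds=[1, 2, 3], return_weights=True,
                      backend="numba")
        assert np.allclose(a.final_weights, b.final_weights, atol=1e-10)
        assert np.array_equal(a.test_accuracy, b.test_accuracy)


class TestRunTest:
    def test_zero_weights_tie_everywhere_gives_chance(self, ii_set):
        assert run_test(np.zeros((N_UNITS, 2)), ii_set) == 0.5

    def test_ideal_indicator_weights_classify_separable_toys(
            self, toy_separable):
        coords = unit_stimulus_coords()
        w = np.zeros((N_UNITS, 2))
        w[coords[:, 0] < 50, 0] = 1.0
        w[coords[:, 0] >= 50, 1] = 1.0
        assert run_test(w, toy_separable) == 1.0

    def test_accuracy_invariant_to_stimulus_order(self, ii_set):
        w = np.random.default_rng(0).uniform(0, 1, (N_UNITS, 2))
        perm = np.random.default_rng(1).permutation(ii_set.n)
        shuffled = StimulusSet(
            stimuli=ii_set.stimuli[perm], labels=ii_set.labels[perm],
            structure_kind=ii_set.structure_kind,
            bound_spec=ii_set.bound_spec,
            n_per_category=ii_set.n_per_category)
        assert run_test(w, ii_set) == run_test(w, shuffled)


class TestRunBatch:
    def test_identical_seeds_give_zero_dispersion(self, ii_set):
        s = run_batch(ModelConfig.model0(**FAST), ii_set, seeds=[5, 5, 5])
        assert s.sd_test_accuracy == 0.0

    def test_model0_learns_well_above_chance(self, ii_set):
        """Independent-feedback learning on II categories over 20 seeds."""
        s = run_batch(ModelConfig.model0(epochs=2), ii_set,
                      seeds=list(range(20)))
        assert s.mean_test_accuracy > 0.9
        assert (s.test_accuracy > 0.6).all()

    def test_bootstrap_dominates_plain_hard_switch_paired(self, ii_set):
        """With identical seeds and parameters, injecting the explicit
        response never hurts the never-switching single-feedback model."""
        seeds = list(range(10))
        for alpha, beta, apr in [(0.03, 0.03, 0.07), (0.3, 0.01, 0.3),
                                 (0.005, 0.2, 0.02)]:
            lp = LearningParams(alpha=alpha, beta=beta)
            plain = run_batch(ModelConfig.model1(learning=lp, alpha_pr=apr,
                                                 epochs=2), ii_set, seeds)
            boot = run_batch(ModelConfig.model1(bootstrap=True, learning=lp,
                                                alpha_pr=apr, epochs=2),
                             ii_set, seeds)
            assert boot.mean_test_accuracy >= plain.mean_test_accuracy

    def test_no_midsession_accuracy_collapse(self, ii_set):
        """Block accuracy never falls off a cliff (>70% to <=55% between
        consecutive 50-trial blocks) in bootstrapped runs or under
        independent feedback: the procedural system is already trained by
        the time it takes control.  (The plain single-feedback soft
        switcher *does* collapse when trust decays before the procedural
        system has learned — the discontinuity that rules it out as an
        account of human learning curves.)"""
        for cfg in (ModelConfig.model2(bootstrap=True, epochs=2,
                                       delta_oe=0.05),
                    ModelConfig.model1(bootstrap=True, epochs=2),
                    ModelConfig.model0(epochs=2)):
            for seed in (1, 2, 3):
                log = run_training(cfg, ii_set, seed=seed).trial_log
                acc = log["correct"].to_numpy()
                blocks = acc[:len(acc) // 50 * 50].reshape(-1, 50).mean(1)
                drops = (blocks[:-1] > 0.70) & (blocks[1:] <= 0.55)
                assert not drops.any()


class TestBootstrappedWeightGeometry:
    def test_explicit_errors_carve_out_the_a_unit_weights(self, ii_set):
        """After bootstrapped never-switch training on II categories, the
        A-unit weights where the explicit rule answers A *incorrectly*
        (true category B) are driven toward zero relative to the region
        where its A answers are correct."""
        cfg = ModelConfig.model1(bootstrap=True, epochs=4)
        batch = run_batch(cfg, ii_set, seeds=list(range(20)),
                          return_weights=True)
        mean_w = batch.final_weights.mean(axis=0)  # (625, 2)
        coords = unit_stimulus_coords()
        exp_lab, _ = explicit_response(batch.rule, coords)
        true_a = coords[:, 1] > coords[:, 0]  # above the diagonal bound
        margin = np.abs(coords[:, 1] - coords[:, 0]) > 8  # off the bound
        wrong_a = (exp_lab == 0) & ~true_a & margin
        right_a = (exp_lab == 0) & true_a & margin
        assert wrong_a.sum() > 10 and right_a.sum() > 10
        assert mean_w[wrong_a, 0].mean() < 0.25 * mean_w[right_a, 0].mean()


class TestRBTakeover:
    def test_takeover_shrinks_as_explicit_accuracy_rises(self):
        from covisim.categories import gen_rb_categories

        rb = gen_rb_categories(seed=11)
        cfg = ModelConfig.model2(epochs=2, delta_oe=0.05,
                                 learning=LearningParams(alpha=0.05,
                                                         beta=0.05))
        props = rb_takeover_experiment(cfg, rb, accuracies=(0.9, 0.95, 1.0),
                                       n_sims=25, seed=0)
        vals = [props[a] for a in (0.9, 0.95, 1.0)]
        assert vals[0] >= vals[1] >= vals[2]
        assert props[1.0] == 0.0

    def test_wrong_architecture_rejected(self, ii_set):
        with pytest.raises(ValueError):
            rb_takeover_experiment(ModelConfig.model1(), ii_set)
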