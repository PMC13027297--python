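"""Loss/schedule closed forms, early stopping, fold bookkeeping and the
ablation harness structure."""

import numpy as np
import pytest

from aphidgrade.fusion import assemble, tiny_config
from aphidgrade.gan import GanConfig
from aphidgrade.nn import Tensor
from aphidgrade.nn.optim import cosine_lr
from aphidgrade.training import (ABLATION_ROWS, TrainConfig, evaluate,
                                 fold_indices, holdout_split,
                                 label_smoothing_loss, prepare_inputs,
                                 run_ablation, smoothed_cross_entropy, train)


def _tiny_dataset(n=40, side=64, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.random((n, side, side, 3)).astype(np.float32)
    labels = np.arange(n) % 4
    return images, labels


class TestLossClosedForms:
    def test_uniform_prediction_gives_ln4(self):
        for eps in (0.0, 0.1, 0.5):
            val = smoothed_cross_entropy([0.25] * 4, label=2, epsilon=eps)
            assert val == pytest.approx(np.log(4.0), abs=1e-12)

    def test_confident_correct_with_no_smoothing_is_zero(self):
        assert smoothed_cross_entropy([1.0, 0.0, 0.0, 0.0], 0,
                                      epsilon=0.0) == pytest.approx(0.0)

    def test_printed_worked_example(self):
        val = smoothed_cross_entropy([0.7, 0.1, 0.1, 0.1], 0, epsilon=0.1)
        # -(0.925 ln 0.7 + 0.025 * 3 * ln 0.1)
        assert val == pytest.approx(0.5026, abs=5e-5)

    def test_tensor_loss_agrees_with_scalar_form(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(6, 4)).astype(np.float32)
        labels = np.array([0, 1, 2, 3, 1, 2])
        t = label_smoothing_loss(Tensor(logits), labels, 0.1)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        expect = np.mean([smoothed_cross_entropy(p, y, 0.1)
                          for p, y in zip(probs, labels)])
        assert float(t.data) == pytest.approx(expect, abs=1e-5)


class TestCosineSchedule:
    def test_endpoints(self):
        assert cosine_lr(0, 100, 1e-3, 1e-6) == pytest.approx(1e-3)
        assert cosine_lr(99, 100, 1e-3, 1e-6) == pytest.approx(1e-6)

    def test_midpoint_of_101_epochs(self):
        lr = cosine_lr(50, 101, 1e-3, 1e-6)
        assert lr == pytest.approx((1e-3 + 1e-6) / 2, rel=1e-9)

    def test_monotone_decrease(self):
        lrs = [cosine_lr(e, 50, 1e-3, 1e-6) for e in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(100, 100, 1e-3, 1e-6)


class TestTrainLoop:
    def test_early_stop_after_patience_without_improvement(self, monkeypatch):
        """A validation schedule that never improves after the first epoch
        stops training at exactly 1 + patience epochs."""
        import aphidgrade.training as T
        flat = iter([1.0] + [1.0] * 200)  # constant: no strict decrease
        monkeypatch.setattr(
            T, "evaluate",
            lambda model, xl, xg, y, cfg: (next(flat), 0.25,
                                           np.zeros(len(y), np.int64)))
        images, labels = _tiny_dataset(24)
        model = assemble(tiny_config(), seed=0)
        xl, xg, y = prepare_inputs(model, images, labels)
        cfg = TrainConfig(epochs=100, patience=10, ema_decay=0.0,
                          augment=False, seed=0)
        history, _ = train(model, (xl[:16], xg[:16], y[:16]),
                           (xl[16:], xg[16:], y[16:]), cfg)
        assert history.stop_epoch == 1 + cfg.patience == 11
        assert history.best_epoch == 0

    def test_history_bounded_by_epoch_cap(self):
        images, labels = _tiny_dataset(24)
        model = assemble(tiny_config(), seed=0)
        xl, xg, y = prepare_inputs(model, images, labels)
        cfg = TrainConfig(epochs=2, seed=0)
        history, _ = train(model, (xl[:16], xg[:16], y[:16]),
                           (xl[16:], xg[16:], y[16:]), cfg)
        assert history.stop_epoch <= 2
        assert len(history.val_loss) == history.stop_epoch
        # best epoch has the minimal validation loss seen
        assert history.val_loss[history.best_epoch] == min(history.val_loss)

    def test_bit_identical_training_for_fixed_seed(self):
        images, labels = _tiny_dataset(40)
        finals = []
        for _ in range(2):
            model = assemble(tiny_config(), seed=3)
            xl, xg, y = prepare_inputs(model, images, labels)
            cfg = TrainConfig(epochs=2, seed=3)
            history, _ = train(model, (xl[:32], xg[:32], y[:32]),
                               (xl[32:], xg[32:], y[32:]), cfg)
            finals.append((history.train_loss[-1], history.val_loss[-1]))
        assert finals[0] == finals[1]

    def test_empty_split_rejected(self):
        images, labels = _tiny_dataset(8)
        model = assemble(tiny_config(), seed=0)
        xl, xg, y = prepare_inputs(model, images, labels)
        with pytest.raises(ValueError):
            train(model, (xl, xg, y), (xl[:0], xg[:0], y[:0]),
                  TrainConfig(epochs=1))


class TestSplits:
    def test_holdout_is_stratified(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        tr, va = holdout_split(labels, 0.2, seed=0)
        assert len(va) == 20 and len(tr) == 80
        assert sorted(np.bincount(labels[va])) == [5, 5, 5, 5]
        assert set(tr) | set(va) == set(range(100))
        assert set(tr) & set(va) == set()

    def test_five_folds_partition_dataset(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        folds = fold_indices(labels, folds=5, seed=1)
        seen = []
        for tr, va in folds:
            assert len(va) == 20
            assert set(tr) & set(va) == set()
            # stratification: per-fold class counts within 1 of n_class/5
            counts = np.bincount(labels[va], minlength=4)
            assert np.all(np.abs(counts - 5) <= 1)
            seen += va.tolist()
        assert sorted(seen) == list(range(100))  # validated exactly once

    def test_fold_assignment_deterministic(self):
        labels = np.repeat([0, 1, 2, 3], 10)
        a = fold_indices(labels, 5, seed=7)
        b = fold_indices(labels, 5, seed=7)
        for (t1, v1), (t2, v2) in zip(a, b):
            assert np.array_equal(v1, v2)

    def test_too_small_class_rejected(self):
        labels = np.array([0, 0, 0, 1, 2, 3, 1, 2, 3, 1, 2, 3])
        with pytest.raises(ValueError):
            fold_indices(labels, folds=5, seed=0)


class TestAblationHarness:
    @pytest.fixture(scope="class")
    def table(self):
        images, labels = _tiny_dataset(40, seed=5)
        cfg = TrainConfig(epochs=1, seed=0, ema_decay=0.0, augment=False)
        gan_cfg = GanConfig(image_side=32, epochs=1, batch_size=4, seed=0)
        return run_ablation(images, labels, tiny_config(), cfg,
                            gan_cfg=gan_cfg)

    def test_full_sweep_emits_seven_rows(self, table):
        assert len(table) == 7
        assert len(set(table["configuration"])) == 7

    def test_component_columns_cover_design(self, table):
        combos = set(zip(table["data_augmentation"], table["architecture"],
                         table["attention"]))
        assert ("-", "single-branch", "-") in combos          # baseline
        assert ("GAN", "hybrid", "GCSA") in combos            # full model
        assert ("GAN", "hybrid", "-") not in combos           # not studied

    def test_metric_columns_present(self, table):
        for col in ("accuracy_pct", "precision_pct", "recall_pct", "f1_pct"):
            assert col in table.columns
            assert table[col].between(0, 100).all()

    def test_all_off_toggles_run_baseline_only(self):
        images, labels = _tiny_dataset(40, seed=6)
        cfg = TrainConfig(epochs=1, seed=0, ema_decay=0.0, augment=False)
        table = run_ablation(images, labels, tiny_config(), cfg, toggles=set())
        assert list(table["configuration"]) == ["baseline"]

    def test_unknown_toggle_rejected(self):
        images, labels = _tiny_dataset(8)
        with pytest.raises(ValueError):
            run_ablation(images, labels, tiny_config(),
                         TrainConfig(epochs=1), toggles={"dropout"})
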