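"""Losses, schedules, cross-batch memory, early stopping, training loops."""

import math

import numpy as np
import pytest

from cxreid import nn
from cxreid.cohort import patient_wise_split
from cxreid.nn import Tensor
from cxreid.nn import tensor as F
from cxreid.pairs import MiningConfig
from cxreid.training import (EarlyStopping, TrainConfig, XBMemory, bce_loss,
                             contrastive_loss, desk_scale_config, lr_range_test,
                             one_cycle_lr, train_retriever, train_verifier)


class TestBceLoss:
    @pytest.mark.parametrize("p,y,expected", [
        (0.5, 1, math.log(2)),
        (0.5, 0, math.log(2)),
        (0.9, 0, -math.log(0.1)),
        (0.9, 1, -math.log(0.9)),
    ])
    def test_matches_closed_form(self, p, y, expected):
        assert bce_loss(np.array([p]), np.array([y])).item() == pytest.approx(
            expected, abs=1e-12)

    def test_perfect_prediction_tends_to_zero(self):
        assert bce_loss(np.array([1.0 - 1e-9]), np.array([1])).item() < 1e-8

    def test_grid_matches_analytic_formula(self):
        ps = np.linspace(0.05, 0.95, 19)
        for y in (0, 1):
            got = np.array([bce_loss([p], [y]).item() for p in ps])
            want = -(y * np.log(ps) + (1 - y) * np.log(1 - ps))
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestContrastiveLoss:
    def test_identical_positives_cost_zero(self):
        z = np.ones((1, 128))
        assert contrastive_loss(z, z, [1]).item() == 0.0

    def test_negatives_beyond_margin_cost_zero(self):
        z1 = np.zeros((1, 4))
        z2 = np.array([[2.0, 0, 0, 0]])
        assert contrastive_loss(z1, z2, [0], margin=1.0).item() == 0.0

    def test_hand_derived_negative_inside_margin(self):
        z1 = np.zeros((1, 4))
        z2 = np.array([[0.5, 0, 0, 0]])
        assert contrastive_loss(z1, z2, [0], margin=1.0).item() == pytest.approx(
            0.25, abs=1e-9)

    def test_positive_pair_costs_squared_distance(self):
        z1 = np.zeros((1, 3))
        z2 = np.array([[3.0, 4.0, 0.0]])       # d = 5
        assert contrastive_loss(z1, z2, [1]).item() == pytest.approx(25.0, rel=1e-9)

    def test_never_negative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        z1, z2 = rng.normal(size=(2, 50, 8))
        y = rng.integers(0, 2, size=50)
        assert contrastive_loss(z1, z2, y).item() >= 0.0

    def test_balanced_reduction_weights_classes_equally(self):
        z1 = np.zeros((3, 2))
        z2 = np.array([[1.0, 0.0], [0.5, 0.0], [0.5, 0.0]])
        y = [1, 0, 0]                            # pos loss 1; neg losses 0.25 each
        got = contrastive_loss(z1, z2, y, margin=1.0, reduction="balanced").item()
        assert got == pytest.approx(1.0 + 0.25, abs=1e-9)


class TestOneCycle:
    PUBLISHED_BOUNDS = dict(lr_min=0.0063, lr_max=0.1584)

    def test_trace_starts_at_lower_bound_and_peaks_at_upper(self):
        total = 200
        trace = [one_cycle_lr(s, total, **self.PUBLISHED_BOUNDS) for s in range(total)]
        assert trace[0] == pytest.approx(0.0063)
        assert max(trace) == pytest.approx(0.1584)

    def test_trace_is_unimodal(self):
        total = 157
        trace = np.array([one_cycle_lr(s, total, **self.PUBLISHED_BOUNDS) for s in range(total)])
        peak = int(np.argmax(trace))
        assert np.all(np.diff(trace[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(trace[peak:]) <= 1e-12)

    def test_out_of_range_step_rejected(self):
        with pytest.raises(ValueError):
            one_cycle_lr(10, 10, 0.01, 0.1)


class TestLrRangeTest:
    def _quadratic(self):
        w = Tensor(np.array([5.0]), requires_grad=True)

        def batch_fn(step):
            return F.tensor_sum(F.mul(w, w))

        return w, batch_fn

    def test_suggestion_interior_and_trace_lengths(self):
        w, batch_fn = self._quadratic()
        opt = nn.SGD([w], lr=0.01, momentum=0.0)
        lr, lrs, losses = lr_range_test(opt, batch_fn, 1e-4, 1.0, 40)
        assert len(lrs) == len(losses) == 40
        assert 1e-4 < lr <= 1.0

    def test_deterministic_given_same_start(self):
        out = []
        for _ in range(2):
            w, batch_fn = self._quadratic()
            opt = nn.SGD([w], lr=0.01, momentum=0.0)
            out.append(lr_range_test(opt, batch_fn, 1e-4, 1.0, 40)[0])
        assert out[0] == out[1]

    def test_too_few_steps_rejected(self):
        w, batch_fn = self._quadratic()
        with pytest.raises(ValueError):
            lr_range_test(nn.SGD([w], lr=0.1), batch_fn, 1e-4, 1.0, 5)


class TestXBMemory:
    def test_five_batches_of_32_keep_exactly_last_four(self):
        mem = XBMemory(128)
        for b in range(5):
            mem.update(np.full((32, 8), b, dtype=float), [f"b{b}"] * 32)
        emb, labels = mem.contents()
        assert len(mem) == 128
        assert set(labels) == {"b1", "b2", "b3", "b4"}
        assert emb[0, 0] == 1.0 and emb[-1, 0] == 4.0

    def test_under_capacity_keeps_everything(self):
        mem = XBMemory(128)
        mem.update(np.zeros((32, 8)), ["a"] * 32)
        assert len(mem) == 32

    def test_eviction_follows_insertion_order(self):
        mem = XBMemory(3)
        for i in range(5):
            mem.update(np.array([[float(i)]]), [str(i)])
        _, labels = mem.contents()
        assert labels == ["2", "3", "4"]

    def test_zero_capacity_is_noop_for_the_loss(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(4, 8))
        labels = ["a", "a", "b", "b"]
        mem = XBMemory(0)
        mem.update(z, labels)
        assert len(mem) == 0
        from cxreid.pairs import enumerate_online_pairs
        mem_emb, mem_labels = mem.contents()
        pairs_with = enumerate_online_pairs(labels, mem_labels)
        pairs_without = enumerate_online_pairs(labels)
        assert pairs_with == pairs_without

    def test_entries_are_detached_snapshots(self):
        z = np.ones((1, 4))
        mem = XBMemory(4)
        mem.update(z, ["a"])
        z[:] = 99.0
        emb, _ = mem.contents()
        assert emb[0, 0] == 1.0


class TestEarlyStopping:
    def test_flat_plateau_stops_after_patience_epochs(self):
        stopper = EarlyStopping(patience=5)
        stops = [stopper.update(e, 0.8) for e in range(10)]
        assert stops.index(True) == 5          # best at epoch 0, stop at 0 + 5

    def test_improvement_resets_the_counter(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(0, 0.5)
        assert not stopper.update(1, 0.6)
        assert not stopper.update(2, 0.55)
        assert not stopper.update(3, 0.7)
        assert not stopper.update(4, 0.6)
        assert stopper.update(5, 0.6)
        assert stopper.best_epoch == 3


class TestTrainingLoops:
    def test_verifier_smoke_run_logs_history(self, small_cohort):
        split = patient_wise_split(small_cohort, seed=2)
        cfg = desk_scale_config(seed=2)
        cfg.epochs = 2
        model, history = train_verifier(split, MiningConfig("FTS", 40, 2), cfg)
        assert len(history.epochs) == 2
        assert all(np.isfinite(e["train_loss"]) for e in history.epochs)

    def test_head_phase_leaves_backbone_bit_identical(self, small_cohort):
        split = patient_wise_split(small_cohort, seed=2)
        cfg = desk_scale_config(seed=2)
        cfg.epochs_head, cfg.epochs_full = 1, 0
        from cxreid.models import RetrievalNet, TinyBackbone
        model = RetrievalNet(backbone=TinyBackbone(16, np.random.default_rng(3)),
                             seed=3, l2_normalize=True)
        backbone_before = {k: v.copy() for k, v in model.backbone.state_dict().items()}
        head_before = [p.data.copy() for p in model.head_parameters()]
        trained, history = train_retriever(split, cfg, model=model)
        for k, v in trained.backbone.state_dict().items():
            np.testing.assert_array_equal(backbone_before[k], v)
        assert any(not np.array_equal(b, p.data)
                   for b, p in zip(head_before, trained.head_parameters()))
        assert len(history.epochs) == 1

    def test_lr_trace_contains_two_unimodal_cycles(self, small_cohort):
        split = patient_wise_split(small_cohort, seed=2)
        cfg = desk_scale_config(seed=2)
        cfg.epochs_head, cfg.epochs_full = 1, 1
        model, history = train_retriever(split, cfg)
        trace = np.array(history.lr_trace)
        # two cycles: each starts near lr_min; find the restart boundary
        restarts = np.where(np.isclose(trace, cfg.lr_min))[0]
        assert trace.max() == pytest.approx(cfg.lr_max)
        assert len(restarts) >= 2
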