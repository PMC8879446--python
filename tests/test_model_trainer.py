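"""Backbone, teacher snapshots, exemplars and the increment loop."""

import numpy as np
import pytest

from mutualcl import (
    LabelSpace,
    SoftmaxMLP,
    TrainConfig,
    expand_label_space,
    run_sequence,
    select_exemplars,
    snapshot_teacher,
    train_increment,
)
from mutualcl.exceptions import SnapshotError, ValidationError
from mutualcl.model import Adadelta
from mutualcl.trainer import continual_batch


@pytest.fixture()
def probe(rng):
    return rng.normal(0.3, 0.2, (8, 12))


def make_model(n_classes=3, input_dim=12, seed=0):
    return SoftmaxMLP(input_dim=input_dim, n_classes=n_classes, hidden_dims=(6,), seed=seed)


class TestModel:
    def test_widen_preserves_existing_logits(self, probe):
        m = make_model()
        before = m.logits(probe)
        m.widen_head(2)
        after = m.logits(probe)
        assert m.n_classes == 5
        np.testing.assert_array_equal(after[:, :3], before)

    def test_backward_matches_finite_difference(self, rng, probe):
        m = make_model()
        idx = rng.integers(0, 3, len(probe))
        onehot = np.eye(3)[idx]

        def loss():
            z = m.logits(probe)
            p = np.exp(z - z.max(1, keepdims=True))
            p /= p.sum(1, keepdims=True)
            return -np.mean(np.log(p[np.arange(len(idx)), idx]))

        z, cache = m.forward(probe)
        p = np.exp(z - z.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        grads = m.backward(cache, (p - onehot) / len(idx))
        eps = 1e-6
        params = m.parameters()
        for p_arr, g_arr in zip(params, grads):
            flat_idx = (0,) * p_arr.ndim
            p_arr[flat_idx] += eps
            up = loss()
            p_arr[flat_idx] -= 2 * eps
            down = loss()
            p_arr[flat_idx] += eps
            assert g_arr[flat_idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)

    def test_adadelta_reduces_simple_loss(self, rng):
        # minimize ||x - target||^2 with adadelta
        x = np.zeros(4)
        target = np.array([1.0, -2.0, 0.5, 3.0])
        opt = Adadelta([x])
        for _ in range(3000):
            opt.step([x], [2 * (x - target)])
        np.testing.assert_allclose(x, target, atol=0.05)


class TestSnapshot:
    def test_snapshot_frozen_under_student_updates(self, probe, rng, bench_two_class):
        cfg = TrainConfig(epochs=2, seed=0)
        h = run_sequence(bench_two_class, cfg)
        snap = snapshot_teacher(h.model, h.label_space)
        x = bench_two_class.increments[0].train_x
        before = snap.model.logits(x).copy()
        # train the student further
        idx = h.label_space.index(bench_two_class.increments[0].train_y)
        train_increment(h.model, None, x, idx, None, None, h.label_space, cfg)
        np.testing.assert_array_equal(snap.model.logits(x), before)

    def test_snapshot_idempotent(self, bench_two_class):
        h = run_sequence(bench_two_class, TrainConfig(epochs=1, seed=0))
        s1 = snapshot_teacher(h.model, h.label_space)
        s2 = snapshot_teacher(s1.model, h.label_space)
        x = bench_two_class.increments[0].train_x
        np.testing.assert_array_equal(s1.model.logits(x), s2.model.logits(x))

    def test_student_moves_away_from_teacher(self, bench_two_class):
        cfg = TrainConfig(epochs=3, seed=0)
        h = run_sequence(bench_two_class, cfg)
        snap = snapshot_teacher(h.model, h.label_space)
        x = bench_two_class.increments[0].train_x
        idx = h.label_space.index(bench_two_class.increments[0].train_y)
        train_increment(h.model, None, x, idx, None, None, h.label_space, cfg)
        assert not np.array_equal(snap.model.logits(x), h.model.logits(x))

    def test_untrained_model_rejected(self):
        with pytest.raises(SnapshotError):
            snapshot_teacher(make_model(), LabelSpace(class_ids=["a", "b", "c"]))


class TestLabelSpace:
    def test_order_preserved(self):
        s = expand_label_space(LabelSpace(), ["gun"])
        s = expand_label_space(s, ["knife"], increment=1)
        assert s.class_ids == ["gun", "knife"]
        assert s.provenance == {"gun": 0, "knife": 1}

    def test_empty_expansion_identity(self):
        s = expand_label_space(LabelSpace(class_ids=["a"], provenance={"a": 0}), [])
        assert s.class_ids == ["a"]

    def test_duplicate_rejected(self):
        s = LabelSpace(class_ids=["a"], provenance={"a": 0})
        with pytest.raises(ValidationError):
            expand_label_space(s, ["a"])


class TestExemplars:
    def test_budget_zero_empty(self):
        assert len(select_exemplars(["a"] * 5, 0, seed=0)) == 0

    def test_budget_covers_class(self):
        idx = select_exemplars(["a"] * 5 + ["b"] * 3, 10, seed=0)
        assert len(idx) == 8

    def test_unlimited_budget(self):
        assert len(select_exemplars(["a"] * 7, None, seed=0)) == 7

    def test_deterministic_and_seed_sensitive(self):
        labels = ["a"] * 100
        a = select_exemplars(labels, 10, seed=5)
        b = select_exemplars(labels, 10, seed=5)
        c = select_exemplars(labels, 10, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestTrainIncrement:
    def test_separable_first_increment_train_accuracy(self, bench_two_class):
        h = run_sequence(bench_two_class, TrainConfig(epochs=20, seed=5))
        inc = bench_two_class.increments[0]
        idx = h.label_space.index(inc.train_y)
        acc = (h.model.predict(inc.train_x) == idx).mean()
        assert acc >= 0.95

    def test_zero_epochs_bitwise_unchanged(self, bench_two_class):
        inc = bench_two_class.increments[0]
        m = make_model(2, inc.train_x.shape[1])
        params_before = [p.copy() for p in m.parameters()]
        space = LabelSpace(class_ids=["d/a", "d/b"], provenance={})
        idx = space.index(inc.train_y)
        _, log = train_increment(m, None, inc.train_x, idx, None, None, space,
                                 TrainConfig(epochs=0))
        assert log == []
        for before, after in zip(params_before, m.parameters()):
            np.testing.assert_array_equal(before, after)

    def test_empty_new_data_rejected(self):
        m = make_model()
        space = LabelSpace(class_ids=["a", "b", "c"], provenance={})
        with pytest.raises(ValidationError):
            train_increment(m, None, np.empty((0, 12)), np.empty(0, int),
                            None, None, space, TrainConfig(epochs=1))

    def test_loss_log_additivity(self, bench3):
        h = run_sequence(bench3, TrainConfig(epochs=2, seed=0))
        for row in h.loss_log:
            assert row["l_cl"] == pytest.approx(
                row["l_md"] + row["l_o"] + row["l_n"], rel=1e-9, abs=1e-12
            )


class TestRunSequence:
    def test_single_increment_history(self, bench_two_class):
        h = run_sequence(bench_two_class, TrainConfig(epochs=1, seed=0))
        assert len(h.entries) == 1
        assert h.entries[0]["memory_reduction"] == pytest.approx(0.0)

    def test_memory_accounting_matches_hand_formula(self, bench3):
        budget = 5
        h = run_sequence(bench3, TrainConfig(epochs=1, seed=0, exemplars_per_class=budget))
        class_sizes = [
            {c: inc.train_y.count(c) for c in set(inc.train_y)}
            for inc in bench3.increments
        ]
        for k, entry in enumerate(h.entries):
            expected = len(bench3.increments[k].train_x) + sum(
                min(budget, s) for j in range(k) for s in class_sizes[j].values()
            )
            assert entry["items_in_memory"] == expected

    def test_label_indices_stable_across_increments(self, bench3):
        h = run_sequence(bench3, TrainConfig(epochs=1, seed=0))
        assert h.registry == bench3.registry
        for k, entry in enumerate(h.entries):
            assert entry["registry_width"] == len(
                [c for inc in bench3.increments[: k + 1] for c in inc.classes]
            )

    def test_determinism_same_seed(self, bench3):
        cfg = TrainConfig(epochs=2, seed=9)
        h1 = run_sequence(bench3, cfg)
        h2 = run_sequence(bench3, cfg)
        for e1, e2 in zip(h1.entries, h2.entries):
            assert e1["accuracy"] == pytest.approx(e2["accuracy"], abs=1e-6)
            assert e1["macro_f1"] == pytest.approx(e2["macro_f1"], abs=1e-6)

    def test_teacher_fixed_within_increment(self, bench3):
        """Teacher outputs on a probe batch are identical across student epochs."""
        cfg = TrainConfig(epochs=2, seed=0)
        h = run_sequence(bench3, cfg)
        snap = snapshot_teacher(h.model, h.label_space)
        probe_x = bench3.increments[0].test_x[:16]
        out1 = snap.model.logits(probe_x).copy()
        inc = bench3.increments[2]
        idx = h.label_space.index(inc.train_y)
        train_increment(h.model, snap, inc.train_x, idx, None, None, h.label_space, cfg)
        np.testing.assert_array_equal(out1, snap.model.logits(probe_x))


class TestContinualBatchKernel:
    def test_ce_objective_gradient_is_softmax_residual(self, rng):
        z = rng.normal(0, 1, (4, 3))
        idx = np.array([0, 1, 2, 0])
        cfg = TrainConfig(objective="ce")
        b, g = continual_batch(z, idx, np.zeros(4, bool), None, 0, None, None, cfg)
        p = np.exp(z) / np.exp(z).sum(1, keepdims=True)
        np.testing.assert_allclose(g, (p - np.eye(3)[idx]) / 4, rtol=1e-10)
        assert b.l_md == 0.0 and b.l_o == 0.0

    def test_kl_distill_reduces_to_ce_without_teacher(self, rng):
        z = rng.normal(0, 1, (4, 3))
        idx = np.array([0, 1, 2, 0])
        b_kl, g_kl = continual_batch(
            z, idx, np.zeros(4, bool), None, 0, None, None, TrainConfig(objective="kl_distill")
        )
        b_ce, g_ce = continual_batch(
            z, idx, np.zeros(4, bool), None, 0, None, None, TrainConfig(objective="ce")
        )
        assert b_kl.l_n == pytest.approx(b_ce.l_n)
        np.testing.assert_allclose(g_kl, g_ce)
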