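import numpy as np
import pytest

from engdd._mlp import sigmoid
from engdd.grownet import (GrownetHyperparams, GrownetModel, boost_targets,
                           corrective_step, fit_stage, predict_grownet,
                           train_grownet)
from engdd.metrics import roc_auc

from .conftest import separable_blobs, xor_blobs


def logistic_loss(y, F):
    return np.logaddexp(0.0, -np.abs(F)) + np.maximum(F, 0.0) - y * F


class TestBoostTargets:
    def test_worked_value_y1_f0(self):
        t, h = boost_targets(np.array([1.0]), np.array([0.0]))
        assert t[0] == pytest.approx(2.0)
        assert h[0] == pytest.approx(0.25)

    def test_label_symmetry(self):
        t1, h1 = boost_targets(np.array([1.0]), np.array([0.0]))
        t0, h0 = boost_targets(np.array([0.0]), np.array([0.0]))
        assert t0[0] == pytest.approx(-t1[0])
        assert h0[0] == pytest.approx(h1[0])

    def test_confident_samples_get_vanishing_pull(self):
        # far into saturation g underflows to 0 while h sits at its
        # floor, so the Newton target collapses to zero
        t, _ = boost_targets(np.array([1.0]), np.array([40.0]))
        assert abs(t[0]) < 1e-10

    def test_matches_finite_differences(self):
        # independent oracle: central finite differences of the
        # logistic loss in the raw score
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=100).astype(float)
        F = rng.normal(scale=3.0, size=100)
        targets, h = boost_targets(y, F)
        eps = 1e-4  # balances truncation against rounding in the 2nd diff
        g_fd = (logistic_loss(y, F + eps) - logistic_loss(y, F - eps)) \
            / (2 * eps)
        h_fd = (logistic_loss(y, F + eps) - 2 * logistic_loss(y, F)
                + logistic_loss(y, F - eps)) / eps ** 2
        np.testing.assert_allclose(-targets * h, g_fd, atol=1e-6)
        np.testing.assert_allclose(h, h_fd, atol=1e-6)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            boost_targets(np.array([0.5]), np.array([0.0]))


class TestFitStage:
    def test_learns_constant_target(self):
        # all targets equal a constant: one epoch must beat the zero
        # function on the weighted objective
        ds = separable_blobs(n=150, seed=1)
        F = np.where(ds.y == 1, -1.0, 1.0) * 0.5  # wrong-ish scores
        hp = GrownetHyperparams(epochs_per_stage=3)
        net, alpha = fit_stage(ds, F, hp, seed=0)
        targets, weights = boost_targets(ds.y, F)
        pred = net.forward(ds.X)
        obj = np.sum(weights * (targets - pred) ** 2)
        obj_zero = np.sum(weights * targets ** 2)
        assert obj < obj_zero
        assert alpha == hp.boost_rate

    def test_never_worse_than_zero_learner(self):
        rng = np.random.default_rng(2)
        ds = separable_blobs(n=80, seed=2)
        F = rng.normal(size=80)
        net, _ = fit_stage(ds, F, GrownetHyperparams(), seed=5)
        targets, weights = boost_targets(ds.y, F)
        pred = net.forward(ds.X)
        assert np.sum(weights * (targets - pred) ** 2) <= \
            np.sum(weights * targets ** 2) + 1e-12

    def test_fixed_seed_bit_identical(self):
        ds = separable_blobs(n=60, seed=3)
        F = np.zeros(60)
        n1, _ = fit_stage(ds, F, GrownetHyperparams(), seed=9)
        n2, _ = fit_stage(ds, F, GrownetHyperparams(), seed=9)
        for a, b in zip(n1.params(), n2.params()):
            np.testing.assert_array_equal(a, b)


class TestCorrectiveStep:
    def _one_learner_model(self, ds, seed=0):
        hp = GrownetHyperparams()
        F0 = float(np.log(ds.y.mean() / (1 - ds.y.mean())))
        net, alpha = fit_stage(ds, np.full(len(ds), F0), hp, seed)
        return GrownetModel([net], [alpha], F0, hp.boost_rate, hp), hp

    def test_zero_epochs_is_noop(self):
        ds = separable_blobs(n=60, seed=4)
        model, hp = self._one_learner_model(ds)
        before = [f.copy_params() for f in model.learners]
        hp0 = GrownetHyperparams(correct_epoch=0)
        corrective_step(model, ds, hp0)
        for f, p in zip(model.learners, before):
            for a, b in zip(f.params(), p):
                np.testing.assert_array_equal(a, b)

    def test_bce_never_increases(self):
        from engdd.grownet import _bce_from_raw
        ds = separable_blobs(n=200, seed=5)
        model, hp = self._one_learner_model(ds)
        before = _bce_from_raw(ds.y.astype(float), model.raw_score(ds.X))
        corrective_step(model, ds, hp, seed=1)
        after = _bce_from_raw(ds.y.astype(float), model.raw_score(ds.X))
        assert after <= before + 1e-6

    def test_guard_restores_on_divergence(self):
        ds = separable_blobs(n=60, seed=6)
        model, _ = self._one_learner_model(ds)
        before = [f.copy_params() for f in model.learners]
        bad_hp = GrownetHyperparams(lr=1e4)
        corrective_step(model, ds, bad_hp, seed=2)
        for f, p in zip(model.learners, before):
            for a, b in zip(f.params(), p):
                np.testing.assert_array_equal(a, b)


class TestTrainPredict:
    def test_single_stage_additive_definition(self):
        ds = separable_blobs(n=100, seed=7)
        hp = GrownetHyperparams(num_nets=1, correct_epoch=0)
        model = train_grownet(ds, hp, seed=3)
        p = predict_grownet(model, ds.X)
        manual = sigmoid(model.initial_score
                         + model.boost_rate * model.learners[0].forward(ds.X))
        np.testing.assert_allclose(p, manual, atol=1e-10)

    def test_balanced_prior_is_half(self):
        ds = separable_blobs(n=100, seed=8)
        # force perfect balance
        y = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        ds.y = y
        model = train_grownet(ds, GrownetHyperparams(num_nets=1), seed=0)
        assert sigmoid(model.initial_score) == pytest.approx(0.5)

    def test_xor_blobs_training_auc(self):
        # non-linear separability is the point of net-based learners
        ds = xor_blobs(n=400, seed=9)
        model = train_grownet(ds, seed=0)
        assert roc_auc(predict_grownet(model, ds.X), ds.y) >= 0.95

    def test_single_class_rejected(self):
        ds = separable_blobs(n=40, seed=10)
        ds.y = np.ones(40, dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            train_grownet(ds)

    def test_empty_learner_list_predicts_prior(self):
        model = GrownetModel([], [], initial_score=0.3, boost_rate=1.0)
        p = predict_grownet(model, np.zeros((5, 2)))
        np.testing.assert_allclose(p, sigmoid(0.3))

    def test_serialization_round_trip(self, tmp_path):
        ds = separable_blobs(n=80, seed=11)
        model = train_grownet(ds, GrownetHyperparams(num_nets=2), seed=1)
        model.save(tmp_path / "g.pkl")
        loaded = GrownetModel.load(tmp_path / "g.pkl")
        np.testing.assert_array_equal(predict_grownet(model, ds.X),
                                      predict_grownet(loaded, ds.X))

    def test_probability_matches_manual_summation(self):
        ds = separable_blobs(n=50, seed=12)
        model = train_grownet(ds, GrownetHyperparams(num_nets=3), seed=2)
        F = np.full(len(ds), model.initial_score)
        for alpha, f in zip(model.step_sizes, model.learners):
            F = F + alpha * f.forward(ds.X)
        np.testing.assert_allclose(predict_grownet(model, ds.X),
                                   sigmoid(F), atol=1e-10)
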