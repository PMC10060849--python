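"""Class weights, weighted BCE, gradient reversal, DANN and SVM training."""

import math

import numpy as np
import pytest

from brainlayers import (
    DannConfig,
    GradientReversal,
    class_weights,
    predict,
    train_dann,
    train_svm,
    weighted_bce,
)
from brainlayers._nn import Linear, Stack
from brainlayers.classifiers import _bce_grad, _one_hot
from oracles import plain_bce_mean


class TestClassWeights:
    def test_balanced_counts_give_half_half(self):
        cw = class_weights([0, 0, 1, 1])
        assert np.allclose(cw.weights, [0.5, 0.5])

    def test_counts_one_two_direct_evaluation(self):
        cw = class_weights([0, 1, 1])
        w0 = math.e / (math.e + math.exp(0.5))
        assert cw.weights[0] == pytest.approx(w0, abs=1e-12)
        assert cw.weights[1] == pytest.approx(1.0 - w0, abs=1e-12)
        assert w0 == pytest.approx(0.62246, abs=5e-6)

    def test_normalization_and_monotonicity(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 50, size=2)
            labels = np.repeat([0, 1], counts)
            cw = class_weights(labels)
            assert cw.weights.sum() == pytest.approx(1.0, abs=1e-12)
            if counts[0] < counts[1]:
                assert cw.weights[0] > cw.weights[1]
            elif counts[0] > counts[1]:
                assert cw.weights[0] < cw.weights[1]

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights([1, 1, 1])


class TestWeightedBce:
    def test_perfect_prediction_is_near_zero(self):
        y = _one_hot(np.array([1, 0, 1]))
        assert weighted_bce(y, y, np.array([0.5, 0.5])) < 1e-5

    def test_balanced_half_probability_equals_log_two(self):
        y = np.array([[1.0, 0.0]])
        yhat = np.array([[0.5, 0.5]])
        loss = weighted_bce(yhat, y, np.array([0.5, 0.5]))
        assert loss == pytest.approx(math.log(2.0), abs=1e-12)

    def test_uniform_weights_match_plain_bce_oracle(self, rng):
        for _ in range(5):
            yhat = rng.uniform(0.01, 0.99, size=(13, 2))
            y = _one_hot(rng.integers(0, 2, size=13))
            ours = weighted_bce(yhat, y, np.array([0.5, 0.5]))
            assert ours == pytest.approx(0.5 * plain_bce_mean(yhat, y), abs=1e-10)

    def test_extreme_probabilities_are_clamped_finite(self):
        y = np.array([[1.0, 0.0]])
        yhat = np.array([[0.0, 1.0]])  # maximally wrong
        loss = weighted_bce(yhat, y, np.array([0.5, 0.5]))
        assert np.isfinite(loss) and loss > 10.0

    def test_rarer_class_errors_cost_more(self):
        # the two sigmoid outputs are uncoupled, so identical per-unit errors
        # are weighted by their class: missing the rare class costs more
        cw = class_weights([0, 0, 0, 0, 1])  # class 1 rare => larger weight
        err_on_rare = weighted_bce(np.array([[0.5, 0.1]]), _one_hot([1]), cw)
        err_on_common = weighted_bce(np.array([[0.1, 0.5]]), _one_hot([0]), cw)
        assert err_on_rare > err_on_common


class TestGradientReversal:
    def test_forward_identity(self, rng):
        grl = GradientReversal(2.5)
        x = rng.normal(size=(4, 3))
        assert np.array_equal(grl.forward(x), x)

    def test_backward_scales_by_minus_lambda(self, rng):
        g = rng.normal(size=(4, 3))
        for lam in (0.0, 0.5, 2.0):
            out = GradientReversal(lam).backward(g)
            assert np.allclose(out, -lam * g)

    def test_backward_matches_finite_difference_baseline(self, rng):
        """On a tiny two-layer net, the parameter sensitivity through the GRL
        equals −λ times the numerical (no-GRL) sensitivity."""
        lower = Linear(3, 2, rng)
        upper = Linear(2, 1, rng)
        grl = GradientReversal(1.7)
        x = rng.normal(size=(5, 3))

        def loss_fn():
            h = lower.forward(x, train=False, rng=None, update_stats=False)
            z = grl.forward(h)  # identity: the loss value ignores λ
            return float(upper.forward(z, train=False, rng=None, update_stats=False).sum())

        loss_fn()
        for p in lower.params() + upper.params():
            p.grad[...] = 0.0
        g = upper.backward(np.ones((5, 1)))
        lower.backward(grl.backward(g))
        analytic = lower.w.grad.copy()

        eps = 1e-6
        numeric = np.zeros_like(lower.w.value)
        for idx in np.ndindex(*lower.w.value.shape):
            old = lower.w.value[idx]
            lower.w.value[idx] = old + eps
            up = loss_fn()
            lower.w.value[idx] = old - eps
            down = loss_fn()
            lower.w.value[idx] = old
            numeric[idx] = (up - down) / (2 * eps)
        assert np.allclose(analytic, -1.7 * numeric, atol=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            GradientReversal(-0.1)


def _separable_problem(rng, n=120, dim=12, gap=4.0):
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, dim))
    x[:, 0] += gap * (y - 0.5)
    x[:, 1] -= gap * (y - 0.5)
    return x, y


class TestTrainDann:
    def test_learns_separable_features(self, rng):
        x, y = _separable_problem(rng)
        xe, ye = _separable_problem(rng, n=60)
        cfg = DannConfig(
            input_dim=12, epochs=150, batch_size=32, seed=4,
            lambda_grl=0.0, domain_adversarial=False,
        )
        model = train_dann(x, y, cfg, eval_x=xe, eval_y=ye)
        assert model.training_log["test_acc"].max() >= 0.95

    def test_fixed_seed_reproduces_training_log(self, rng):
        x, y = _separable_problem(rng, n=60)
        xt = rng.normal(size=(20, 12))
        cfg = DannConfig(input_dim=12, epochs=10, batch_size=16, seed=9)
        logs = [
            train_dann(x, y, cfg, x_target=xt, eval_x=x, eval_y=y).training_log
            for _ in range(2)
        ]
        assert logs[0].equals(logs[1])

    def test_lambda_zero_matches_plain_mlp_trajectory(self, rng):
        """With λ = 0 the domain head receives no influence over the extractor,
        so the label path evolves exactly as a DANN-free MLP with the same seed."""
        x, y = _separable_problem(rng, n=80)
        xt = rng.normal(size=(30, 12)) + 2.0
        base = dict(input_dim=12, epochs=12, batch_size=16, seed=21)
        dann = train_dann(x, y, DannConfig(lambda_grl=0.0, **base), x_target=xt)
        mlp = train_dann(x, y, DannConfig(domain_adversarial=False, **base))
        net_d, net_m = dann.model, mlp.model
        for a, b in zip(
            net_d.extractor.params() + net_d.label_head.params(),
            net_m.extractor.params() + net_m.label_head.params(),
        ):
            assert np.array_equal(a.value, b.value)
        assert dann.training_log["train_acc"].equals(mlp.training_log["train_acc"])

    def test_adversarial_pressure_raises_domain_loss(self, rng):
        """λ > 0 makes the extractor confuse the domain classifier: the
        domain loss settles higher than with λ = 0."""
        x, y = _separable_problem(rng, n=80)
        xt = rng.normal(size=(40, 12)) + 1.5
        base = dict(input_dim=12, epochs=50, batch_size=32, seed=7)
        loss = {}
        for lam in (0.0, 2.0):
            m = train_dann(x, y, DannConfig(lambda_grl=lam, **base), x_target=xt)
            loss[lam] = m.training_log["domain_loss"].iloc[-10:].mean()
        assert loss[2.0] > loss[0.0]

    def test_single_class_and_empty_features_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_dann(x, np.ones(10, int), DannConfig(input_dim=3, epochs=1))
        with pytest.raises(ValueError, match="relax"):
            DannConfig(input_dim=0)


class TestSvmAndPredict:
    def test_two_point_toy_is_separated(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        model = train_svm(x, y)
        labels, _ = predict(model, x)
        assert np.array_equal(labels, y)

    def test_xor_is_not_linearly_separable(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        labels, _ = predict(train_svm(x, y), x)
        assert (labels == y).mean() <= 0.75

    def test_margin_direction_matches_brute_force_2d(self, rng):
        """On a separable 2-D toy the SVM decision agrees with the
        max-margin separator found by brute-force grid search."""
        x = np.vstack([rng.normal(size=(20, 2)) - 2.0, rng.normal(size=(20, 2)) + 2.0])
        y = np.repeat([0, 1], 20)
        model = train_svm(x, y)
        best, best_margin = None, -np.inf
        for theta in np.linspace(0, np.pi, 361):
            wdir = np.array([np.cos(theta), np.sin(theta)])
            proj = x @ wdir
            lo, hi = proj[y == 1].min(), proj[y == 0].max()
            margin = lo - hi
            if margin > best_margin:
                best_margin, best = margin, (wdir, (lo + hi) / 2)
        wdir, b = best
        brute_labels = (x @ wdir > b).astype(int)
        svm_labels, _ = predict(model, x)
        assert np.array_equal(svm_labels, brute_labels)

    def test_dann_scores_in_unit_interval_and_batch_invariance(self, rng):
        x, y = _separable_problem(rng, n=40)
        cfg = DannConfig(input_dim=12, epochs=5, batch_size=16, seed=2,
                         domain_adversarial=False)
        model = train_dann(x, y, cfg)
        labels, scores = predict(model, x)
        assert np.all((scores > 0.0) & (scores < 1.0))
        single = [predict(model, x[k : k + 1]) for k in range(6)]
        assert np.array_equal(labels[:6], np.concatenate([s[0] for s in single]))
        assert np.allclose(scores[:6], np.concatenate([s[1] for s in single]))

    def test_width_mismatch_rejected(self, rng):
        x, y = _separable_problem(rng, n=30)
        model = train_svm(x, y)
        with pytest.raises(ValueError, match="width"):
            predict(model, x[:, :5])
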