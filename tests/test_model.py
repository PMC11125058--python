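"""Model construction, forward contracts, losses and metrics.

Loss and metric implementations are checked against independently coded
brute-force loops (explicit per-sample Python arithmetic) on random inputs.
"""
import numpy as np
import pytest

from metspecs.errors import ConfigError, MetspecsError
from metspecs.model import (
    MultitaskConfig,
    build_model,
    classification_metrics,
    loss_combined,
    loss_ee,
    loss_par,
    onehot,
    regression_metrics,
)

SMALL = dict(input_shape=(128, 6), n_blocks=2, kernel_counts=(4, 8),
             kernel_size=9, pool_size=4, dropout_rate=0.2,
             head1_dense=(16,), head2_dense=(16,), n_classes=6)


class TestConfig:
    def test_default_routing_valid(self):
        cfg = MultitaskConfig(**SMALL, head2_block_set=(1, 2))
        assert build_model(cfg, 0).n_parameters > 0

    def test_all_blocks_routing_valid(self):
        cfg = MultitaskConfig(input_shape=(1280, 6), head2_block_set=(1, 2, 3, 4))
        assert build_model(cfg, 0).n_parameters > 0

    def test_block_index_out_of_range(self):
        with pytest.raises(ConfigError):
            MultitaskConfig(**SMALL, head2_block_set=(5,))

    def test_empty_block_set(self):
        with pytest.raises(ConfigError):
            MultitaskConfig(**SMALL, head2_block_set=())


@pytest.fixture(scope="module")
def net():
    return build_model(MultitaskConfig(**SMALL, head2_block_set=(1, 2)), 3)


class TestForward:

    def test_output_shapes_and_prob_normalisation(self, net):
        rng = np.random.default_rng(0)
        x = rng.random((7, 128, 6)).astype(np.float32)
        mass = rng.normal(size=7)
        probs, mets = net.forward(x, mass, "eval", rng)
        assert probs.shape == (7, 6) and mets.shape == (7,)
        assert np.all(np.abs(probs.sum(axis=1) - 1.0) < 1e-6)
        assert np.all(mets > 0)

    def test_eval_mode_deterministic(self, net):
        rng = np.random.default_rng(0)
        x = rng.random((4, 128, 6)).astype(np.float32)
        mass = rng.normal(size=4)
        p1, m1 = net.forward(x, mass, "eval", np.random.default_rng(1))
        p2, m2 = net.forward(x, mass, "eval", np.random.default_rng(99))
        assert np.array_equal(p1, p2) and np.array_equal(m1, m2)

    def test_shape_mismatch_rejected(self, net):
        with pytest.raises(ConfigError):
            net.forward(np.zeros((2, 64, 6), dtype=np.float32),
                        np.zeros(2), "eval", np.random.default_rng(0))

    def test_gradients_match_finite_differences(self):
        """Backprop against central differences (absolute tolerance)."""
        from metspecs.nn import sigmoid
        cfg = MultitaskConfig(input_shape=(64, 3), n_blocks=2,
                              kernel_counts=(3, 4), kernel_size=5, pool_size=2,
                              dropout_rate=0.0, head1_dense=(8,),
                              head2_dense=(8,), head2_block_set=(1, 2),
                              n_classes=3)
        net = build_model(cfg, 1)
        rng = np.random.default_rng(2)
        x = rng.random((4, 64, 3)).astype(np.float32)
        mass = rng.normal(size=4).astype(np.float32)
        yc = np.array([0, 1, 2, 1])
        ym = np.array([2.0, 3.0, 4.0, 5.0])
        w1, w2 = 0.4, 0.6

        def total_loss():
            p, m = net.forward(x, mass, "eval", rng)
            return w1 * loss_par(onehot(yc, 3), p) + w2 * loss_ee(ym, m)

        p, m = net.forward(x, mass, "eval", rng)
        d_log = (w1 * (p - onehot(yc, 3)) / 4).astype(np.float32)
        d_z2 = (w2 * 2.0 * (m - ym) / 4 * sigmoid(net._z2)).astype(np.float32)
        for par in net.all_params():
            par.zero_grad()
        net.backward(d_log, d_z2)

        check_rng = np.random.default_rng(11)
        for par in net.all_params():
            flat = par.value.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                old = flat[i]
                eps = 1e-3
                flat[i] = old + eps
                lp = total_loss()
                flat[i] = old - eps
                lm = total_loss()
                flat[i] = old
                assert abs((lp - lm) / (2 * eps) - par.grad.ravel()[i]) < 5e-3


class TestLosses:
    def test_perfect_prediction_zero_ce(self):
        y = onehot(np.array([2]), 4)
        assert loss_par(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_two_class(self):
        assert loss_par(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_batch_mean_equals_mean_of_singles(self):
        rng = np.random.default_rng(0)
        y = onehot(rng.integers(0, 4, size=10), 4)
        p = rng.dirichlet(np.ones(4), size=10)
        singles = [loss_par(y[i:i + 1], p[i:i + 1]) for i in range(10)]
        assert loss_par(y, p) == pytest.approx(np.mean(singles), abs=1e-12)

    def test_mse_examples(self):
        assert loss_ee([2.0, 4.0], [3.0, 3.0]) == pytest.approx(1.0)
        assert loss_ee([1.0, 2.0], [1.0, 2.0]) == 0.0
        # quadratic scaling
        assert loss_ee([0, 0], [2, 2]) == pytest.approx(4 * loss_ee([0, 0], [1, 1]))

    def test_mse_empty_rejected(self):
        with pytest.raises(MetspecsError):
            loss_ee([], [])

    def test_combined_examples(self):
        assert loss_combined(0.3, 0.7, 1.0, 2.0) == pytest.approx(1.7)
        assert loss_combined(1.0, 0.0, 0.42, 9.0) == pytest.approx(0.42)

    def test_combined_invalid_weights(self):
        with pytest.raises(ConfigError):
            loss_combined(0.5, 0.6, 1.0, 1.0)

    def test_combined_linear_in_losses(self):
        a1 = loss_combined(0.3, 0.7, 1.0, 0.0)
        a2 = loss_combined(0.3, 0.7, 0.0, 1.0)
        assert loss_combined(0.3, 0.7, 2.0, 3.0) == pytest.approx(2 * a1 + 3 * a2)

    def test_ce_matches_brute_force(self):
        rng = np.random.default_rng(5)
        y = onehot(rng.integers(0, 6, size=200), 6)
        p = rng.dirichlet(np.ones(6), size=200)
        brute = 0.0
        for i in range(200):
            s = 0.0
            for c in range(6):
                s -= y[i, c] * np.log(max(p[i, c], 1e-12))
            brute += s
        brute /= 200
        assert loss_par(y, p) == pytest.approx(brute, abs=1e-10)


class TestRegressionMetrics:
    def test_examples(self):
        assert regression_metrics([2.0, 4.0], [1.0, 3.0]) == \
            pytest.approx((1.0, 0.375))
        assert regression_metrics([3.0], [3.0]) == (0.0, 0.0)

    def test_zero_actual_rejected_with_indices(self):
        with pytest.raises(MetspecsError, match=r"\[1\]"):
            regression_metrics([2.0, 0.0], [1.0, 1.0])

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0.5, 10.0, size=1000)
        y_hat = y + rng.normal(0, 1, size=1000)
        mse, mape = regression_metrics(y, y_hat)
        b_mse = sum((y[i] - y_hat[i]) ** 2 for i in range(1000)) / 1000
        b_mape = sum(abs(y[i] - y_hat[i]) / y[i] for i in range(1000)) / 1000
        assert mse == pytest.approx(b_mse, abs=1e-10)
        assert mape == pytest.approx(b_mape, abs=1e-10)


class TestClassificationMetrics:
    def test_all_correct(self):
        assert classification_metrics(list("ABAB"), list("ABAB")) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        acc, prec, rec, f1 = classification_metrics(list("AABB"), list("ABBB"))
        assert acc == pytest.approx(0.75)
        assert prec == pytest.approx(5 / 6)
        assert rec == pytest.approx(0.75)
        assert f1 == pytest.approx((2 / 3 + 0.8) / 2)

    def test_total_permutation_zero_accuracy(self):
        assert classification_metrics(list("ABC"), list("BCA"))[0] == 0.0

    def test_matches_confusion_matrix_oracle(self):
        """Macro averages against an independent confusion-matrix loop."""
        rng = np.random.default_rng(12)
        y = rng.integers(0, 4, size=300)
        p = rng.integers(0, 4, size=300)
        acc, prec, rec, f1 = classification_metrics(y, p)
        labels = sorted(set(y) | set(p))
        precs, recs, f1s = [], [], []
        for c in labels:
            tp = int(np.sum((y == c) & (p == c)))
            fp = int(np.sum((y != c) & (p == c)))
            fn = int(np.sum((y == c) & (p != c)))
            pr = tp / (tp + fp) if tp + fp else 0.0
            rc = tp / (tp + fn) if tp + fn else 0.0
            precs.append(pr)
            recs.append(rc)
            f1s.append(2 * pr * rc / (pr + rc) if pr + rc else 0.0)
        assert acc == pytest.approx(np.mean(y == p), abs=1e-12)
        assert prec == pytest.approx(np.mean(precs), abs=1e-10)
        assert rec == pytest.approx(np.mean(recs), abs=1e-10)
        assert f1 == pytest.approx(np.mean(f1s), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(MetspecsError):
            classification_metrics([], [])
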