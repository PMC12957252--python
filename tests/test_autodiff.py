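"""Gradient correctness of the autodiff core against finite differences."""

import numpy as np
import pytest

from dspmcf.nn import (
    Tensor,
    GRU,
    BatchNorm,
    Linear,
    MLP,
    concat,
    stack,
    grad_reversal,
    log_softmax,
    cross_entropy,
    symmetric_kl,
    Adam,
)


def numeric_grad(f, x0, eps=1e-6):
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x0.copy(), x0.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(Tensor(xp)).item() - f(Tensor(xm)).item()) / (2 * eps)
    return g


def check(f, x0, tol=1e-5):
    x = Tensor(x0.copy(), requires_grad=True)
    f(x).backward()
    assert x.grad is not None
    np.testing.assert_allclose(x.grad, numeric_grad(f, x0), atol=tol)


class TestElementwiseAndMatmul:
    def test_mixed_elementwise_chain(self, rng):
        x0 = rng.normal(size=(3, 4))
        W = Tensor(rng.normal(size=(4, 5)))
        check(lambda x: ((x @ W).tanh().sigmoid() * 2 + (x**2).mean()).sum(), x0)

    def test_log_exp_relu(self, rng):
        x0 = rng.normal(size=(4, 3))
        check(lambda x: ((x.relu() + 1.0).log().exp()).mean(axis=0).sum(), x0)

    def test_division_and_pow(self, rng):
        x0 = rng.normal(size=(3, 3)) + 3.0
        check(lambda x: ((x**0.5) / (x + 1.0)).sum(), x0)

    @pytest.mark.parametrize("shape_a,shape_b", [((3, 4), (4, 2)), ((2, 3, 4), (4, 2)), ((2, 3, 4), (2, 4, 2))])
    def test_matmul_shapes(self, rng, shape_a, shape_b):
        B = Tensor(rng.normal(size=shape_b))
        x0 = rng.normal(size=shape_a)
        check(lambda x: ((x @ B) ** 2).sum(), x0)

    def test_matmul_vector_cases(self, rng):
        v = Tensor(rng.normal(size=4))
        x3 = rng.normal(size=(2, 3, 4))
        check(lambda x: ((x @ v) ** 2).sum(), x3)
        B3 = Tensor(rng.normal(size=(2, 4, 3)))
        check(lambda t: ((t @ B3) ** 2).sum(), rng.normal(size=4))

    def test_reductions_and_reshape(self, rng):
        x0 = rng.normal(size=(2, 3, 4))
        check(lambda x: x.sum(axis=(0, 2)).sum() + x.mean(axis=1, keepdims=True).sum(), x0)
        check(lambda x: (x.reshape(6, 4).transpose(1, 0) ** 2).sum() + x.mean(), x0)

    def test_getitem_and_concat_stack(self, rng):
        x0 = rng.normal(size=(3, 5))
        check(lambda x: (concat([x[:, :2], x[:, 2:]], axis=1) ** 2).sum(), x0)
        check(lambda x: (stack([x[0], x[1], x[2]], axis=0).tanh()).sum(), x0)
        idx = np.array([2, 1, 0])
        check(lambda x: (x[:, np.array([4, 0, 1])] ** 2).sum() + x[idx].sum(), x0)


class TestModules:
    def test_gru_gradients(self, rng):
        gru = GRU(4, 6, rng)
        x0 = rng.normal(size=(2, 5, 4))
        check(lambda x: gru(x)[1].sum() + gru(x)[0].mean(), x0, tol=1e-4)

    def test_batchnorm_train_mode(self, rng):
        bn = BatchNorm(4)
        x0 = rng.normal(size=(10, 4))
        check(lambda x: (bn(x) ** 2).sum(), x0, tol=1e-4)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = BatchNorm(4)
        for _ in range(50):
            bn(Tensor(rng.normal(loc=2.0, scale=3.0, size=(64, 4))))
        bn.eval()
        out1 = bn(Tensor(np.ones((1, 4)))).data
        out2 = bn(Tensor(np.ones((1, 4)))).data
        np.testing.assert_array_equal(out1, out2)
        assert abs(bn.running_mean.mean() - 2.0) < 0.5

    def test_state_dict_round_trip(self, rng):
        m1 = MLP(3, 8, 2, rng)
        m2 = MLP(3, 8, 2, np.random.default_rng(999))
        x = Tensor(rng.normal(size=(4, 3)))
        assert not np.allclose(m1(x).data, m2(x).data)
        m2.load_state_dict(m1.state_dict())
        np.testing.assert_array_equal(m1(x).data, m2(x).data)

    def test_adam_minimizes_quadratic(self):
        w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([w], lr=0.1)
        for _ in range(300):
            loss = (w * w).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(w.data).max() < 1e-2


class TestGradReversal:
    def test_forward_is_identity(self, rng):
        x = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        np.testing.assert_array_equal(grad_reversal(x, 0.5).data, x.data)

    @pytest.mark.parametrize("lam", [0.0, 0.05, 1.0])
    def test_backward_scales_by_minus_lambda(self, rng, lam):
        x = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
        grad_reversal(x, lam).sum().backward()
        np.testing.assert_allclose(x.grad, np.full((4, 5), -lam))

    def test_gradient_through_downstream_net(self, rng):
        """-lam-scaled vs plain gradients agree through a nonlinear head."""
        net = MLP(4, 8, 3, rng)
        x0 = rng.normal(size=(2, 4))
        x1 = Tensor(x0.copy(), requires_grad=True)
        cross_entropy(net(grad_reversal(x1, 0.7)), np.array([0, 2])).backward()
        x2 = Tensor(x0.copy(), requires_grad=True)
        cross_entropy(net(x2), np.array([0, 2])).backward()
        np.testing.assert_allclose(x1.grad, -0.7 * x2.grad, atol=1e-12)


class TestLosses:
    def test_log_softmax_normalizes(self, rng):
        lp = log_softmax(Tensor(rng.normal(size=(6, 4))), axis=-1)
        np.testing.assert_allclose(np.exp(lp.data).sum(axis=-1), 1.0, atol=1e-9)

    def test_cross_entropy_uniform_is_log_c(self):
        for c in (3, 4):
            logits = Tensor(np.zeros((7, c)))
            labels = np.arange(7) % c
            assert cross_entropy(logits, labels).item() == pytest.approx(np.log(c), abs=1e-12)

    def test_symmetric_kl_hand_value(self):
        p = Tensor(np.array([[0.8, 0.2]]))
        q = Tensor(np.array([[0.5, 0.5]]))
        assert symmetric_kl(p, q).item() == pytest.approx(0.41589, abs=1e-5)

    def test_symmetric_kl_properties(self, rng):
        raw = rng.random((5, 3)) + 0.05
        p = Tensor(raw / raw.sum(axis=1, keepdims=True))
        raw2 = rng.random((5, 3)) + 0.05
        q = Tensor(raw2 / raw2.sum(axis=1, keepdims=True))
        assert symmetric_kl(p, q).item() >= 0
        assert symmetric_kl(p, q).item() == pytest.approx(symmetric_kl(q, p).item())
        assert symmetric_kl(p, p).item() == pytest.approx(0.0, abs=1e-12)
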