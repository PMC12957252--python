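"""Spatial GCN branch: layer algebra, pooling, decoder accumulator."""

import numpy as np
import pytest

from dspmcf.nn import Tensor, no_grad, mse
from dspmcf.graph import ElectrodeGraph, normalized_operator
from dspmcf.spatial import SpatialBranch, gcn_layer, spatial_reconstruction_loss, collapse_time


@pytest.fixture()
def branch(rng):
    coords = rng.normal(size=(6, 3))
    g = ElectrodeGraph.from_coords(coords)
    return SpatialBranch(n_subjects=2, operator=g.operator, n_bands=4, hidden=16, rng=rng)


class TestGcnLayer:
    def test_identity_map(self, rng):
        H = Tensor(rng.normal(size=(5, 5)))
        out = gcn_layer(H, Tensor(np.eye(5)), Tensor(np.eye(5)), Tensor(np.zeros(5)))
        np.testing.assert_allclose(out.data, H.data)

    def test_three_node_hand_graph_row_sums(self):
        """H = ones, W = I: each output row equals the operator's row sums."""
        A = np.ones((3, 3)) - np.eye(3)
        L = normalized_operator(A)
        out = gcn_layer(Tensor(np.ones((3, 3))), Tensor(L), Tensor(np.eye(3)), Tensor(np.zeros(3)))
        np.testing.assert_allclose(out.data, np.repeat(L.sum(axis=1, keepdims=True), 3, axis=1))

    def test_linearity_with_zero_bias(self, rng):
        L = Tensor(rng.random((4, 4)))
        W = Tensor(rng.normal(size=(3, 5)))
        b = Tensor(np.zeros(5))
        H1, H2 = Tensor(rng.normal(size=(4, 3))), Tensor(rng.normal(size=(4, 3)))
        lhs = gcn_layer(Tensor(2 * H1.data + 3 * H2.data), L, W, b)
        rhs = 2 * gcn_layer(H1, L, W, b) + 3 * gcn_layer(H2, L, W, b)
        np.testing.assert_allclose(lhs.data, rhs.data, atol=1e-12)


class TestEncoder:
    def test_global_is_channel_mean_of_local(self, branch, rng):
        frame = Tensor(rng.normal(size=(3, 6, 4)))
        with no_grad():
            local, global_ = branch.encode(frame)
        assert local.shape == (3, 6, 16)
        np.testing.assert_allclose(global_.data, local.data.mean(axis=1), atol=1e-12)

    def test_eval_mode_deterministic_per_sample(self, branch, rng):
        branch.eval()
        x = rng.normal(size=(1, 6, 4))
        batch = Tensor(np.concatenate([x, x], axis=0))
        with no_grad():
            local, _ = branch.encode(batch)
        np.testing.assert_array_equal(local.data[0], local.data[1])


class TestDecoder:
    def test_output_shape(self, branch, rng):
        with no_grad():
            local, _ = branch.encode(Tensor(rng.normal(size=(3, 6, 4))))
            out = branch.decoders[0](local, branch.L_op)
        assert out.shape == (3, 6, 4)

    def test_zero_weights_give_bias_only_output(self, rng):
        coords = rng.normal(size=(6, 3))
        g = ElectrodeGraph.from_coords(coords)
        br = SpatialBranch(2, g.operator, n_bands=4, hidden=16, n_layers=1, rng=rng)
        dec = br.decoders[0]
        for W in dec.Ws:
            W.data[:] = 0.0
        with no_grad():
            out = dec(Tensor(rng.normal(size=(2, 6, 16))), br.L_op)
        # relu(BN(0)) is constant over the batch; projection of a constant is constant
        np.testing.assert_allclose(out.data[0], out.data[1], atol=1e-12)

    def test_accumulator_changes_output(self, rng):
        """The hidden-state accumulation ablation alters the computation."""
        coords = rng.normal(size=(6, 3))
        g = ElectrodeGraph.from_coords(coords)
        a = SpatialBranch(1, g.operator, n_bands=4, hidden=16, rng=np.random.default_rng(0))
        b = SpatialBranch(1, g.operator, n_bands=4, hidden=16, hidden_state=False, rng=np.random.default_rng(0))
        b.load_state_dict(a.state_dict())
        x = Tensor(rng.normal(size=(3, 6, 16)))
        with no_grad():
            out_a = a.decoders[0](x, a.L_op)
            out_b = b.decoders[0](x, b.L_op)
        assert not np.allclose(out_a.data, out_b.data)

    def test_accumulator_off_is_plain_feedforward_stack(self, rng):
        """Without the accumulator each layer consumes only the previous output."""
        coords = rng.normal(size=(5, 3))
        g = ElectrodeGraph.from_coords(coords)
        br = SpatialBranch(1, g.operator, n_bands=3, hidden=8, hidden_state=False, rng=rng)
        dec = br.decoders[0]
        x = Tensor(rng.normal(size=(2, 5, 8)))
        with no_grad():
            out = dec(x, br.L_op)
            # manual feed-forward replication
            h = x
            for W, bias, bn in zip(dec.Ws, dec.bs, dec.bns):
                h = bn(gcn_layer(h, br.L_op, W, bias)).relu()
            manual = dec.head(h)
        np.testing.assert_allclose(out.data, manual.data, atol=1e-12)


class TestStage2AndLoss:
    def test_stage2_permutation_invariant(self, branch, rng):
        o1 = [Tensor(rng.normal(size=(2, 6, 4))) for _ in range(2)]
        with no_grad():
            a = branch.stage2(o1)
            b = branch.stage2([o1[1], o1[0]])
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.data, y.data, atol=1e-12)

    def test_loss_oracle(self, rng):
        outs = [Tensor(rng.normal(size=(3, 6, 4))) for _ in range(2)]
        tgts = [Tensor(rng.normal(size=(3, 6, 4))) for _ in range(2)]
        brute = sum(np.mean((o.data - t.data) ** 2) for o, t in zip(outs, tgts))
        assert spatial_reconstruction_loss(outs, tgts).item() == pytest.approx(brute, rel=1e-12)
        assert spatial_reconstruction_loss(outs, outs).item() == 0.0


class TestCollapse:
    def test_mean_and_last(self, rng):
        x = rng.normal(size=(2, 7, 6, 4))
        np.testing.assert_allclose(collapse_time(x, "mean"), x.mean(axis=1))
        np.testing.assert_allclose(collapse_time(x, "last"), x[:, -1])
        with pytest.raises(ValueError):
            collapse_time(x, "median")

    def test_masked_channels_stay_zero_after_collapse(self, rng):
        x = rng.normal(size=(2, 7, 6, 4))
        x[:, :, 2, :] = 0.0
        assert np.all(collapse_time(x, "mean")[:, 2, :] == 0)
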