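"""Spatial masked-autoencoder branch over the electrode graph.

The branch consumes a per-window spatial frame (C, B) — the time-mean of
the (T, C, B) window (``time_collapse="last"`` takes the final step
instead).  A stack of graph convolutions over the distance-based electrode
adjacency encodes the frame; batch normalization yields *local* per-channel
features and mean pooling over channels yields the *global* feature used by
the subject discriminator.  Per-subject decoders run the same graph
convolutions but accumulate a running hidden state layer by layer (each
layer's activated output is added to the features aggregated so far), then
project back to (C, B).  Stage-1/stage-2 mixing and the loss
``L_srec = sum_i MSE(O_s2^i, S^i)`` mirror the temporal branch, with the
normalized unmasked frame ``S^i`` as target.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Linear, BatchNorm, mse

__all__ = ["SpatialBranch", "gcn_layer", "spatial_reconstruction_loss", "collapse_time"]


def collapse_time(x: np.ndarray, mode: str = "mean") -> np.ndarray:
    """(…, T, C, B) window -> (…, C, B) spatial frame."""
    if mode == "mean":
        return np.asarray(x).mean(axis=-3)
    if mode == "last":
        return np.asarray(x)[..., -1, :, :]
    raise ValueError(f"unknown time_collapse mode: {mode}")


def gcn_layer(H: Tensor, L_op: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """One graph convolution: L · H · W + b (activation applied by callers)."""
    return L_op @ H @ W + b


class GCNStack(Module):
    """Encoder stack: graph convolutions with ReLU between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        bound = lambda f: 1.0 / np.sqrt(f)
        self.Ws = [
            Tensor(rng.uniform(-bound(a), bound(a), size=(a, b)), requires_grad=True)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.bs = [Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]]

    def __call__(self, H: Tensor, L_op: Tensor) -> Tensor:
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            H = gcn_layer(H, L_op, W, b)
            if i < len(self.Ws) - 1:
                H = H.relu()
        return H


class SpatialDecoder(Module):
    """Graph-convolution decoder with hidden-state accumulation.

    A zero-initialized hidden state collects each layer's activated,
    batch-normalized graph-convolution output, so earlier layers' aggregated
    features stay present in every later layer's input; a final linear head
    (shared across channels) maps F back to B.  ``hidden_state=False`` is
    the ablation that turns this into a plain feed-forward GCN stack.
    """

    def __init__(self, hidden: int, n_bands: int, n_layers: int, rng: np.random.Generator, hidden_state: bool = True):
        bound = 1.0 / np.sqrt(hidden)
        self.Ws = [
            Tensor(rng.uniform(-bound, bound, size=(hidden, hidden)), requires_grad=True)
            for _ in range(n_layers)
        ]
        self.bs = [Tensor(np.zeros(hidden), requires_grad=True) for _ in range(n_layers)]
        self.bns = [BatchNorm(hidden) for _ in range(n_layers)]
        self.head = Linear(hidden, n_bands, rng)
        self.hidden_state = hidden_state

    def __call__(self, x_local: Tensor, L_op: Tensor) -> Tensor:
        h = x_local
        accum = None  # H_hidden^0 = 0
        for W, b, bn in zip(self.Ws, self.bs, self.bns):
            out = bn(gcn_layer(h, L_op, W, b)).relu()
            if self.hidden_state:
                h = out if accum is None else accum + out
                accum = h
            else:
                h = out
        return self.head(h)


class SpatialBranch(Module):
    def __init__(
        self,
        n_subjects: int,
        operator: np.ndarray,
        n_bands: int,
        hidden: int = 64,
        n_layers: int = 2,
        time_collapse: str = "mean",
        hidden_state: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.L_op = Tensor(np.asarray(operator))
        self.n_subjects = n_subjects
        self.time_collapse = time_collapse
        self.encoder = GCNStack([n_bands] + [hidden] * n_layers, rng)
        self.enc_bn = BatchNorm(hidden)
        self.decoders = [
            SpatialDecoder(hidden, n_bands, n_layers, rng, hidden_state=hidden_state)
            for _ in range(n_subjects)
        ]

    def frame(self, x: np.ndarray) -> np.ndarray:
        return collapse_time(x, self.time_collapse)

    def encode(self, frame: Tensor) -> tuple[Tensor, Tensor]:
        """(batch, C, B) -> (local (batch, C, F), global (batch, F))."""
        local = self.enc_bn(self.encoder(frame, self.L_op))
        global_feat = local.mean(axis=1)
        return local, global_feat

    def stage1(self, masked_frames: list[Tensor]) -> tuple[list[Tensor], list[Tensor]]:
        if len(masked_frames) != self.n_subjects:
            raise ValueError(f"expected {self.n_subjects} subject tensors, got {len(masked_frames)}")
        outputs, globals_ = [], []
        for i, f in enumerate(masked_frames):
            local, g = self.encode(f)
            globals_.append(g)
            outputs.append(self.decoders[i](local, self.L_op))
        return outputs, globals_

    def stage2(self, stage1_outputs: list[Tensor]) -> list[Tensor]:
        mixed = stage1_outputs[0]
        for o in stage1_outputs[1:]:
            mixed = mixed + o
        local, _ = self.encode(mixed)
        return [dec(local, self.L_op) for dec in self.decoders]


def spatial_reconstruction_loss(stage2_outputs: list[Tensor], targets: list[Tensor]) -> Tensor:
    """L_srec: per-subject MSE against normalized unmasked frames, summed."""
    total = mse(stage2_outputs[0], targets[0])
    for o, s in zip(stage2_outputs[1:], targets[1:]):
        total = total + mse(o, s)
    return total
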