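"""Temporal masked-autoencoder branch.

A single recurrent encoder ``E_t`` is shared by all N source subjects; each
subject i owns a decoder ``D_t^i``.  Training proceeds in two stages with
the *same* parameters:

* stage 1 — each subject's masked, attention-weighted window is encoded and
  decoded back to a full (T, C, B) tensor ``O_t1^i``;
* stage 2 — the stage-1 outputs of all subjects are summed into one mixed
  feature (a mixup-style augmentation across subjects sharing the emotion
  label), re-encoded, and decoded per subject into ``O_t2^i``.

The reconstruction target ``r^i`` is the attention-weighted *unmasked*
window of subject i with the same label, and the branch loss is
``L_trec = sum_i MSE(O_t2^i, r^i)``.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Linear, GRU, mse, stack

__all__ = ["TemporalBranch", "temporal_reconstruction_loss"]


class TimeAttention(Module):
    """Additive importance weighting over time steps.

    Scores each (C*B) frame with ``v . tanh(W f + b)``, softmax-normalizes
    over T, and rescales the weights to mean 1 so that a constant scorer
    (e.g. zero weights) reproduces the input exactly.  Scorer weights are
    initialized at zero: attention starts neutral and is learned.
    """

    def __init__(self, frame_dim: int, hidden: int = 16):
        self.W = Tensor(np.zeros((frame_dim, hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(hidden), requires_grad=True)
        self.v = Tensor(np.zeros(hidden), requires_grad=True)

    def weights(self, flat: Tensor) -> Tensor:
        """(batch, T) weights with mean 1 across T."""
        T = flat.shape[1]
        scores = (flat @ self.W + self.b).tanh() @ self.v  # (batch, T)
        shift = Tensor(scores.data.max(axis=1, keepdims=True))
        e = (scores - shift).exp()
        w = e / e.sum(axis=1, keepdims=True)
        return w * float(T)

    def __call__(self, x: Tensor) -> Tensor:
        batch, T = x.shape[0], x.shape[1]
        flat = x.reshape(batch, T, -1)
        w = self.weights(flat)
        return x * w.reshape(batch, T, 1, 1)


class SeqDecoder(Module):
    """Mirror of the encoder: unrolls T steps from the encoder context.

    The encoder's final hidden state is fed as input at every step (initial
    decoder state zero), each step's hidden state is mapped to a (C, B)
    frame by a linear head, and the frame order is reversed — the decoder
    reconstructs the sequence back-to-front, opposite to the encoder's
    read direction.
    """

    def __init__(self, hidden: int, n_channels: int, n_bands: int, rng: np.random.Generator):
        self.gru = GRU(hidden, hidden, rng)
        self.head = Linear(hidden, n_channels * n_bands, rng)
        self.n_channels = n_channels
        self.n_bands = n_bands

    def __call__(self, context: Tensor, T: int) -> Tensor:
        batch = context.shape[0]
        inputs = stack([context] * T, axis=1)  # (batch, T, H)
        states, _ = self.gru(inputs)
        frames = self.head(states.reshape(batch * T, -1))
        out = frames.reshape(batch, T, self.n_channels, self.n_bands)
        idx = np.arange(T)[::-1].copy()
        return out[:, idx, :, :]


class TemporalBranch(Module):
    def __init__(
        self,
        n_subjects: int,
        n_channels: int,
        n_bands: int,
        hidden: int = 64,
        attention: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        frame_dim = n_channels * n_bands
        self.n_subjects = n_subjects
        self.use_attention = attention
        self.attn = TimeAttention(frame_dim)
        self.encoder = GRU(frame_dim, hidden, rng)
        self.decoders = [SeqDecoder(hidden, n_channels, n_bands, rng) for _ in range(n_subjects)]

    # -- pieces ---------------------------------------------------------------
    def attention_weight(self, x: Tensor) -> Tensor:
        return self.attn(x) if self.use_attention else x

    def encode(self, x: Tensor) -> Tensor:
        """(batch, T, C, B) -> final hidden state (batch, H)."""
        batch, T = x.shape[0], x.shape[1]
        _, h = self.encoder(x.reshape(batch, T, -1))
        return h

    # -- stages ---------------------------------------------------------------
    def stage1(self, masked: list[Tensor]) -> tuple[list[Tensor], list[Tensor]]:
        """Per-subject masked inputs -> (stage-1 outputs, encoder states)."""
        if len(masked) != self.n_subjects:
            raise ValueError(f"expected {self.n_subjects} subject tensors, got {len(masked)}")
        outputs, states = [], []
        T = masked[0].shape[1]
        for i, x_m in enumerate(masked):
            h = self.encode(self.attention_weight(x_m))
            states.append(h)
            outputs.append(self.decoders[i](h, T))
        return outputs, states

    def stage2(self, stage1_outputs: list[Tensor]) -> list[Tensor]:
        """Sum-mix the stage-1 reconstructions, re-encode, decode per subject."""
        mixed = stage1_outputs[0]
        for o in stage1_outputs[1:]:
            mixed = mixed + o
        T = mixed.shape[1]
        h = self.encode(mixed)
        return [dec(h, T) for dec in self.decoders]


def temporal_reconstruction_loss(stage2_outputs: list[Tensor], targets: list[Tensor]) -> Tensor:
    """L_trec: MSE per subject (mean over elements), summed over subjects."""
    total = mse(stage2_outputs[0], targets[0])
    for o, r in zip(stage2_outputs[1:], targets[1:]):
        total = total + mse(o, r)
    return total
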