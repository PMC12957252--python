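"""Loss functions and probability ops shared by both training stages."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "softmax",
    "log_softmax",
    "mse",
    "nll_loss",
    "cross_entropy",
    "symmetric_kl",
]

_EPS = 1e-8  # probability floor inside KL terms


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (constant) rowwise max for numerical stability
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def mse(pred: Tensor, target: Tensor) -> Tensor:
    """Mean squared error over every element."""
    return ((pred - target) ** 2).mean()


def nll_loss(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Negative log-likelihood of integer labels; batch-mean reduction."""
    labels = np.asarray(labels)
    n = log_probs.shape[0]
    picked = log_probs[np.arange(n), labels]
    return -picked.mean()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    return nll_loss(log_softmax(logits, axis=-1), labels)


def symmetric_kl(p: Tensor, q: Tensor) -> Tensor:
    """Symmetric Kullback-Leibler divergence KL(p||q) + KL(q||p).

    ``p`` and ``q`` are probability vectors along the last axis
    (batch-mean reduction over leading axes).  Probabilities are floored at
    1e-8 so the divergence stays finite when one view assigns (numerically)
    zero mass to a class the other view supports.
    """
    pc = p.clip_min(_EPS)
    qc = q.clip_min(_EPS)
    kl_pq = (pc * (pc.log() - qc.log())).sum(axis=-1)
    kl_qp = (qc * (qc.log() - pc.log())).sum(axis=-1)
    return (kl_pq + kl_qp).mean()
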