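"""Subject-adversarial domain generalization (DG-DANN).

A subject discriminator tries to identify which source subject produced an
encoder feature; a gradient reversal layer (GRL) in front of it flips (and
scales by λ) the gradient flowing back into the encoder, so minimizing the
discriminator's cross-entropy simultaneously trains the encoder to *erase*
subject identity.  One discriminator per branch (temporal feature space and
spatial global-feature space differ), applied only to stage-1 encoder
outputs.  The stored adversarial losses are the plain nonnegative
cross-entropies; the −λ of the minimax objective lives structurally in the
GRL's backward pass.

λ follows the standard domain-adversarial ramp
``λ(p) = 2 / (1 + exp(−10 p)) − 1`` over training progress p ∈ [0, 1]
(a fixed value may be configured instead).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, MLP, concat, grad_reversal, cross_entropy

__all__ = ["SubjectDiscriminator", "grl_lambda", "adversarial_loss", "pretrain_total"]


def grl_lambda(progress: float) -> float:
    """Ramp from 0 to 1 with training progress ``p`` in [0, 1]."""
    p = min(max(progress, 0.0), 1.0)
    return 2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0


class SubjectDiscriminator(Module):
    """2-layer perceptron over N subject IDs, entered through a GRL."""

    def __init__(self, feature_dim: int, n_subjects: int, hidden: int = 64, rng=None):
        rng = rng or np.random.default_rng()
        self.net = MLP(feature_dim, hidden, n_subjects, rng)
        self.n_subjects = n_subjects

    def logits(self, features: Tensor, lam: float) -> Tensor:
        return self.net(grad_reversal(features, lam))


def adversarial_loss(
    disc: SubjectDiscriminator,
    per_subject_features: list[Tensor],
    lam: float,
) -> Tensor:
    """Batch-mean subject-ID cross-entropy through the GRL.

    ``per_subject_features[i]`` holds the stage-1 encoder features of
    subject ``i`` (any batch size); the label of every row is ``i``.
    """
    feats = concat(per_subject_features, axis=0)
    labels = np.concatenate(
        [np.full(f.shape[0], i) for i, f in enumerate(per_subject_features)]
    )
    if labels.max() >= disc.n_subjects:
        raise ValueError("subject id out of discriminator range")
    return cross_entropy(disc.logits(feats, lam), labels)


def pretrain_total(
    L_trec: Tensor,
    L_srec: Tensor,
    L_tadv: Tensor,
    L_sadv: Tensor,
    alpha: float = 0.5,
    beta: float = 0.05,
    gamma: float = 0.05,
) -> Tensor:
    """Pre-training objective: L_trec + α·L_srec + β·L_tadv + γ·L_sadv.

    α weights the spatial reconstruction (0.5 in the 3-class profile, 0.1 in
    the 4-class profile); β = γ = 0.05 balance the adversarial terms.
    """
    for name, w in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if w < 0:
            raise ValueError(f"{name} must be nonnegative")
    return L_trec + alpha * L_srec + beta * L_tadv + gamma * L_sadv
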