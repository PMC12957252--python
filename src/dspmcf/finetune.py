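"""Multi-view consistency fine-tuning head.

After pre-training, the decoders are discarded; the two encoders are fused
by a learnable scalar μ (initialized at 0.5 for an unbiased prior):

    F_fused = μ · E_t(x) + (1 − μ) · E_s(x)

computed for both the masked view ``x_m`` and the unmasked view ``x_um`` of
the same window.  A linear softmax classifier produces per-view emotion
log-probabilities; both views incur a supervised NLL, and a symmetric KL
divergence between the two predictive distributions (the multi-view
consistency loss L_MVC) aligns them:

    L_fine_tune = L_mcls + L_umcls + θ · L_MVC
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Linear, log_softmax, nll_loss, symmetric_kl

__all__ = ["FusionClassifier", "fuse", "mvc_loss", "finetune_total", "classification_losses"]


def fuse(temporal_feat: Tensor, spatial_feat: Tensor, mu: Tensor | float) -> Tensor:
    """μ-weighted combination of the two encoder features (equal dims)."""
    if temporal_feat.shape != spatial_feat.shape:
        raise ValueError(
            f"feature dimension mismatch: {temporal_feat.shape} vs {spatial_feat.shape}"
        )
    if not isinstance(mu, Tensor):
        mu = Tensor(np.asarray(mu))
    return mu * temporal_feat + (1.0 - mu) * spatial_feat


class FusionClassifier(Module):
    """Learnable fusion weight μ plus a linear softmax emotion classifier."""

    def __init__(self, feature_dim: int, n_classes: int, mu_init: float = 0.5, rng=None):
        rng = rng or np.random.default_rng()
        self.mu = Tensor(np.asarray(mu_init, dtype=np.float64), requires_grad=True)
        self.head = Linear(feature_dim, n_classes, rng)

    def fused(self, temporal_feat: Tensor, spatial_feat: Tensor) -> Tensor:
        return fuse(temporal_feat, spatial_feat, self.mu)

    def log_probs(self, fused_features: Tensor) -> Tensor:
        """Per-sample class log-probabilities (exp sums to 1)."""
        return log_softmax(self.head(fused_features), axis=-1)


def mvc_loss(log_probs_masked: Tensor, log_probs_unmasked: Tensor) -> Tensor:
    """Symmetric KL between the masked-view and unmasked-view predictions.

    Nonnegative, zero iff the two distributions coincide, and invariant
    under exchanging the views; batch-mean reduction.
    """
    return symmetric_kl(log_probs_masked.exp(), log_probs_unmasked.exp())


def finetune_total(L_mcls: Tensor, L_umcls: Tensor, L_mvc: Tensor, theta: float = 1.0) -> Tensor:
    """Fine-tuning objective: L_mcls + L_umcls + θ·L_MVC (θ = 0 drops MVC)."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    return L_mcls + L_umcls + theta * L_mvc


def classification_losses(
    log_probs_masked: Tensor, log_probs_unmasked: Tensor, labels: np.ndarray
) -> tuple[Tensor, Tensor]:
    """Per-view supervised NLL (batch mean): (L_mcls, L_umcls)."""
    labels = np.asarray(labels)
    c = log_probs_masked.shape[-1]
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range")
    return nll_loss(log_probs_masked, labels), nll_loss(log_probs_unmasked, labels)
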