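"""Full model assembly: both branches, discriminators, fusion classifier.

The ablation switches mirror the framework's component study:
``use_spatial=False`` removes the entire spatial branch (fusion then passes
the temporal feature through unchanged), ``use_temporal=False`` removes the
temporal branch, and ``hidden_state=False`` strips the decoder's
hidden-state accumulator.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, no_grad
from .temporal import TemporalBranch
from .spatial import SpatialBranch
from .adversarial import SubjectDiscriminator
from .finetune import FusionClassifier

__all__ = ["DSPMCF"]


class DSPMCF(Module):
    def __init__(
        self,
        n_subjects: int,
        n_channels: int,
        n_bands: int,
        n_classes: int,
        graph_operator: np.ndarray,
        hidden: int = 64,
        attention: bool = True,
        spatial_layers: int = 2,
        time_collapse: str = "mean",
        hidden_state: bool = True,
        use_temporal: bool = True,
        use_spatial: bool = True,
        mu_init: float = 0.5,
        seed: int = 3,
    ):
        if not (use_temporal or use_spatial):
            raise ValueError("at least one branch must be enabled")
        rng = np.random.default_rng(seed)
        self.n_subjects = n_subjects
        self.n_classes = n_classes
        self.use_temporal = use_temporal
        self.use_spatial = use_spatial
        self.hidden = hidden
        if use_temporal:
            self.temporal = TemporalBranch(
                n_subjects, n_channels, n_bands, hidden=hidden, attention=attention, rng=rng
            )
            self.t_disc = SubjectDiscriminator(hidden, n_subjects, hidden=hidden, rng=rng)
        if use_spatial:
            self.spatial = SpatialBranch(
                n_subjects,
                graph_operator,
                n_bands,
                hidden=hidden,
                n_layers=spatial_layers,
                time_collapse=time_collapse,
                hidden_state=hidden_state,
                rng=rng,
            )
            self.s_disc = SubjectDiscriminator(hidden, n_subjects, hidden=hidden, rng=rng)
        self.fusion = FusionClassifier(hidden, n_classes, mu_init=mu_init, rng=rng)

    # -- feature extraction ----------------------------------------------------
    def encode_views(self, x: np.ndarray) -> Tensor:
        """(batch, T, C, B) -> fused (batch, H) feature for classification."""
        xt = Tensor(np.asarray(x))
        if self.use_temporal:
            h_t = self.temporal.encode(self.temporal.attention_weight(xt))
        if self.use_spatial:
            frame = Tensor(self.spatial.frame(np.asarray(x)))
            _, h_s = self.spatial.encode(frame)
        if self.use_temporal and self.use_spatial:
            return self.fusion.fused(h_t, h_s)
        return h_t if self.use_temporal else h_s

    def predict_log_probs(self, x: np.ndarray) -> Tensor:
        return self.fusion.log_probs(self.encode_views(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard class predictions without building a gradient tape."""
        with no_grad():
            lp = self.predict_log_probs(x)
        return lp.data.argmax(axis=-1)

    def export_features(self, x: np.ndarray) -> np.ndarray:
        """Fused feature matrix for external visualization (e.g. t-SNE)."""
        with no_grad():
            f = self.encode_views(x)
        return f.data.copy()

    def finetune_parameters(self, freeze_encoders: bool = False):
        """Parameters optimized during fine-tuning (decoders are discarded)."""
        params = list(self.fusion.parameters())
        if not freeze_encoders:
            if self.use_temporal:
                params += self.temporal.attn.parameters() + self.temporal.encoder.parameters()
            if self.use_spatial:
                params += self.spatial.encoder.parameters() + self.spatial.enc_bn.parameters()
        return params

    def pretrain_parameters(self):
        params = []
        if self.use_temporal:
            params += self.temporal.parameters() + self.t_disc.parameters()
        if self.use_spatial:
            params += self.spatial.parameters() + self.s_disc.parameters()
        return params
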