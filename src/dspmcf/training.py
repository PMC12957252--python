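"""Training loops, leave-one-subject-out evaluation, ablation suite.

The protocol is strict domain generalization: for each LOSO fold the target
subject contributes nothing to any training-time computation — not the
normalization statistics, not the discriminator labels, not the batches.
Pre-training optimizes the masked dual-branch reconstruction plus the
subject-adversarial terms; fine-tuning optimizes the two-view supervised
loss plus the multi-view consistency term with save-best checkpoint
selection on a held-out fraction of the *source* pool.  Test-time
evaluation masks the target data with the same dynamic strategy and
averages accuracy over several mask draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Tensor, Adam, no_grad
from .data import FeatureDataset, Normalizer
from .masking import MaskSampler, apply_mask, DEFAULT_GRID
from .graph import ElectrodeGraph, normalize_coords
from .model import DSPMCF
from .temporal import temporal_reconstruction_loss
from .spatial import spatial_reconstruction_loss
from .adversarial import adversarial_loss, grl_lambda, pretrain_total
from .finetune import classification_losses, mvc_loss, finetune_total

__all__ = [
    "RunConfig",
    "EvalReport",
    "loso_split",
    "pretrain",
    "finetune",
    "evaluate",
    "prepare_fold",
    "run_fold",
    "save_checkpoint",
    "load_checkpoint",
    "run_loso",
    "run_ablation_suite",
]


@dataclass
class RunConfig:
    """All tunables of a run.  Profiles:

    * ``"seed"``  — 3-class conditions: T=30, batch 512, 120/200 epochs, α=0.5
    * ``"seed4"`` — 4-class conditions: T=10, batch 256, 200/200 epochs, α=0.1
    * ``"custom"`` (default) — scaled-down synthetic conditions.
    """

    window_length: int = 8
    batch_size: int = 16  # tuples in pre-training, samples in fine-tuning
    pretrain_epochs: int = 20
    finetune_epochs: int = 30
    lr: float = 1e-3
    weight_decay: float = 5e-4
    alpha: float = 0.5
    beta: float = 0.05
    gamma: float = 0.05
    theta: float = 1.0
    mask_grid: tuple = DEFAULT_GRID
    mask_mode: str = "dynamic"  # dynamic | fixed | none
    eval_seed: int = 97
    n_eval_draws: int = 5
    hidden: int = 64
    attention: bool = True
    spatial_layers: int = 2
    time_collapse: str = "mean"
    hidden_state: bool = True
    use_temporal: bool = True
    use_spatial: bool = True
    freeze_encoders: bool = False
    mu_init: float = 0.5
    lambda_mode: str = "schedule"  # "schedule" or "fixed"
    lambda_fixed: float = 1.0
    val_fraction: float = 0.1
    delta: float = 8.0
    seed: int = 3

    @staticmethod
    def profile(name: str, **overrides) -> "RunConfig":
        base = {
            "seed": dict(window_length=30, batch_size=512, pretrain_epochs=120,
                         finetune_epochs=200, alpha=0.5),
            "seed4": dict(window_length=10, batch_size=256, pretrain_epochs=200,
                          finetune_epochs=200, alpha=0.1),
            "custom": dict(),
        }
        if name not in base:
            raise ValueError(f"unknown profile: {name}")
        kwargs = {**base[name], **overrides}
        cfg = RunConfig(**kwargs)
        if cfg.pretrain_epochs < 1 or cfg.finetune_epochs < 1:
            raise ValueError("epochs must be >= 1")
        return cfg

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class EvalReport:
    """Per-fold evaluation result (accuracies as fractions in [0, 1])."""

    target_subject: int
    masked_accuracy: float
    masked_accuracy_per_draw: list[float]
    unmasked_accuracy: float
    confusion: np.ndarray  # (c, c) rows = true class, summed over mask draws
    view_divergence: float  # mean symmetric KL between masked/unmasked predictions
    n_samples: int
    missing_classes: list[int] = field(default_factory=list)
    # per-sample table from the first mask draw: true label, predicted
    # label, then one probability column per class
    predictions: np.ndarray | None = field(default=None, repr=False)

    def predictions_table(self) -> str:
        """Delimited text: sample id, true, predicted, per-class probabilities."""
        c = self.confusion.shape[0]
        header = "sample\ttrue\tpredicted\t" + "\t".join(f"p_class{k}" for k in range(c))
        rows = [header]
        for i, row in enumerate(self.predictions):
            probs = "\t".join(f"{p:.4f}" for p in row[2:])
            rows.append(f"{i}\t{int(row[0])}\t{int(row[1])}\t{probs}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# protocol


def loso_split(ds: FeatureDataset) -> list[tuple[list[int], int]]:
    """One fold per subject: (source subject ids, target subject id)."""
    ids = [s.subject_id for s in ds.subjects]
    if len(ids) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([i for i in ids if i != target], target) for target in ids]


def _lam(cfg: RunConfig, progress: float) -> float:
    return cfg.lambda_fixed if cfg.lambda_mode == "fixed" else grl_lambda(progress)


class _TupleBatcher:
    """Label-aligned tuples: (label k; one random sample per subject with label k)."""

    def __init__(self, ds: FeatureDataset, rng: np.random.Generator):
        self.ds = ds
        self.rng = rng
        self.by_class = []
        for s in ds.subjects:
            idx = {k: np.flatnonzero(s.labels == k) for k in range(ds.n_classes)}
            empty = [k for k, v in idx.items() if len(v) == 0]
            if empty:
                raise ValueError(f"subject {s.subject_id} missing classes {empty}")
            self.by_class.append(idx)

    def batch(self, n_tuples: int) -> tuple[list[np.ndarray], np.ndarray]:
        labels = self.rng.integers(self.ds.n_classes, size=n_tuples)
        per_subject = []
        for s, idx in zip(self.ds.subjects, self.by_class):
            rows = [self.rng.choice(idx[k]) for k in labels]
            per_subject.append(s.features[rows])
        return per_subject, labels


def pretrain(
    model: DSPMCF,
    source: FeatureDataset,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
    audit_sink: list | None = None,
) -> list[dict]:
    """Masked dual-branch reconstruction + subject-adversarial pre-training.

    ``source`` must already be normalized.  Returns per-epoch loss records.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    model.train()
    batcher = _TupleBatcher(source, rng)
    sampler = MaskSampler(source.n_channels, cfg.mask_grid, cfg.mask_mode,
                          seed=int(rng.integers(2**31)))
    opt = Adam(model.pretrain_parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    min_samples = min(s.n_samples for s in source.subjects)
    n_batches = max(1, min_samples // cfg.batch_size)
    history = []
    for epoch in range(cfg.pretrain_epochs):
        lam = _lam(cfg, epoch / max(cfg.pretrain_epochs - 1, 1))
        sums = dict.fromkeys(("L_trec", "L_srec", "L_tadv", "L_sadv", "total"), 0.0)
        for _ in range(n_batches):
            xs, _labels = batcher.batch(cfg.batch_size)
            if audit_sink is not None:
                audit_sink.extend(xs)
            spec = sampler()
            masked = [apply_mask(x, spec) if spec is not None else x for x in xs]

            zero = Tensor(np.zeros(()))
            L_trec = L_srec = L_tadv = L_sadv = zero
            if model.use_temporal:
                xm_t = [Tensor(m) for m in masked]
                o1, states = model.temporal.stage1(xm_t)
                o2 = model.temporal.stage2(o1)
                targets = [model.temporal.attention_weight(Tensor(x)) for x in xs]
                L_trec = temporal_reconstruction_loss(o2, targets)
                L_tadv = adversarial_loss(model.t_disc, states, lam)
            if model.use_spatial:
                frames_m = [Tensor(model.spatial.frame(m)) for m in masked]
                o1s, globals_ = model.spatial.stage1(frames_m)
                o2s = model.spatial.stage2(o1s)
                targets_s = [Tensor(model.spatial.frame(x)) for x in xs]
                L_srec = spatial_reconstruction_loss(o2s, targets_s)
                L_sadv = adversarial_loss(model.s_disc, globals_, lam)

            total = pretrain_total(L_trec, L_srec, L_tadv, L_sadv,
                                   alpha=cfg.alpha, beta=cfg.beta, gamma=cfg.gamma)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"pre-training diverged at epoch {epoch}: "
                    f"trec={L_trec.item():.3g} srec={L_srec.item():.3g}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            for key, t in (("L_trec", L_trec), ("L_srec", L_srec),
                           ("L_tadv", L_tadv), ("L_sadv", L_sadv), ("total", total)):
                sums[key] += t.item()
        rec = {k: v / n_batches for k, v in sums.items()}
        rec.update(epoch=epoch, lam=lam)
        history.append(rec)
    return history


def _stratified_split(features, labels, subjects, frac, rng):
    """Hold out ``frac`` of samples stratified by (subject, label)."""
    val_idx = []
    for s in np.unique(subjects):
        for k in np.unique(labels):
            pool = np.flatnonzero((subjects == s) & (labels == k))
            n_val = max(1, int(round(frac * len(pool)))) if len(pool) > 1 else 0
            val_idx.extend(rng.permutation(pool)[:n_val])
    val = np.zeros(len(labels), dtype=bool)
    val[val_idx] = True
    return ~val, val


def finetune(
    model: DSPMCF,
    source: FeatureDataset,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
    audit_sink: list | None = None,
) -> list[dict]:
    """Two-view supervised fine-tuning with the consistency loss and save-best.

    Validation = ``val_fraction`` of source samples, stratified by subject
    and label, scored on the masked view with a fixed-seed mask stream; the
    parameters with the highest validation accuracy are restored at the end.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    model.train()
    feats = np.concatenate([s.features for s in source.subjects])
    labels = np.concatenate([s.labels for s in source.subjects])
    subj = np.concatenate([np.full(s.n_samples, s.subject_id) for s in source.subjects])
    # the validation split depends only on the config seed, so save-best
    # selection is reproducible independently of the training rng stream
    split_rng = np.random.default_rng(cfg.seed + 10007)
    tr, va = _stratified_split(feats, labels, subj, cfg.val_fraction, split_rng)
    x_tr, y_tr = feats[tr], labels[tr]
    x_va, y_va = feats[va], labels[va]

    sampler = MaskSampler(source.n_channels, cfg.mask_grid, cfg.mask_mode,
                          seed=int(rng.integers(2**31)))
    opt = Adam(model.finetune_parameters(cfg.freeze_encoders), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    history, best = [], (-1.0, None)
    n = len(x_tr)
    for epoch in range(cfg.finetune_epochs):
        order = rng.permutation(n)
        sums = dict.fromkeys(("L_mcls", "L_umcls", "L_mvc", "total"), 0.0)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            xb, yb = x_tr[rows], y_tr[rows]
            if audit_sink is not None:
                audit_sink.append(xb)
            xb_m, _spec = sampler.mask_batch(xb)
            lp_m = model.predict_log_probs(xb_m)
            lp_um = model.predict_log_probs(xb)
            L_mcls, L_umcls = classification_losses(lp_m, lp_um, yb)
            L_mvc = mvc_loss(lp_m, lp_um)
            total = finetune_total(L_mcls, L_umcls, L_mvc, theta=cfg.theta)
            if not np.isfinite(total.item()):
                raise RuntimeError(f"fine-tuning diverged at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for key, t in (("L_mcls", L_mcls), ("L_umcls", L_umcls),
                           ("L_mvc", L_mvc), ("total", total)):
                sums[key] += t.item()
            n_batches += 1
        val_acc = _masked_accuracy(model, x_va, y_va, cfg) if len(x_va) else 0.0
        rec = {k: v / n_batches for k, v in sums.items()}
        rec.update(epoch=epoch, mu=float(model.fusion.mu.data), val_acc=val_acc)
        history.append(rec)
        if val_acc > best[0]:
            best = (val_acc, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return history


def _masked_accuracy(model: DSPMCF, x: np.ndarray, y: np.ndarray, cfg: RunConfig,
                     n_draws: int = 3) -> float:
    """Masked-view accuracy averaged over ``n_draws`` fixed mask streams.

    Averaging keeps the save-best selection metric from being dominated by
    a single lucky mask draw on a small validation set.
    """
    model.eval()
    correct, total = 0, 0
    for d in range(n_draws):
        sampler = MaskSampler(x.shape[2], cfg.mask_grid, cfg.mask_mode, seed=cfg.eval_seed + d)
        for start in range(0, len(x), 256):
            xb = x[start : start + 256]
            xb_m, _ = sampler.mask_batch(xb)
            correct += int((model.predict(xb_m) == y[start : start + 256]).sum())
            total += len(xb)
    model.train()
    return correct / total


def evaluate(model: DSPMCF, target: FeatureDataset, cfg: RunConfig) -> EvalReport:
    """Score the (normalized) target subject under test-time channel masking.

    Accuracy is averaged over ``n_eval_draws`` independent mask streams;
    the unmasked accuracy and the mean masked/unmasked prediction
    divergence are reported alongside for diagnostics.
    """
    assert target.n_subjects == 1
    model.eval()
    rec = target.subjects[0]
    x, y = rec.features, rec.labels
    c = target.n_classes
    confusion = np.zeros((c, c), dtype=int)
    draws = []
    div_sum, div_n = 0.0, 0
    pred_rows = []
    for d in range(cfg.n_eval_draws):
        sampler = MaskSampler(x.shape[2], cfg.mask_grid, cfg.mask_mode,
                              seed=cfg.eval_seed + d)
        correct = 0
        for start in range(0, len(x), 256):
            xb, yb = x[start : start + 256], y[start : start + 256]
            xb_m, _ = sampler.mask_batch(xb)
            with no_grad():
                lp_m = model.predict_log_probs(xb_m)
                lp_um = model.predict_log_probs(xb)
            pred = lp_m.data.argmax(axis=-1)
            correct += int((pred == yb).sum())
            np.add.at(confusion, (yb, pred), 1)
            p_m, p_um = np.exp(lp_m.data), np.exp(lp_um.data)
            if d == 0:
                pred_rows.append(np.column_stack([yb, pred, p_m]))
            eps = 1e-8
            kl = lambda a, b: (np.maximum(a, eps) * (np.log(np.maximum(a, eps)) - np.log(np.maximum(b, eps)))).sum(-1)
            div_sum += float((kl(p_m, p_um) + kl(p_um, p_m)).sum())
            div_n += len(yb)
        draws.append(correct / len(x))
    with no_grad():
        lp = model.predict_log_probs(x)
    unmasked_acc = float((lp.data.argmax(axis=-1) == y).mean())
    missing = [k for k in range(c) if not np.any(y == k)]
    return EvalReport(
        target_subject=rec.subject_id,
        masked_accuracy=float(np.mean(draws)),
        masked_accuracy_per_draw=draws,
        unmasked_accuracy=unmasked_acc,
        confusion=confusion,
        view_divergence=div_sum / max(div_n, 1),
        n_samples=len(x),
        missing_classes=missing,
        predictions=np.concatenate(pred_rows) if pred_rows else None,
    )


# ---------------------------------------------------------------------------
# LOSO driver


def prepare_fold(
    ds: FeatureDataset,
    source_ids: list[int],
    target_id: int,
    cfg: RunConfig,
    graph: ElectrodeGraph | None = None,
) -> tuple[DSPMCF, FeatureDataset, FeatureDataset, Normalizer, ElectrodeGraph]:
    """Build the model and source/target views of one fold.

    Normalization statistics are fitted on the source subjects only and
    reused for the target subject.
    """
    source_raw = ds.subset(source_ids)
    target_raw = ds.subset([target_id])
    norm = Normalizer.fit(source_raw)  # source statistics only
    source = norm.transform(source_raw)
    target = norm.transform(target_raw)
    if graph is None:
        if ds.coords is not None:
            coords = normalize_coords(ds.coords)
        else:
            rng_g = np.random.default_rng(0)
            coords = normalize_coords(rng_g.normal(size=(ds.n_channels, 3)))
        graph = ElectrodeGraph.from_coords(coords, delta=cfg.delta)
    model = DSPMCF(
        n_subjects=len(source_ids),
        n_channels=ds.n_channels,
        n_bands=ds.n_bands,
        n_classes=ds.n_classes,
        graph_operator=graph.operator,
        hidden=cfg.hidden,
        attention=cfg.attention,
        spatial_layers=cfg.spatial_layers,
        time_collapse=cfg.time_collapse,
        hidden_state=cfg.hidden_state,
        use_temporal=cfg.use_temporal,
        use_spatial=cfg.use_spatial,
        mu_init=cfg.mu_init,
        seed=cfg.seed,
    )
    return model, source, target, norm, graph


def run_fold(
    ds: FeatureDataset,
    source_ids: list[int],
    target_id: int,
    cfg: RunConfig,
    graph: ElectrodeGraph | None = None,
    audit_sink: list | None = None,
) -> tuple[DSPMCF, EvalReport, dict]:
    """Train on the source subjects of one fold and score the target."""
    model, source, target, _norm, _graph = prepare_fold(ds, source_ids, target_id, cfg, graph)
    rng = np.random.default_rng(cfg.seed + 1000 * (target_id + 1))
    pre_hist = pretrain(model, source, cfg, rng=rng, audit_sink=audit_sink)
    ft_hist = finetune(model, source, cfg, rng=rng, audit_sink=audit_sink)
    report = evaluate(model, target, cfg)
    return model, report, {"pretrain": pre_hist, "finetune": ft_hist}


def run_loso(
    ds: FeatureDataset,
    cfg: RunConfig,
    graph: ElectrodeGraph | None = None,
) -> dict:
    """Full leave-one-subject-out sweep; accuracies reported in percent."""
    reports = []
    for source_ids, target_id in loso_split(ds):
        _, report, _ = run_fold(ds, source_ids, target_id, cfg, graph=graph)
        reports.append(report)
    masked = np.array([r.masked_accuracy for r in reports]) * 100
    unmasked = np.array([r.unmasked_accuracy for r in reports]) * 100
    return {
        "reports": reports,
        "per_subject": {r.target_subject: r.masked_accuracy * 100 for r in reports},
        "mean": float(masked.mean()),
        "std": float(masked.std()),
        "mean_unmasked": float(unmasked.mean()),
        "mean_view_divergence": float(np.mean([r.view_divergence for r in reports])),
    }


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: DSPMCF, norm: Normalizer, graph: ElectrodeGraph, cfg: RunConfig) -> None:
    """Persist model parameters + normalization stats + graph + config."""
    meta = {
        "n_subjects": model.n_subjects,
        "n_classes": model.n_classes,
        "use_temporal": model.use_temporal,
        "use_spatial": model.use_spatial,
        "hidden": model.hidden,
        "config": asdict(cfg),
    }
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(
        path,
        __meta__=json.dumps(meta),
        __norm_mean__=norm.mean,
        __norm_sd__=norm.sd,
        __operator__=graph.adjacency,  # adjacency stored; operator rebuilt
        **state,
    )


def load_checkpoint(path, n_channels: int, n_bands: int) -> tuple[DSPMCF, Normalizer, RunConfig]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = RunConfig(**meta["config"])
        cfg.mask_grid = tuple(cfg.mask_grid)
        norm = Normalizer(mean=z["__norm_mean__"], sd=z["__norm_sd__"])
        from .graph import normalized_operator

        operator = normalized_operator(z["__operator__"])
        model = DSPMCF(
            n_subjects=meta["n_subjects"],
            n_channels=n_channels,
            n_bands=n_bands,
            n_classes=meta["n_classes"],
            graph_operator=operator,
            hidden=meta["hidden"],
            attention=cfg.attention,
            spatial_layers=cfg.spatial_layers,
            time_collapse=cfg.time_collapse,
            hidden_state=cfg.hidden_state,
            use_temporal=meta["use_temporal"],
            use_spatial=meta["use_spatial"],
            mu_init=cfg.mu_init,
            seed=cfg.seed,
        )
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
        model.load_state_dict(state)
    return model, norm, cfg


ABLATION_VARIANTS = {
    "full": {},
    "w/o hidden": {"hidden_state": False},
    "w/o Spatial-branch": {"use_spatial": False},
    "w/o Temporal-branch": {"use_temporal": False},
    "w/o L_MVC": {"theta": 0.0},
}

MASK_STRATEGIES = {
    "dynamic(10,20,30)": {"mask_mode": "dynamic", "mask_grid": (0.1, 0.2, 0.3)},
    "dynamic(40,50,60)": {"mask_mode": "dynamic", "mask_grid": (0.4, 0.5, 0.6)},
    **{f"fixed {int(r*100)}%": {"mask_mode": "fixed", "mask_grid": (r,)} for r in
       (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)},
}


def run_ablation_suite(
    ds: FeatureDataset,
    cfg: RunConfig,
    graph: ElectrodeGraph | None = None,
    variants: list[str] | None = None,
    strategies: list[str] | None = None,
):
    """Component × masking-strategy sweep; one LOSO run per row.

    Returns a pandas DataFrame with mean/std accuracy in percent.
    """
    import pandas as pd
    from dataclasses import replace

    rows = []
    for vname in variants or list(ABLATION_VARIANTS):
        for sname in strategies or ["dynamic(10,20,30)"]:
            run_cfg = replace(cfg, **ABLATION_VARIANTS[vname], **MASK_STRATEGIES[sname])
            res = run_loso(ds, run_cfg, graph=graph)
            rows.append({"variant": vname, "masking": sname,
                         "mean": res["mean"], "std": res["std"]})
    return pd.DataFrame(rows)
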