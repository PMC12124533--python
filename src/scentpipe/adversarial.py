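"""Domain-adversarial classifier with gradient reversal.

A shared convolutional backbone embeds each scent image into a latent
vector.  Two heads sit on top: a disease head predicting the risk class
(Control / LowRisk / HighRisk) and a source head predicting the collection
site.  The source head's gradient flows into the backbone through a
gradient-reversal layer — identity in the forward pass, negation scaled by
lambda in the backward pass — so the backbone is trained to make the site
*hard* to read while keeping the risk class readable.  The objective being
minimized is the tug-of-war loss

    L_total(theta, lambda) = L_0(theta) - lambda * L_q(theta),

with lambda in [0, 1] trading disease accuracy against source-bias removal
(lambda = 0 recovers a plain classifier).  After training, the
residual-bias probe freezes the backbone and fits a fresh source classifier
on the latent features; its held-out accuracy is the package's quantitative
measure of how much source information survived debiasing.

The network stack is the in-package numpy kernel (:mod:`scentpipe._nn`);
everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    AvgPool2,
    BatchNorm1d,
    Conv3x3,
    Dense,
    Flatten,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .gcms_io import RISK_LEVELS

__all__ = [
    "AdvConfig",
    "ProbeConfig",
    "TrainedModel",
    "total_loss",
    "train_adversarial",
    "predict_risk",
    "latent_features",
    "residual_bias_probe",
    "save_model",
    "load_model",
]


def total_loss(l0: float, lq: float, lam: float) -> float:
    """The adversarial objective L0 - lambda * Lq (lambda in [0, 1])."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if not (np.isfinite(l0) and np.isfinite(lq)):
        raise ValueError("losses must be finite")
    return l0 - lam * lq


@dataclass
class AdvConfig:
    """Training configuration for the adversarial classifier.

    The source head is a linear classifier that is periodically refit to
    (L2-regularized) optimality on the current latent features — a maximally
    trained adversary, so the backbone can only raise the source loss by
    genuinely mixing the sources rather than by stepping over a lagging
    head's decision boundary.  ``lambda_schedule='ramp'`` holds lambda at 0
    for the first ``warmup_frac`` of training (letting the disease signal
    form) and then ramps it up to its configured value; the learning rate
    follows a cosine decay so the tug-of-war settles by the final epoch.
    """

    lam: float = 0.5
    backbone: str = "small_cnn"
    epochs: int = 45
    batch_size: int = 25
    lr: float = 2e-3
    seed: int = 0
    input_size: int = 32            # images are average-pooled to this side length
    feature_dim: int = 32
    lambda_schedule: str = "ramp"   # or "constant"
    warmup_frac: float = 0.25       # fraction of epochs before the ramp engages
    lr_decay: bool = True           # cosine decay of the main learning rate
    clip_norm: float = 5.0          # global gradient-norm clip (stabilizes the tug-of-war)
    adversary_refits_per_epoch: int = 2   # full refits of the source head per epoch
    adversary_C: float = 1.0        # L2 regularization of the refit source head
    class_weights: bool = False     # inverse-frequency weights on the disease loss
    block_source_grad: bool = False  # sever the source branch from the backbone

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.backbone == "resnet18":
            raise ValueError(
                "the resnet18 backbone is not available in this build; "
                "use the default small_cnn"
            )
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if 256 % self.input_size:
            raise ValueError("input_size must divide 256")


@dataclass
class ProbeConfig:
    """Configuration of the frozen-feature residual-bias probe."""

    n_folds: int = 5
    seed: int = 0
    max_iter: int = 2000
    C: float = 1.0


@dataclass
class TrainedModel:
    backbone: Sequential
    disease_head: Sequential
    source_head: Sequential
    cfg: AdvConfig
    risk_classes: tuple[str, ...]
    source_classes: tuple[str, ...]
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


def _build_small_cnn(cfg: AdvConfig, rng: np.random.Generator) -> Sequential:
    """Four conv blocks then a batch-normalized dense latent projection.

    The latent batch norm keeps every feature dimension at unit variance,
    so the adversarial branch cannot win by collapsing the latent space to
    a constant."""
    side = cfg.input_size // 8
    return Sequential(
        [
            Conv3x3(3, 8, rng), ReLU(), AvgPool2(),
            Conv3x3(8, 16, rng), ReLU(), AvgPool2(),
            Conv3x3(16, 32, rng), ReLU(), AvgPool2(),
            Conv3x3(32, 32, rng), ReLU(),
            Flatten(),
            Dense(32 * side * side, cfg.feature_dim, rng),
            BatchNorm1d(cfg.feature_dim),
        ]
    )


def _build_heads(
    cfg: AdvConfig, n_sources: int, rng: np.random.Generator
) -> tuple[Sequential, Sequential]:
    disease = Sequential([Dense(cfg.feature_dim, len(RISK_LEVELS), rng)])
    source = Sequential([Dense(cfg.feature_dim, n_sources, rng)])
    return disease, source


def _refit_source_head(
    source_head: Sequential,
    feats: np.ndarray,
    y_source: np.ndarray,
    C: float,
) -> None:
    """Set the linear source head to the regularized ML solution on the
    current (frozen) latent features."""
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(max_iter=500, C=C).fit(feats, y_source)
    dense = source_head.layers[0]
    if clf.coef_.shape[0] == 1:  # sklearn collapses the binary case
        dense.W.value[...] = np.column_stack([-clf.coef_[0], clf.coef_[0]]) / 2
        dense.b.value[...] = np.array([-clf.intercept_[0], clf.intercept_[0]]) / 2
    else:
        dense.W.value[...] = clf.coef_.T
        dense.b.value[...] = clf.intercept_


def prepare_inputs(images: np.ndarray, input_size: int = 32) -> np.ndarray:
    """uint8 [N, 256, 256, 3] -> float64 NCHW at the training resolution.

    Images are average-pooled down and standardized per image (zero mean,
    unit SD) so the conv stack sees well-scaled activations regardless of
    each image's dynamic range.
    """
    x = np.asarray(images, dtype=np.float64) / 255.0
    n, h, w, c = x.shape
    f = h // input_size
    x = x.reshape(n, input_size, f, input_size, f, c).mean(axis=(2, 4))
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    sd = x.std(axis=(1, 2, 3), keepdims=True)
    x = (x - mu) / (sd + 1e-8)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _adversarial_step(
    backbone: Sequential,
    disease_head: Sequential,
    source_head: Sequential,
    x: np.ndarray,
    y_disease: np.ndarray,
    y_source: np.ndarray,
    lam: float,
    block_source_grad: bool = False,
) -> tuple[float, float]:
    """One forward/backward pass; accumulates gradients on all params.

    The disease head and the source head each minimize their own
    cross-entropy; the backbone receives the disease gradient plus the
    source-branch gradient negated and scaled by lambda (the
    gradient-reversal contract).
    """
    feats = backbone.forward(x)
    l0, g0 = softmax_cross_entropy(disease_head.forward(feats), y_disease)
    lq, gq = softmax_cross_entropy(source_head.forward(feats), y_source)
    grad_f = disease_head.backward(g0)
    grad_f_src = source_head.backward(gq)
    if not block_source_grad:
        grad_f = grad_f + (-lam) * grad_f_src
    backbone.backward(grad_f)
    return l0, lq


def _lambda_at(cfg: AdvConfig, epoch: int) -> float:
    if cfg.lambda_schedule == "constant":
        return cfg.lam
    if cfg.lambda_schedule == "ramp":
        p = epoch / max(cfg.epochs - 1, 1)
        if p <= cfg.warmup_frac:
            return 0.0
        q = (p - cfg.warmup_frac) / max(1.0 - cfg.warmup_frac, 1e-9)
        return cfg.lam * (2.0 / (1.0 + np.exp(-10.0 * q)) - 1.0)
    raise ValueError(f"unknown lambda schedule {cfg.lambda_schedule!r}")


def _lr_at(cfg: AdvConfig, epoch: int) -> float:
    if not cfg.lr_decay:
        return cfg.lr
    p = epoch / max(cfg.epochs - 1, 1)
    return cfg.lr * 0.5 * (1.0 + np.cos(np.pi * 0.9 * p))


def train_adversarial(
    images: np.ndarray,
    risks: np.ndarray,
    sources: np.ndarray,
    cfg: AdvConfig | None = None,
) -> TrainedModel:
    """Train the adversarial classifier on scent images.

    ``images`` is a uint8 array [N, 256, 256, 3]; ``risks`` and ``sources``
    are per-sample string labels.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AdvConfig()
    risks = np.asarray(risks)
    sources = np.asarray(sources)
    risk_classes = tuple(r for r in RISK_LEVELS if r in set(risks))
    if len(risk_classes) < 2:
        raise ValueError("need >= 2 risk classes to train")
    source_classes = tuple(sorted(set(sources)))
    if len(source_classes) < 2 and cfg.lam > 0:
        raise ValueError("a single-source dataset cannot drive the adversary (lambda > 0)")
    y_d = np.array([risk_classes.index(r) for r in risks])
    y_s = np.array([source_classes.index(s) for s in sources])

    rng = np.random.default_rng(cfg.seed)
    backbone = _build_small_cnn(cfg, rng)
    disease_head, source_head = _build_heads(cfg, len(source_classes), rng)
    params = backbone.params() + disease_head.params() + source_head.params()
    opt_main = Adam(backbone.params() + disease_head.params(), lr=cfg.lr,
                    clip_norm=cfg.clip_norm)

    x_all = prepare_inputs(images, cfg.input_size)
    n = x_all.shape[0]
    n_batches_total = int(np.ceil(n / cfg.batch_size))
    refit_every = max(n_batches_total // max(cfg.adversary_refits_per_epoch, 1), 1)

    def frozen_feats() -> np.ndarray:
        backbone.set_training(False)
        try:
            return backbone.forward(x_all)
        finally:
            backbone.set_training(True)

    rows = []
    for epoch in range(cfg.epochs):
        lam = _lambda_at(cfg, epoch)
        opt_main.lr = _lr_at(cfg, epoch)
        order = rng.permutation(n)
        l0_sum = lq_sum = 0.0
        n_batches = 0
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start : start + cfg.batch_size]
            if lam > 0 and bi % refit_every == 0:
                _refit_source_head(source_head, frozen_feats(), y_s, cfg.adversary_C)
            for p in params:
                p.grad[...] = 0.0
            l0, lq = _adversarial_step(
                backbone, disease_head, source_head,
                x_all[idx], y_d[idx], y_s[idx], lam,
                block_source_grad=cfg.block_source_grad,
            )
            opt_main.step()
            l0_sum += l0
            lq_sum += lq
            n_batches += 1
        l0_ep = l0_sum / n_batches
        lq_ep = lq_sum / n_batches
        rows.append(
            {
                "epoch": epoch,
                "lambda": lam,
                "l0": l0_ep,
                "lq": lq_ep,
                "ltotal": total_loss(l0_ep, lq_ep, lam),
            }
        )
    return TrainedModel(
        backbone=backbone,
        disease_head=disease_head,
        source_head=source_head,
        cfg=cfg,
        risk_classes=risk_classes,
        source_classes=source_classes,
        history=pd.DataFrame(rows),
    )


def latent_features(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Frozen-backbone embeddings of a batch of images (inference mode)."""
    x = prepare_inputs(images, model.cfg.input_size)
    model.backbone.set_training(False)
    try:
        return model.backbone.forward(x)
    finally:
        model.backbone.set_training(True)


def predict_risk(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Per-sample class probabilities over the model's risk classes."""
    feats = latent_features(model, images)
    return softmax(model.disease_head.forward(feats))


def predict_risk_labels(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    probs = predict_risk(model, images)
    return np.array([model.risk_classes[i] for i in probs.argmax(axis=1)])


def _model_arrays(model: TrainedModel) -> list[np.ndarray]:
    """All learnable parameters and batch-norm buffers, in a fixed order."""
    arrays: list[np.ndarray] = []
    for seq in (model.backbone, model.disease_head, model.source_head):
        for layer in seq.layers:
            for p in layer.params():
                arrays.append(p.value)
            if isinstance(layer, BatchNorm1d):
                arrays.append(layer.running_mean)
                arrays.append(layer.running_var)
    return arrays


def save_model(model: TrainedModel, path) -> None:
    """Persist weights, config snapshot and training history to a directory."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = _model_arrays(model)
    np.savez(path / "weights.npz", **{f"a{i}": a for i, a in enumerate(arrays)})
    (path / "config.json").write_text(
        json.dumps(
            {
                "cfg": asdict(model.cfg),
                "risk_classes": list(model.risk_classes),
                "source_classes": list(model.source_classes),
            },
            indent=2,
        )
    )
    model.history.to_csv(path / "history.csv", index=False, float_format="%.17g")


def load_model(path) -> TrainedModel:
    """Rebuild a saved model; predictions match the saved model exactly."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    cfg = AdvConfig(**meta["cfg"])
    rng = np.random.default_rng(cfg.seed)
    backbone = _build_small_cnn(cfg, rng)
    disease_head, source_head = _build_heads(
        cfg, len(meta["source_classes"]), rng
    )
    history = pd.read_csv(path / "history.csv", float_precision="round_trip")
    model = TrainedModel(
        backbone=backbone,
        disease_head=disease_head,
        source_head=source_head,
        cfg=cfg,
        risk_classes=tuple(meta["risk_classes"]),
        source_classes=tuple(meta["source_classes"]),
        history=history,
    )
    with np.load(path / "weights.npz") as payload:
        arrays = _model_arrays(model)
        if len(payload.files) != len(arrays):
            raise ValueError("saved weights do not match the model architecture")
        for i, target in enumerate(arrays):
            np.copyto(target, payload[f"a{i}"])
    return model


def residual_bias_probe(
    model: TrainedModel,
    images: np.ndarray,
    sources: np.ndarray,
    probe_cfg: ProbeConfig | None = None,
) -> float:
    """Held-out source accuracy of a fresh classifier on frozen features.

    This is the residual-bias measure: if debiasing worked, a classifier
    trained only on the latent features should recover the collection site
    no better than chance.  Accuracy is estimated by stratified k-fold
    cross-validation so every sample contributes one held-out prediction.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    probe_cfg = probe_cfg or ProbeConfig()
    feats = latent_features(model, np.asarray(images))
    sources = np.asarray(sources)
    _, counts = np.unique(sources, return_counts=True)
    n_folds = int(min(probe_cfg.n_folds, counts.min()))
    if n_folds < 2:
        raise ValueError("probe needs >= 2 samples from every source")
    cv = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=probe_cfg.seed
    )
    clf = LogisticRegression(max_iter=probe_cfg.max_iter, C=probe_cfg.C)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        scores = cross_val_score(clf, feats, sources, cv=cv)
    return float(scores.mean())
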