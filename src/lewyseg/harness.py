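"""Training/evaluation harness for the two supervised tasks.

Covers the protocol shared by binary tile classification (does this tile
contain an aggregate?) and six-class aggregate morphology classification:
AdamW optimization in either full fine-tuning or frozen-backbone mode, a
linear head with dropout 0.2 and ReLU activation between backbone features
and logits, checkpoint selection by lowest validation loss, and
balanced-accuracy reporting (mean of per-class recalls, robust to the
heavy class imbalance of aggregate datasets).

The tested default backbone is the package's tiny dense network on
downsampled pixel features; any feature extractor with the same
forward/backward/params interface can be plugged in.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .nn import (
    MLP,
    AdamW,
    binary_cross_entropy,
    crop_features,
    cross_entropy,
    flatten_grads,
    flatten_params,
    softmax,
    step_decay,
    warmup_cosine,
)

SIX_CLASS_SCHEME = (
    "lewy_body",
    "axon",
    "dendrite",
    "undifferentiated_neurite",
    "multiple_lewy_bodies",
    "artifact",
)


@dataclass
class TrainConfig:
    mode: str = "full_finetune"  # or "frozen_backbone"
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    loss: str = "cross_entropy"  # or "binary_cross_entropy"
    epochs: int = 20
    batch_size: int = 32
    schedule: str = "warmup_cosine"  # or "step"
    step_period: int = 10
    step_factor: float = 0.1
    warmup_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.mode not in ("full_finetune", "frozen_backbone"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class HeadSpec:
    dropout: float = 0.2
    hidden_activation: str = "relu"

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must lie in [0, 1)")


class Classifier:
    """Backbone + (ReLU -> dropout -> linear) head.

    ``featurizer`` selects the crop representation fed to the backbone:
    "morphology" (shape descriptors, desk-scale default) or "pixels"
    (downsampled intensities). Standardization statistics are fitted on
    the training split and frozen into the model.
    """

    def __init__(self, backbone: MLP, n_classes: int, head: HeadSpec | None = None,
                 seed: int = 0, featurizer: str = "morphology",
                 feature_res: int = 24):
        self.backbone = backbone
        self.head_spec = head or HeadSpec()
        self.featurizer = featurizer
        self.feature_res = feature_res
        self.feat_mean = None
        self.feat_std = None
        rng = np.random.default_rng(seed + 1)
        d = backbone.sizes[-1]
        out = 1 if n_classes == 2 else n_classes
        self.n_classes = n_classes
        self.head_W = rng.normal(0.0, np.sqrt(2.0 / d), (d, out))
        self.head_b = np.zeros(out)

    def featurize(self, images, fit: bool = False):
        imgs = np.asarray(images, dtype=float)
        if imgs.ndim <= 2:
            return imgs  # already feature vectors
        if self.featurizer == "pixels":
            X = crop_features(imgs, self.feature_res)
        else:
            from .features import crop_descriptors

            X = crop_descriptors(imgs)
        if fit:
            self.feat_mean = X.mean(axis=0)
            self.feat_std = np.maximum(X.std(axis=0), 1e-9)
        if self.feat_mean is not None:
            X = (X - self.feat_mean) / self.feat_std
        return X

    # -- forward/backward -------------------------------------------------
    def forward(self, X, train: bool = False, rng=None):
        feats, cache = self.backbone.forward(X, train=train)
        act = np.maximum(feats, 0.0)
        if train and self.head_spec.dropout > 0:
            keep = 1.0 - self.head_spec.dropout
            mask = (rng.random(act.shape) < keep) / keep
        else:
            mask = np.ones_like(act)
        dropped = act * mask
        logits = dropped @ self.head_W + self.head_b
        return logits, (cache, feats, mask, dropped)

    def backward(self, fwd_cache, dlogits, frozen_backbone: bool):
        cache, feats, mask, dropped = fwd_cache
        gW = dropped.T @ dlogits
        gb = dlogits.sum(axis=0)
        if frozen_backbone:
            return [gW, gb], None
        dact = (dlogits @ self.head_W.T) * mask * (feats > 0)
        bb_grads, _ = self.backbone.backward(cache, dact)
        return [gW, gb], bb_grads

    def predict(self, X):
        logits, _ = self.forward(X)
        if self.head_W.shape[1] == 1:
            return (logits.ravel() > 0).astype(int)
        return logits.argmax(axis=1)

    def snapshot(self):
        return {
            "backbone": [[W.copy(), b.copy()] for W, b in self.backbone.params],
            "head_W": self.head_W.copy(),
            "head_b": self.head_b.copy(),
        }

    def restore(self, snap):
        self.backbone.params = [[W.copy(), b.copy()] for W, b in snap["backbone"]]
        self.head_W = snap["head_W"].copy()
        self.head_b = snap["head_b"].copy()


def make_default_classifier(n_classes: int, featurizer: str = "morphology",
                            feature_res: int = 24, hidden=(64, 32),
                            seed: int = 0) -> Classifier:
    if featurizer == "pixels":
        d = 3 * feature_res**2
    else:
        from .features import DESCRIPTOR_DIM

        d = DESCRIPTOR_DIM
    backbone = MLP([d] + list(hidden), seed=seed)
    return Classifier(backbone, n_classes, seed=seed, featurizer=featurizer,
                      feature_res=feature_res)


def _encode_labels(y, scheme):
    lut = {name: i for i, name in enumerate(scheme)}
    try:
        return np.asarray([lut[v] for v in y])
    except KeyError as e:
        raise ParameterError(f"label {e.args[0]!r} not in class scheme") from e


def train_classifier(
    train_set,
    val_set,
    model: Classifier,
    config: TrainConfig | None = None,
    scheme=None,
):
    """Train and return ``(model_at_best_checkpoint, history)``.

    ``train_set`` / ``val_set`` are ``(images_or_features, labels)``;
    labels may be class names from ``scheme`` or integer indices. The
    checkpoint with the lowest validation loss is restored into the model;
    history is a DataFrame with per-epoch train/val loss and validation
    balanced accuracy.
    """
    config = config or TrainConfig()
    Xtr, ytr = train_set
    Xva, yva = val_set
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ParameterError("train and validation splits must be non-empty")
    if scheme is not None:
        ytr = _encode_labels(ytr, scheme)
        yva = _encode_labels(yva, scheme)
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)

    Xtr = model.featurize(np.asarray(Xtr, dtype=float), fit=True)
    Xva = model.featurize(np.asarray(Xva, dtype=float))

    frozen = config.mode == "frozen_backbone"
    head_params = [model.head_W, model.head_b]
    if frozen:
        opt_params = head_params
    else:
        opt_params = flatten_params(model.backbone) + head_params
    opt = AdamW(opt_params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)

    n = len(Xtr)
    steps_per_epoch = max(int(np.ceil(n / config.batch_size)), 1)
    total = config.epochs * steps_per_epoch
    warm = max(int(config.warmup_fraction * total), 1)

    def loss_fn(logits, y):
        if config.loss == "binary_cross_entropy":
            return binary_cross_entropy(logits, y)
        return cross_entropy(logits, y)

    history = []
    best = (np.inf, None)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        train_losses = []
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size : (s + 1) * config.batch_size]
            if idx.size == 0:
                continue
            logits, fwd = model.forward(Xtr[idx], train=True, rng=rng)
            loss, dlogits = loss_fn(logits, ytr[idx])
            head_g, bb_g = model.backward(fwd, dlogits, frozen)
            grads = head_g if frozen else flatten_grads(bb_g) + head_g
            if config.schedule == "step":
                scale = step_decay(epoch, config.step_period, config.step_factor)
            else:
                scale = warmup_cosine(step, total, warm)
            opt.step(opt_params, grads, lr_scale=scale)
            train_losses.append(loss)
            step += 1
        val_logits, _ = model.forward(Xva)
        val_loss, _ = loss_fn(val_logits, yva)
        val_pred = model.predict(Xva)
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": float(val_loss),
                "val_balanced_accuracy": balanced_accuracy(yva, val_pred),
            }
        )
        if val_loss < best[0]:
            best = (val_loss, model.snapshot())
    model.restore(best[1])
    return model, pd.DataFrame(history)


def balanced_accuracy(y_true, y_pred, scheme=None) -> float:
    """Mean of per-class recalls, in percent. Classes of the scheme absent
    from ``y_true`` are excluded with a warning."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ParameterError("empty input")
    if y_true.shape != y_pred.shape:
        raise ParameterError("length mismatch")
    if scheme is not None:
        classes = list(scheme)
        missing = [c for c in classes if not np.any(y_true == c)]
        if missing:
            warnings.warn(
                f"classes absent from y_true excluded: {missing}", RuntimeWarning
            )
            classes = [c for c in classes if c not in missing]
    else:
        classes = list(np.unique(y_true))
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in classes
    ]
    return float(np.mean(recalls) * 100.0)


@dataclass
class CountAgreement:
    mean_relative_difference_pct: float
    n_pairs: int
    zero_manual_tiles: list = field(default_factory=list)


def evaluate_count_agreement(detected, manual) -> CountAgreement:
    """Average relative difference between detected and manual per-tile
    aggregate counts, in percent: mean over tiles of |d - m| / m. Tiles
    with zero manual count are excluded from the mean and reported
    separately with their (false-positive) detected counts."""
    detected = np.asarray(detected, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if detected.shape != manual.shape:
        raise ParameterError("paired counts must have equal length")
    valid = manual > 0
    if not np.any(valid):
        raise ParameterError("no tiles with positive manual count")
    rel = np.abs(detected[valid] - manual[valid]) / manual[valid]
    zero = [
        (int(i), float(detected[i])) for i in np.flatnonzero(~valid)
    ]
    return CountAgreement(float(rel.mean() * 100.0), int(valid.sum()), zero)
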