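"""Minimal dense neural-network stack (NumPy, explicit gradients).

Provides the small trainable components the retrieval and classification
harnesses need at desk scale: a fully connected network with ReLU hidden
layers, an AdamW optimizer, warmup-cosine and step learning-rate
schedules, and pixel-feature extraction for image crops. Backbones are
pluggable through the same ``forward`` / ``backward`` / ``params``
interface, so an external feature extractor can replace :class:`MLP`
without touching the harnesses.
"""

from __future__ import annotations

import copy

import numpy as np


def crop_features(images: np.ndarray, res: int = 24, white_point: float = 255.0):
    """Downsample RGB crops to ``res`` x ``res`` and flatten to feature
    vectors in [0, 1] (stain-dark pixels high: features are 1 - I/I0)."""
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim == 3:
        imgs = imgs[None]
    n, h, w, c = imgs.shape
    if h % res == 0 and w % res == 0:
        f = imgs.reshape(n, res, h // res, res, w // res, c).mean(axis=(2, 4))
    else:
        from skimage.transform import resize

        f = np.stack(
            [resize(im, (res, res), order=1, anti_aliasing=True) for im in imgs]
        )
    return 1.0 - f.reshape(n, -1) / white_point


class MLP:
    """Fully connected net: ReLU on hidden layers, linear output."""

    def __init__(self, sizes, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            self.params.append([W, np.zeros(fan_out)])

    def forward(self, X, train: bool = False):
        cache = [np.asarray(X, dtype=float)]
        a = cache[0]
        for i, (W, b) in enumerate(self.params):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.params) - 1 else z
            cache.append(a)
        return a, cache

    def backward(self, cache, dout):
        grads = [None] * len(self.params)
        delta = np.asarray(dout, dtype=float)
        for i in range(len(self.params) - 1, -1, -1):
            W, _ = self.params[i]
            if i < len(self.params) - 1:
                delta = delta * (cache[i + 1] > 0)
            grads[i] = [cache[i].T @ delta, delta.sum(axis=0)]
            delta = delta @ W.T
        return grads, delta

    def copy(self):
        clone = MLP.__new__(MLP)
        clone.sizes = list(self.sizes)
        clone.params = [[W.copy(), b.copy()] for W, b in self.params]
        return clone

    def state_equal(self, other) -> bool:
        return all(
            np.array_equal(W, W2) and np.array_equal(b, b2)
            for (W, b), (W2, b2) in zip(self.params, other.params)
        )


class AdamW:
    """Decoupled weight decay Adam on a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def flatten_params(net: MLP):
    return [arr for pair in net.params for arr in pair]


def flatten_grads(grads):
    return [arr for pair in grads for arr in pair]


def warmup_cosine(step: int, total_steps: int, warmup_steps: int) -> float:
    """LR scale: linear warmup then cosine decay to zero."""
    if total_steps <= 0:
        return 1.0
    if warmup_steps > 0 and step < warmup_steps:
        return (step + 1) / warmup_steps
    frac = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    return 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))


def step_decay(epoch: int, period: int = 10, factor: float = 0.1) -> float:
    """LR scale: multiply by ``factor`` every ``period`` epochs."""
    return factor ** (epoch // period)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y_idx):
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y_idx)
    loss = -np.mean(np.log(p[np.arange(n), y_idx] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, grad / n


def binary_cross_entropy(logit, y):
    """Mean BCE on a single-logit output and its gradient."""
    z = logit.ravel()
    y = np.asarray(y, dtype=float)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
    return loss, ((p - y) / len(y))[:, None]
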