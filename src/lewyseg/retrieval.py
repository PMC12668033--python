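"""Self-supervised crop embeddings and nearest-neighbor retrieval.

An encoder f_theta is fine-tuned with the SimCLR objective on unlabeled
aggregate crops: each crop is augmented twice, and the NT-Xent loss pulls
the two views together while pushing apart all other views in the batch.
Queries against the resulting embedding index return the k nearest crops
(k = 250 in the annotation-bootstrapping workflow), giving a
neuropathologist class-coherent candidate sets to label.

For a batch of 2B L2-normalized embeddings z with positives paired
(i, i+B) and temperature tau:

    L = mean_i [ -s(i, p(i)) + log sum_{j != i} exp(s(i, j)) ],
    s(i, j) = z_i . z_j / tau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .nn import (
    MLP,
    AdamW,
    crop_features,
    flatten_grads,
    flatten_params,
    warmup_cosine,
)


@dataclass
class ContrastiveBatchConfig:
    """Contrastive fine-tuning settings (AdamW + warmup-cosine)."""

    batch_size: int = 128
    temperature: float = 0.5
    learning_rate: float = 2e-4
    weight_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.95
    epochs: int = 10
    warmup_fraction: float = 0.1
    featurizer: str = "morphology"
    feature_res: int = 24
    embed_dim: int = 32
    #: hidden width of the encoder MLP; 0 (default) means a single linear
    #: projection, which preserves descriptor geometry far better than a
    #: randomly initialized ReLU layer at this input dimensionality
    hidden: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.batch_size % 2:
            raise ParameterError("batch size must be even after pairing")


def nt_xent_loss(embeddings: np.ndarray, temperature: float = 0.5) -> float:
    """NT-Xent loss of a batch of 2B embeddings with positives (i, i+B)."""
    loss, _ = nt_xent_loss_and_grad(embeddings, temperature)
    return loss


def nt_xent_loss_and_grad(embeddings: np.ndarray, temperature: float):
    """Loss plus gradient w.r.t. the raw (pre-normalization) embeddings."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    E = np.asarray(embeddings, dtype=float)
    n = E.shape[0]
    if n < 4 or n % 2:
        raise ParameterError("need an even batch of at least 4 embeddings")
    b = n // 2
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    z = E / norms
    s = (z @ z.T) / temperature
    np.fill_diagonal(s, -np.inf)
    pos = np.concatenate([np.arange(b) + b, np.arange(b)])

    row_max = s.max(axis=1, keepdims=True)
    expn = np.exp(s - row_max)
    denom = expn.sum(axis=1, keepdims=True)
    logsumexp = (np.log(denom) + row_max).ravel()
    loss = float(np.mean(logsumexp - s[np.arange(n), pos]))

    # dL/ds = (softmax over each row - indicator of the positive) / n
    G = expn / denom
    G[np.arange(n), pos] -= 1.0
    G /= n
    dz = ((G + G.T) @ z) / temperature
    # through the normalization: project out the radial component
    dE = (dz - (dz * z).sum(axis=1, keepdims=True) * z) / norms
    return loss, dE


def augment_crop(img: np.ndarray, rng: np.random.Generator,
                 white_point: float = 255.0) -> np.ndarray:
    """SimCLR-style augmentation preserving magenta hue identity: flips,
    random resized crop (70-100% area), mild brightness/gain jitter and
    occasional slight blur."""
    from scipy.ndimage import gaussian_filter
    from skimage.transform import resize

    out = img.astype(float)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1]
    h, w, _ = out.shape
    scale = rng.uniform(0.7, 1.0)
    ch, cw = int(h * scale), int(w * scale)
    r0 = rng.integers(0, h - ch + 1)
    c0 = rng.integers(0, w - cw + 1)
    out = resize(out[r0 : r0 + ch, c0 : c0 + cw], (h, w), order=1,
                 anti_aliasing=False)
    out = out + rng.uniform(-10, 10)                 # brightness
    out = out * rng.uniform(0.95, 1.05)              # common gain
    if rng.random() < 0.3:
        out = gaussian_filter(out, sigma=(0.8, 0.8, 0))
    return np.clip(out, 0.0, white_point)


@dataclass
class Embedder:
    """Tiny conv-free encoder: crop features -> dense net.

    ``featurizer`` selects the input representation: "morphology"
    (rotation-invariant shape descriptors, the desk-scale default) or
    "pixels" (downsampled intensities). Feature standardization statistics
    are frozen at training time.
    """

    net: MLP
    featurizer: str = "morphology"
    feature_res: int = 24
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    loss_history: list = field(default_factory=list)

    def featurize(self, crops: np.ndarray) -> np.ndarray:
        if self.featurizer == "pixels":
            X = crop_features(crops, self.feature_res)
        else:
            from .features import crop_descriptors

            X = crop_descriptors(crops)
        if self.feat_mean is not None:
            X = (X - self.feat_mean) / self.feat_std
        return X

    def embed(self, crops: np.ndarray) -> np.ndarray:
        out, _ = self.net.forward(self.featurize(crops))
        return out


def train_embedder(
    crops: np.ndarray,
    config: ContrastiveBatchConfig | None = None,
    encoder: Embedder | None = None,
    seed: int = 0,
) -> Embedder:
    """SimCLR fine-tuning of the tiny encoder on unlabeled crops.

    Two augmented views per crop form the positive pairs; AdamW with the
    configured betas/weight decay and a warmup-cosine schedule minimizes
    NT-Xent. With ``epochs=0`` the encoder is returned untouched.
    """
    config = config or ContrastiveBatchConfig()
    crops = np.asarray(crops, dtype=float)
    n = len(crops)
    if n < 2 * config.batch_size:
        raise ParameterError(
            f"need at least {2 * config.batch_size} crops, got {n}"
        )
    batch = config.batch_size
    rng = np.random.default_rng(seed)
    if encoder is None:
        if config.featurizer == "pixels":
            d = 3 * config.feature_res**2
        else:
            from .features import DESCRIPTOR_DIM

            d = DESCRIPTOR_DIM
        sizes = (
            [d, config.hidden, config.embed_dim]
            if config.hidden
            else [d, config.embed_dim]
        )
        encoder = Embedder(
            MLP(sizes, seed=seed),
            featurizer=config.featurizer,
            feature_res=config.feature_res,
        )
    if config.epochs == 0:
        return encoder

    # freeze feature standardization on the unaugmented training crops
    if encoder.feat_mean is None:
        stats_src = encoder.featurize(crops)
        encoder.feat_mean = stats_src.mean(axis=0)
        encoder.feat_std = np.maximum(stats_src.std(axis=0), 1e-9)

    net = encoder.net
    opt = AdamW(
        flatten_params(net),
        lr=config.learning_rate,
        betas=(config.beta1, config.beta2),
        weight_decay=config.weight_decay,
    )
    steps_per_epoch = max(n // batch, 1)
    total = config.epochs * steps_per_epoch
    warm = max(int(config.warmup_fraction * total), 1)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            idx = order[s * batch : (s + 1) * batch]
            if len(idx) < 2:
                continue
            views = [augment_crop(crops[i], rng) for i in idx] + [
                augment_crop(crops[i], rng) for i in idx
            ]
            X = encoder.featurize(np.stack(views))
            emb, cache = net.forward(X, train=True)
            loss, dE = nt_xent_loss_and_grad(emb, config.temperature)
            grads, _ = net.backward(cache, dE)
            opt.step(
                flatten_params(net),
                flatten_grads(grads),
                lr_scale=warmup_cosine(step, total, warm),
            )
            encoder.loss_history.append(loss)
            step += 1
    return encoder


# ---------------------------------------------------------------------------
# index + queries


@dataclass
class EmbeddingIndex:
    vectors: np.ndarray
    ids: np.ndarray
    metric: str = "cosine"

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.ids = np.asarray(self.ids)
        if self.metric not in ("cosine", "euclidean"):
            raise ParameterError(f"unknown metric {self.metric!r}")
        if len(self.vectors) != len(self.ids):
            raise ValueError("ids and vectors misaligned")
        if len(self.vectors) < 1:
            raise ValueError("index must contain at least one vector")


def build_index(encoder: Embedder, crops: np.ndarray, ids=None,
                metric: str = "cosine") -> EmbeddingIndex:
    vectors = encoder.embed(np.asarray(crops, dtype=float))
    if ids is None:
        ids = np.arange(len(vectors))
    return EmbeddingIndex(vectors, ids, metric)


def knn_query(index: EmbeddingIndex, query: np.ndarray, k: int = 250):
    """Ids and distances of the k nearest indexed vectors, ascending
    distance, ties broken by id."""
    n = len(index.vectors)
    if k > n:
        raise ParameterError(f"k={k} exceeds index size {n}")
    q = np.asarray(query, dtype=float).ravel()
    if index.metric == "cosine":
        vn = index.vectors / np.maximum(
            np.linalg.norm(index.vectors, axis=1, keepdims=True), 1e-12
        )
        qn = q / max(np.linalg.norm(q), 1e-12)
        dist = 1.0 - vn @ qn
    else:
        dist = np.linalg.norm(index.vectors - q, axis=1)
    order = np.lexsort((index.ids, dist))[:k]
    return index.ids[order], dist[order]


def flag_duplicates(index: EmbeddingIndex, tol: float = 1e-6):
    """Pairs of entries closer than ``tol`` (near-duplicate crops)."""
    pairs = []
    v = index.vectors
    for i in range(len(v)):
        d = np.linalg.norm(v[i + 1 :] - v[i], axis=1)
        for j in np.flatnonzero(d < tol):
            pairs.append((index.ids[i], index.ids[i + 1 + j]))
    return pairs


def save_encoder(encoder: Embedder, path):
    """Encoder weights + feature statistics as an .npz archive."""
    arrays = {"sizes": np.asarray(encoder.net.sizes)}
    for i, (W, b) in enumerate(encoder.net.params):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if encoder.feat_mean is not None:
        arrays["feat_mean"] = encoder.feat_mean
        arrays["feat_std"] = encoder.feat_std
    arrays["meta"] = np.asarray([encoder.featurizer, str(encoder.feature_res)])
    np.savez(Path(path), **arrays)


def load_encoder(path) -> Embedder:
    with np.load(Path(path), allow_pickle=False) as data:
        sizes = [int(s) for s in data["sizes"]]
        net = MLP(sizes, seed=0)
        net.params = [
            [data[f"W{i}"].copy(), data[f"b{i}"].copy()]
            for i in range(len(sizes) - 1)
        ]
        featurizer, res = data["meta"]
        enc = Embedder(net, featurizer=str(featurizer), feature_res=int(res))
        if "feat_mean" in data:
            enc.feat_mean = data["feat_mean"].copy()
            enc.feat_std = data["feat_std"].copy()
    return enc


def save_index(index: EmbeddingIndex, path):
    """Flat float32 binary matrix + JSON header."""
    path = Path(path)
    index.vectors.astype(np.float32).tofile(path.with_suffix(".bin"))
    header = {
        "ids": [str(i) for i in index.ids],
        "metric": index.metric,
        "dim": int(index.vectors.shape[1]),
    }
    path.with_suffix(".json").write_text(json.dumps(header))


def load_index(path) -> EmbeddingIndex:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    vec = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
    vec = vec.reshape(-1, header["dim"]).astype(float)
    return EmbeddingIndex(vec, np.asarray(header["ids"]), header["metric"])
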