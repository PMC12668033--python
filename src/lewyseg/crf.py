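"""Fully connected CRF refinement by mean-field inference.

Binary (foreground/background) dense CRF with Potts compatibility. The
energy combines a unary term from the attention probability map with two
Gaussian pairwise kernels in the style of the standard fully connected CRF:

* a smoothness kernel on pixel positions (sd ``gamma``, weight ``w2``);
* an appearance kernel on position and RGB color (spatial sd ``alpha``,
  color sd ``beta``, weight ``w1``), which pulls the mask toward color
  edges.

Message passing uses separable Gaussian blurs approximated by a cascade of
three box filters (cost independent of the kernel width), and the
appearance kernel is approximated by quantizing colors into a small number
of k-means bins and exchanging blurred messages between bins weighted by
their color affinity. Default hyperparameters follow the common dense-CRF
defaults (w1=10, alpha=80, beta=13, w2=3, gamma=3, 5 iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ParameterError


@dataclass
class CRFParams:
    """Mean-field dense-CRF hyperparameters (pixel units for sds)."""

    iterations: int = 5
    w_appearance: float = 10.0   # w1
    sd_spatial_appearance: float = 80.0   # alpha
    sd_color: float = 13.0       # beta
    w_smooth: float = 3.0        # w2
    sd_spatial_smooth: float = 3.0  # gamma
    n_color_bins: int = 8
    unary_from_mask: bool = False  # use the binarized attention mask as unary
    #: attention maps are localization heat maps, not calibrated
    #: probabilities: the unary is a logistic in (P - unary_tau) so values
    #: above the inclusive attention threshold count as foreground evidence
    unary_tau: float = 0.1
    unary_softness: float = 0.05
    #: unary probabilities are clipped to [0.05, 0.95] so the pairwise
    #: appearance vote can always override a confident-looking unary
    unary_clip: float = 0.05
    seed: int = 0


def _box_sizes(sigma: float, passes: int = 3):
    # three box passes approximating a Gaussian of the given sigma
    w_ideal = np.sqrt(12.0 * sigma**2 / passes + 1.0)
    wl = int(np.floor(w_ideal))
    if wl % 2 == 0:
        wl -= 1
    wu = wl + 2
    m_ideal = (12 * sigma**2 - passes * wl**2 - 4 * passes * wl - 3 * passes) / (
        -4 * wl - 4
    )
    m = int(round(m_ideal))
    return [wl if i < m else wu for i in range(passes)]


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Approximate Gaussian blur by three box filters per axis."""
    if sigma <= 0:
        return img.copy()
    out = np.asarray(img, dtype=float)
    for size in _box_sizes(sigma):
        if size >= 3:
            out = uniform_filter1d(out, size, axis=0, mode="nearest")
            out = uniform_filter1d(out, size, axis=1, mode="nearest")
    return out


def _color_bins(image: np.ndarray, n_bins: int, seed: int):
    """Quantize RGB into k-means bins; returns per-pixel bin map and the
    bin-to-bin appearance affinities are computed by the caller."""
    from sklearn.cluster import KMeans

    h, w, _ = image.shape
    flat = image.reshape(-1, 3).astype(float)
    rng = np.random.default_rng(seed)
    n_sample = min(4000, flat.shape[0])
    sample = flat[rng.choice(flat.shape[0], n_sample, replace=False)]
    uniq = np.unique(np.round(sample), axis=0)
    k = min(n_bins, len(uniq))
    km = KMeans(n_clusters=k, n_init=2, random_state=seed).fit(sample)
    labels = km.predict(flat).reshape(h, w)
    return labels, km.cluster_centers_


def mean_field_crf(
    image: np.ndarray,
    prob_fg: np.ndarray,
    params: CRFParams | None = None,
) -> np.ndarray:
    """Run mean-field inference; returns the refined foreground probability.

    ``image`` is H x W x 3 (any intensity scale), ``prob_fg`` the unary
    foreground probability in [0, 1].
    """
    params = params or CRFParams()
    if params.iterations < 0:
        raise ParameterError("iterations must be >= 0")
    p = np.clip(np.asarray(prob_fg, dtype=float), 1e-6, 1.0 - 1e-6)
    if params.iterations == 0:
        return p
    unary = -np.stack([np.log(1.0 - p), np.log(p)])  # (2, H, W); 1 = fg

    bins, centers = _color_bins(image, params.n_color_bins, params.seed)
    k = len(centers)
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    affinity = np.exp(-d2 / (2.0 * params.sd_color**2))
    bin_masks = [bins == b for b in range(k)]

    # blurred per-bin densities for normalizing the appearance votes
    bin_density = [
        gaussian_blur(bm.astype(float), params.sd_spatial_appearance)
        for bm in bin_masks
    ]
    density = np.zeros((k,) + p.shape)
    for b in range(k):
        for b2 in range(k):
            if affinity[b, b2] > 1e-4:
                density[b] += affinity[b, b2] * bin_density[b2]

    Q = np.exp(-unary)
    Q /= Q.sum(axis=0, keepdims=True)
    for _ in range(params.iterations):
        msg = np.zeros_like(Q)
        for lab in range(2):
            # smoothness: local mean of Q (normalized Gaussian vote)
            smooth = gaussian_blur(Q[lab], params.sd_spatial_smooth)
            # appearance: color-affinity-weighted vote of Q over the
            # bilateral neighborhood, normalized by the same-color density
            # so that rare colors (thin magenta structures) are not
            # outvoted by sheer background mass
            blurred = [
                gaussian_blur(Q[lab] * bm, params.sd_spatial_appearance)
                for bm in bin_masks
            ]
            appear = np.zeros_like(Q[lab])
            for b, bm in enumerate(bin_masks):
                acc = np.zeros_like(Q[lab])
                for b2 in range(k):
                    if affinity[b, b2] > 1e-4:
                        acc += affinity[b, b2] * blurred[b2]
                appear[bm] = acc[bm] / np.maximum(density[b][bm], 1e-9)
            msg[lab] = params.w_smooth * smooth + params.w_appearance * appear
        # Potts: each label is penalized by support for the other label
        energy = unary + msg[::-1]
        energy -= energy.min(axis=0, keepdims=True)
        Q = np.exp(-energy)
        Q /= Q.sum(axis=0, keepdims=True)
    return Q[1]
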