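"""Attention-driven semantic segmentation.

A tile-level binary classifier (ViT backbone + linear head in the original
design) exposes, through the :class:`AttentionProvider` contract, a
tile-contains-aggregate score and the last-layer multi-head self-attention
tensor. The attention row from the class token to the patch tokens,
averaged over heads, localizes class-relevant regions:

    a_cls[j] = (1/h) * sum_k A_k[cls, j]

The vector is min-max normalized, reshaped to the patch grid, bilinearly
resized to tile resolution and re-normalized into a probability map P.
Thresholding P at a deliberately inclusive tau (0.1) gives S_attention,
which a fully connected CRF refines into S_refined; finally only connected
components that overlap the alkaline-phosphatase stain mask survive
(S_combined), making the result robust to brown-into-magenta channel
bleed that defeats stain thresholding alone.

Two attention backends ship with the package: a surrogate that emulates a
trained classifier from reference-basis stain projections (for desk-scale
runs), and an oracle that reads the synthetic ground truth (tests only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from .crf import CRFParams, gaussian_blur, mean_field_crf
from .errors import ParameterError
from .stain import rgb_to_od
from .types import REFERENCE_OD_VECTORS, BinaryMask, RGBTile

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class AttentionTensor:
    """Last-layer MHSA tensor: (heads, N+1, N+1) with the class token at
    index 0; each attention row sums to 1."""

    A: np.ndarray
    patch_grid: tuple
    cls_index: int = 0

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must be (heads, N+1, N+1)")
        n = self.patch_grid[0] * self.patch_grid[1]
        if self.A.shape[1] != n + 1:
            raise ValueError("token count inconsistent with patch grid")
        rows = self.A.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-4):
            raise ValueError("attention rows must sum to 1")


@dataclass
class ProbabilityMap:
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)


def class_attention(t: AttentionTensor) -> np.ndarray:
    """Mean over heads of the class-token row, restricted to patch tokens."""
    if t.A.shape[0] == 0:
        raise ValueError("attention tensor must have at least one head")
    cls = t.cls_index
    patch_cols = [j for j in range(t.A.shape[1]) if j != cls]
    return t.A[:, cls, patch_cols].mean(axis=0)


def _minmax(a):
    lo, hi = float(np.min(a)), float(np.max(a))
    if hi - lo <= 0:
        return np.zeros_like(a, dtype=float)
    return (a - lo) / (hi - lo)


def attention_to_map(a_cls: np.ndarray, patch_grid, tile_dims) -> ProbabilityMap:
    """Normalize, reshape to the patch grid, bilinearly upsample to tile
    resolution and re-normalize. A constant vector maps to an all-zero map
    (degenerate min-max convention)."""
    rows, cols = patch_grid
    a = np.asarray(a_cls, dtype=float)
    if a.size != rows * cols:
        raise ValueError("class-attention length does not match patch grid")
    grid = _minmax(a).reshape(rows, cols)
    up = sk_resize(grid, tile_dims, order=1, mode="edge", anti_aliasing=False)
    return ProbabilityMap(_minmax(up))


def threshold_attention(P: ProbabilityMap, tau: float = 0.1) -> BinaryMask:
    """Inclusive preliminary mask ``S_attention = P > tau``."""
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"tau must lie in [0, 1], got {tau}")
    return BinaryMask(P.P > tau, provenance="attention")


def crf_refine(
    tile: RGBTile,
    P: ProbabilityMap,
    s_attention: BinaryMask,
    params: CRFParams | None = None,
) -> BinaryMask:
    """Dense-CRF refinement of the attention map into S_refined.

    With ``iterations=0`` the attention mask passes through unchanged.
    The unary comes from P by default; ``params.unary_from_mask`` switches
    to the binarized S_attention instead.
    """
    params = params or CRFParams()
    if P.P.shape != tile.shape or s_attention.mask.shape != tile.shape:
        raise ValueError("probability map / mask dims must match the tile")
    if params.iterations == 0:
        return BinaryMask(s_attention.mask.copy(), provenance="refined")
    if params.unary_from_mask:
        unary = np.where(s_attention.mask, 0.9, 0.1)
    else:
        logistic = 1.0 / (
            1.0 + np.exp(-(P.P - params.unary_tau) / params.unary_softness)
        )
        unary = np.clip(logistic, params.unary_clip, 1.0 - params.unary_clip)
    q = mean_field_crf(tile.pixels, unary, params)
    return BinaryMask(q > 0.5, provenance="refined")


def combine_with_stain(
    s_refined: BinaryMask,
    s_alkaline: BinaryMask,
    min_overlap_fraction: float = 0.0,
) -> BinaryMask:
    """Keep whole 8-connected components of S_refined that overlap the
    stain mask (by at least one pixel, or by ``min_overlap_fraction`` of
    their area if set); drop the rest."""
    if s_refined.mask.shape != s_alkaline.mask.shape:
        raise ValueError("mask dims differ")
    labels, n = ndimage.label(s_refined.mask, structure=EIGHT_CONN)
    if n == 0:
        return BinaryMask(np.zeros_like(s_refined.mask), provenance="combined")
    overlap = np.bincount(
        labels[s_alkaline.mask & (labels > 0)], minlength=n + 1
    )
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    required = np.maximum(min_overlap_fraction * areas, 1e-9)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = overlap[1:] >= np.maximum(required[1:], 1.0)
    return BinaryMask(keep[labels], provenance="combined")


# ---------------------------------------------------------------------------
# attention providers


def _attention_tensor_from_patch_weights(weights: np.ndarray, patch_grid):
    """Wrap nonnegative per-patch weights into a valid single-head
    attention tensor whose class-token row reproduces them."""
    n = weights.size
    w = np.clip(weights, 0.0, None).ravel()
    total = w.sum()
    cls_self = 0.02
    if total <= 0:
        row = np.full(n + 1, 1.0 / (n + 1))
    else:
        row = np.concatenate([[cls_self], (1.0 - cls_self) * w / total])
    A = np.full((1, n + 1, n + 1), 1.0 / (n + 1))
    A[0, 0, :] = row
    return AttentionTensor(A, patch_grid)


def _patch_pool(img: np.ndarray, patch: int) -> np.ndarray:
    h, w = img.shape
    rows, cols = h // patch, w // patch
    return img[: rows * patch, : cols * patch].reshape(
        rows, patch, cols, patch
    ).mean(axis=(1, 3))


@dataclass
class SurrogateAttentionProvider:
    """Desk-scale stand-in for a trained tile classifier.

    Emulates what the trained attention learns: strong response on
    magenta-stained (alkaline-phosphatase) structures, suppressed response
    where the brown (DAB) channel dominates, plus a few seeded distractor
    lobes so downstream stages cannot rely on the map being clean. The
    tile score is a logistic in the high quantile of the suppressed
    magenta optical density.
    """

    patch_size: int = 16
    blur_sigma: float = 4.0
    n_distractors: int = 2
    distractor_amplitude: float = 0.15
    dab_suppression: float = 1.5
    score_midpoint_od: float = 0.35
    score_scale_od: float = 0.06
    seed: int = 0
    backend_name: str = "surrogate"

    def __call__(self, tile: RGBTile):
        od = rgb_to_od(tile).od
        pinv = np.linalg.pinv(REFERENCE_OD_VECTORS)
        conc = np.einsum("sc,hwc->shw", pinv, od)
        alk = np.clip(conc[1], 0.0, None)
        dab = np.clip(conc[2], 0.0, None)
        evidence = np.clip(alk - self.dab_suppression * dab, 0.0, None)
        smooth = gaussian_blur(evidence, self.blur_sigma)

        grid = _patch_pool(smooth, self.patch_size)
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_distractors):
            r = rng.integers(grid.shape[0])
            c = rng.integers(grid.shape[1])
            grid[r, c] += self.distractor_amplitude * max(grid.max(), 0.05)

        k = max(int(round(evidence.size * 0.001)), 1)
        top = np.partition(evidence.ravel(), -k)[-k:].mean()
        score = float(
            1.0 / (1.0 + np.exp(-(top - self.score_midpoint_od) / self.score_scale_od))
        )
        return score, _attention_tensor_from_patch_weights(grid, grid.shape)


@dataclass
class OracleAttentionProvider:
    """Test-only backend that reads the synthetic ground truth."""

    ground_truth: object  # synthetic.GroundTruth
    patch_size: int = 8
    blur_sigma: float = 2.0
    backend_name: str = "oracle"

    def __call__(self, tile: RGBTile):
        labels = self.ground_truth.labels
        fg = gaussian_blur((labels > 0).astype(float), self.blur_sigma)
        grid = _patch_pool(fg, self.patch_size)
        score = 1.0 if labels.max() > 0 else 0.0
        return score, _attention_tensor_from_patch_weights(grid, grid.shape)


PROVIDERS = {
    "surrogate": SurrogateAttentionProvider,
    "oracle": OracleAttentionProvider,
}
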