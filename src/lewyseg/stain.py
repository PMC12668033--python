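"""Stain separation: Beer-Lambert optical density and sparse NMF unmixing.

A brightfield pixel transmits intensity ``I = I0 * 10**(-W @ h)`` where the
columns of W are per-stain absorption (OD) vectors and h the local stain
concentrations. Converting to optical density ``V = -log10(I / I0)`` makes
the mixing linear, ``V = W H``, so the stains can be unmixed by sparse
non-negative matrix factorization:

    min_{W,H >= 0}  ||V - W H||_F^2 + lam * ||H||_1,   ||W[:, k]|| = 1.

The alkaline-phosphatase (magenta) concentration row of H, rescaled to
[0, 1], acts as a per-pixel probability of alpha-synuclein aggregate and is
thresholded at 0.5 into the stain mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    DegenerateInputError,
    DomainError,
    InvalidWhitePointError,
    ParameterError,
)
from .types import (
    REFERENCE_OD_VECTORS,
    STAIN_NAMES,
    BinaryMask,
    ConcentrationMaps,
    OpticalDensityImage,
    RGBTile,
    StainBasis,
    StainProbabilityMap,
)

#: Pixels whose OD vector norm falls below this are treated as background
#: (classic luminosity-filter convention).
TISSUE_OD_CUTOFF = 0.15

#: Pixels with any channel OD above this (transmission below ~3% of the
#: white point) are excluded from basis fitting: near-opaque pixels have
#: numerically unstable OD under intensity noise.
DARK_OD_CUTOFF = 1.5


def rgb_to_od(tile: RGBTile, eps: float = 1e-6) -> OpticalDensityImage:
    """Convert intensities to optical density, ``-log10((I + eps) / I0)``.

    OD is clipped at 0 so that pixels at the white point map exactly to
    zero despite ``eps``.
    """
    if tile.white_point <= 0:
        raise InvalidWhitePointError("white point must be positive")
    od = -np.log10((tile.pixels + eps) / tile.white_point)
    return OpticalDensityImage(np.clip(od, 0.0, None))


def od_to_rgb(od: OpticalDensityImage, white_point: float = 255.0) -> RGBTile:
    """Invert :func:`rgb_to_od`: ``I = I0 * 10**(-od)``."""
    arr = np.asarray(od.od, dtype=float)
    if np.any(arr < 0):
        raise DomainError("optical density must be nonnegative")
    pixels = np.clip(white_point * 10.0 ** (-arr), 0.0, white_point)
    return RGBTile(pixels, white_point=white_point)


@dataclass
class SNMFResult:
    basis: StainBasis
    concentrations: ConcentrationMaps
    objective_trace: np.ndarray
    converged: bool
    seed: int


def _snmf_objective(V, W, H, lam):
    return float(np.sum((V - W @ H) ** 2) + lam * np.sum(np.abs(H)))


def _update_H(V, W, H, lam, eps=1e-12):
    WtV = W.T @ V
    WtWH = W.T @ W @ H
    return H * WtV / (WtWH + lam + eps)


def solve_concentrations(
    od: OpticalDensityImage, basis: StainBasis, n_iter: int = 80
) -> ConcentrationMaps:
    """Nonnegative concentrations for a fixed basis (multiplicative updates
    warm-started from the clipped least-squares solution)."""
    h, w = od.shape
    V = od.od.reshape(h * w, 3).T
    W = basis.W
    H = np.clip(np.linalg.pinv(W) @ V, 1e-8, None)
    for _ in range(n_iter):
        H = _update_H(V, W, H, lam=0.0)
    return ConcentrationMaps(H, stain_names=basis.stain_names)


def fit_stain_basis(
    od: OpticalDensityImage,
    n_stains: int = 3,
    sparsity: float = 0.01,
    max_iter: int = 200,
    seed: int = 0,
    tol: float = 1e-6,
    max_fit_pixels: int = 5000,
) -> SNMFResult:
    """Fit the stain basis and concentration maps by sparse NMF.

    The dictionary W is fitted on a seeded subsample of tissue pixels
    (OD norm above :data:`TISSUE_OD_CUTOFF`) with alternating multiplicative
    updates; columns are renormalized to unit length with the compensating
    scale folded into H so the reconstruction is unchanged. Full-resolution
    concentrations are then solved with W held fixed.

    Raises
    ------
    DegenerateInputError
        if fewer than ``n_stains * 50`` tissue pixels are present.
    """
    if n_stains != 3:
        raise ParameterError("only 3-stain decomposition is supported")
    h, w = od.shape
    V_full = od.od.reshape(h * w, 3).T
    norms = np.linalg.norm(V_full, axis=0)
    tissue = np.flatnonzero(
        (norms > TISSUE_OD_CUTOFF) & (V_full.max(axis=0) < DARK_OD_CUTOFF)
    )
    if tissue.size < n_stains * 50:
        raise DegenerateInputError(
            f"only {tissue.size} tissue pixels above OD cutoff; "
            f"need at least {n_stains * 50}"
        )
    rng = np.random.default_rng(seed)
    if tissue.size > max_fit_pixels:
        tissue = rng.choice(tissue, size=max_fit_pixels, replace=False)
    V = V_full[:, tissue]

    # initialize stain vectors from k-means centers of the OD *directions*
    # of tissue pixels; pure-stain pixel clusters put the init near the
    # basin of the true basis, which plain random init often misses
    from sklearn.cluster import KMeans

    directions = (V / np.linalg.norm(V, axis=0, keepdims=True)).T
    km = KMeans(n_clusters=n_stains, n_init=4, random_state=seed)
    km.fit(directions)
    W = np.clip(km.cluster_centers_.T, 1e-3, None)
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    # refit on a cluster-balanced subsample: rare stains (e.g. sparse DAB
    # deposits) would otherwise be sacrificed to the abundant counterstain
    # when intensity noise is present
    per_cluster = max(max_fit_pixels // (2 * n_stains), 100)
    parts = []
    for c in range(n_stains):
        members = np.flatnonzero(km.labels_ == c)
        take = min(per_cluster, members.size)
        parts.append(rng.choice(members, size=take, replace=False))
    V = V[:, np.concatenate(parts)]
    H = np.clip(np.linalg.pinv(W) @ V, 1e-8, None)

    trace = [_snmf_objective(V, W, H, sparsity)]
    best = (trace[0], W.copy(), H.copy())
    converged = False
    for _ in range(max_iter):
        H = _update_H(V, W, H, sparsity)
        W = W * (V @ H.T) / (W @ (H @ H.T) + 1e-12)
        col = np.linalg.norm(W, axis=0)
        col[col == 0] = 1.0
        W /= col
        H *= col[:, None]
        obj = _snmf_objective(V, W, H, sparsity)
        if obj >= best[0] - tol * max(best[0], 1e-12):
            # no sufficient decrease: the alternating updates have reached
            # their floor (the unit-norm projection interacts with the L1
            # term); stop and keep the best iterate
            converged = True
            break
        trace.append(obj)
        best = (obj, W.copy(), H.copy())
    _, W, H = best
    if not converged:
        warnings.warn(
            "SNMF did not converge within max_iter; returning best iterate",
            RuntimeWarning,
        )

    basis = StainBasis(W, stain_names=tuple(f"stain_{i}" for i in range(n_stains)))
    concs = solve_concentrations(od, basis)
    concs = ConcentrationMaps(concs.H, stain_names=basis.stain_names)
    return SNMFResult(basis, concs, np.asarray(trace), converged, seed)


def reconstruction_error(
    od: OpticalDensityImage, basis: StainBasis, concs: ConcentrationMaps
) -> float:
    """Relative Frobenius error ``||V - W H|| / ||V||`` over pixels in the
    stable-OD domain (any-channel OD below :data:`DARK_OD_CUTOFF`);
    near-opaque pixels have no meaningful optical density to reconstruct."""
    V = od.od.reshape(-1, 3).T
    ok = V.max(axis=0) < DARK_OD_CUTOFF
    resid = V[:, ok] - (basis.W @ concs.H)[:, ok]
    return float(np.linalg.norm(resid) / max(np.linalg.norm(V[:, ok]), 1e-12))


def assign_stain_identities(
    basis: StainBasis,
    reference_vectors: np.ndarray = REFERENCE_OD_VECTORS,
    ambiguity_margin: float = 0.01,
):
    """Name SNMF columns by optimal one-to-one cosine matching to reference
    hematoxylin / alkaline-phosphatase / DAB OD vectors.

    Returns the relabeled basis (columns reordered to
    hematoxylin, alkaline_phosphatase, dab) and the permutation ``perm``
    such that ``new_W[:, j] = old_W[:, perm[j]]``. Warns when the best
    assignment beats the runner-up by less than ``ambiguity_margin`` total
    similarity.
    """
    Wn = basis.W / np.linalg.norm(basis.W, axis=0, keepdims=True)
    R = np.asarray(reference_vectors, dtype=float)
    R = R / np.linalg.norm(R, axis=0, keepdims=True)
    sim = R.T @ Wn  # sim[ref, col]
    ref_idx, col_idx = linear_sum_assignment(-sim)
    perm = np.empty(3, dtype=int)
    perm[ref_idx] = col_idx
    best = sim[ref_idx, col_idx].sum()

    scores = sorted(
        (sum(sim[i, p[i]] for i in range(3)) for p in itertools.permutations(range(3))),
        reverse=True,
    )
    if best - scores[1] < ambiguity_margin:
        warnings.warn(
            "stain identity assignment is ambiguous "
            f"(margin {best - scores[1]:.4f})",
            RuntimeWarning,
        )
    return StainBasis(basis.W[:, perm], stain_names=STAIN_NAMES), perm


def alkaline_probability(
    concs: ConcentrationMaps,
    shape,
    norm_percentile: float = 99.0,
    min_normalizer: float = 0.3,
) -> StainProbabilityMap:
    """Reshape the alkaline row of H to the tile grid and rescale to [0, 1].

    The row is divided by its ``norm_percentile``-th percentile (99 by
    default, to resist single-pixel outliers) and clipped to 1; an all-zero
    row maps to an all-zero probability map. The normalizer is floored at
    ``min_normalizer`` (OD concentration units): on tiles without magenta
    staining the percentile sits at the unmixing cross-talk level, and
    dividing by it would amplify noise into spurious full-strength
    probabilities.
    """
    row = concs.H[concs.alkaline_row_index].reshape(shape)
    normalizer = float(np.percentile(row, norm_percentile))
    if normalizer <= 0:
        return StainProbabilityMap(np.zeros(shape), normalizer=0.0)
    normalizer = max(normalizer, min_normalizer)
    return StainProbabilityMap(
        np.clip(row / normalizer, 0.0, 1.0), normalizer=normalizer
    )


def threshold_stain(prob: StainProbabilityMap, t: float = 0.5) -> BinaryMask:
    """Binary stain mask ``S_alkaline = H_alkaline > t`` (strict)."""
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"threshold must lie in [0, 1], got {t}")
    return BinaryMask(prob.H_alkaline > t, provenance="stain")


def separate_stains(
    tile: RGBTile,
    sparsity: float = 0.01,
    max_iter: int = 200,
    seed: int = 0,
    norm_percentile: float = 99.0,
    reference_basis: StainBasis | None = None,
):
    """Full stain route for one tile: OD, SNMF (or a fixed reference basis),
    identity assignment, alkaline probability map.

    Returns ``(basis, concentrations, probability_map)``. When
    ``reference_basis`` is given the SNMF fit is skipped and concentrations
    are solved against that basis — the fallback for degenerate tiles and
    the "fit once, reuse" mode.
    """
    od = rgb_to_od(tile)
    if reference_basis is not None:
        basis = reference_basis
        concs = solve_concentrations(od, basis)
    else:
        result = fit_stain_basis(
            od, sparsity=sparsity, max_iter=max_iter, seed=seed
        )
        basis, perm = assign_stain_identities(result.basis)
        concs = ConcentrationMaps(
            result.concentrations.H[perm], stain_names=STAIN_NAMES
        )
    prob = alkaline_probability(concs, tile.shape, norm_percentile)
    return basis, concs, prob
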