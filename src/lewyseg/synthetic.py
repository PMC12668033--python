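"""Seeded generator of brightfield-like IHC tiles with ground truth.

The generator inverts the analysis model: it composes per-stain
concentration maps (hematoxylin background texture and nuclei, magenta
alpha-synuclein objects, brown microglia distractors), optionally bleeds a
fraction of the DAB concentration into the magenta channel to emulate
brown-stain contamination, and renders pixels through the Beer-Lambert law
``I = I0 * 10**(-W_true @ h)`` plus Gaussian intensity noise.

Aggregate objects come in six shape families mirroring the morphological
classes used for aggregate classification: round Lewy bodies, thin straight
axons, thick tapering dendrites, intermediate wavy undifferentiated
neurites, clusters of closely spaced Lewy bodies, and dispersed speckle
artifacts.

The generator shares no stain-fitting code with the analysis modules: it
only composes with a known basis, which the analyzer must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .types import REFERENCE_OD_VECTORS, RGBTile, StainBasis

AGGREGATE_FAMILIES = (
    "lewy_body",
    "axon",
    "dendrite",
    "undifferentiated_neurite",
    "multiple_lewy_bodies",
    "artifact",
)

#: Families whose rendered objects pass the default size/shape filters
#: (artifacts are dispersed speckle that the area filter is meant to drop).
DETECTABLE_FAMILIES = AGGREGATE_FAMILIES[:5]


@dataclass
class ObjectSpec:
    """One renderable object: a shape family plus concrete geometry.

    Geometry is frozen at sampling time (disk centers, polylines, widths)
    so rasterization is a pure function of the spec.
    """

    shape_family: str
    position: tuple
    amplitude: float = 1.0
    geometry: dict = field(default_factory=dict)


@dataclass
class SceneSpec:
    """Full description of a synthetic tile."""

    tile_size: int = 1024
    stain_basis: StainBasis = None
    objects: list = field(default_factory=list)
    dab_objects: list = field(default_factory=list)
    contamination: float = 0.0
    noise_sd: float = 2.0
    background_od: float = 0.15
    background_texture_od: float = 0.06
    n_nuclei: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.stain_basis is None:
            self.stain_basis = StainBasis(REFERENCE_OD_VECTORS.copy())
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must lie in [0, 1)")


@dataclass
class ObjectRecord:
    label: int
    shape_family: str
    area_px: int
    centroid: tuple
    max_feret_px: float
    coords: np.ndarray


@dataclass
class GroundTruth:
    labels: np.ndarray
    records: list
    H_true: np.ndarray  # (3, H, W) stain concentration maps
    overlapping_labels: list = field(default_factory=list)
    expected_surviving: set | None = None


def feret_bruteforce(coords: np.ndarray) -> float:
    """O(n^2) maximum pairwise pixel-center distance (generator-side oracle,
    kept independent of the analysis implementation)."""
    pts = np.asarray(coords, dtype=np.int64)
    if len(pts) < 2:
        return 0.0
    best = 0
    step = 2000
    for i in range(0, len(pts), step):
        chunk = pts[i : i + step]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, int(d2.max()))
    return float(np.sqrt(best))


def min_set_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two pixel coordinate sets."""
    tree = cKDTree(np.asarray(a, dtype=float))
    d, _ = tree.query(np.asarray(b, dtype=float), k=1)
    return float(np.min(d))


# ---------------------------------------------------------------------------
# rasterization


def _clip_coords(rr, cc, size):
    keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
    return rr[keep], cc[keep]


def _disk_coords(center, radius, size, axis_ratio=1.0, angle=0.0):
    rr, cc = draw_ellipse(
        center[0], center[1], radius, max(radius * axis_ratio, 1.0),
        rotation=angle,
    )
    return _clip_coords(rr, cc, size)


from functools import lru_cache


@lru_cache(maxsize=None)
def _disk_offsets(radius_tenths: int) -> np.ndarray:
    r = radius_tenths / 10.0
    n = int(np.ceil(r))
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    keep = dr * dr + dc * dc <= r * r
    return np.stack([dr[keep], dc[keep]], axis=1)


def _curve_coords(points, widths, size):
    """Stamp disks of the given radii along a dense polyline."""
    pts = np.asarray(points, dtype=float)
    widths = np.asarray(widths, dtype=float)
    dense_p, dense_w = [], []
    for i in range(len(pts) - 1):
        n = max(int(np.ceil(np.linalg.norm(pts[i + 1] - pts[i]))), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        dense_p.append(pts[i] * (1 - t) + pts[i + 1] * t)
        dense_w.append(widths[i] * (1 - t[:, 0]) + widths[i + 1] * t[:, 0])
    P = np.round(np.concatenate(dense_p)).astype(np.int64)
    R10 = np.round(
        np.clip(np.concatenate(dense_w) / 2.0, 0.8, None) * 10
    ).astype(int)
    rows, cols = [], []
    for r10 in np.unique(R10):
        off = _disk_offsets(int(r10))
        c = (P[R10 == r10][:, None, :] + off[None, :, :]).reshape(-1, 2)
        rows.append(c[:, 0])
        cols.append(c[:, 1])
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    flat = rr * (size + 1024) + cc
    _, idx = np.unique(flat, return_index=True)
    return _clip_coords(rr[idx], cc[idx], size)


def rasterize_object(obj: ObjectSpec, tile_size: int):
    """Pixel coordinates (rows, cols) covered by an object."""
    g = obj.geometry
    fam = obj.shape_family
    if fam == "lewy_body":
        return _disk_coords(
            obj.position, g["radius"], tile_size,
            axis_ratio=g.get("axis_ratio", 1.0), angle=g.get("angle", 0.0),
        )
    if fam in ("axon", "dendrite", "undifferentiated_neurite"):
        return _curve_coords(g["points"], g["widths"], tile_size)
    if fam in ("multiple_lewy_bodies", "artifact"):
        rows, cols = [], []
        for center, radius in zip(g["centers"], g["radii"]):
            rr, cc = _disk_coords(center, radius, tile_size)
            rows.append(rr)
            cols.append(cc)
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
        flat = rr.astype(np.int64) * (tile_size + 1024) + cc
        _, idx = np.unique(flat, return_index=True)
        return rr[idx], cc[idx]
    if fam == "microglia":
        rows, cols = [], []
        rr, cc = _disk_coords(obj.position, g["soma_radius"], tile_size)
        rows.append(rr)
        cols.append(cc)
        for pts, w in zip(g["branch_points"], g["branch_widths"]):
            rr, cc = _curve_coords(pts, [w] * len(pts), tile_size)
            rows.append(rr)
            cols.append(cc)
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
        flat = rr.astype(np.int64) * (tile_size + 1024) + cc
        _, idx = np.unique(flat, return_index=True)
        return rr[idx], cc[idx]
    raise ValueError(f"unknown shape family {fam!r}")


# ---------------------------------------------------------------------------
# object sampling

def _random_curve(rng, start, direction, length, curviness, n_ctrl=6):
    pts = [np.asarray(start, dtype=float)]
    theta = direction
    step = length / (n_ctrl - 1)
    for _ in range(n_ctrl - 1):
        theta += rng.normal(0.0, curviness)
        pts.append(pts[-1] + step * np.array([np.sin(theta), np.cos(theta)]))
    return np.stack(pts)


def sample_object(rng: np.random.Generator, family: str, position,
                  amplitude: float | None = None) -> ObjectSpec:
    """Draw one object of a family with within-family parameter jitter.

    Family parameter ranges are chosen so the six classes are separable by
    construction: axons are long, thin and straight; dendrites thick,
    shorter and tapering; undifferentiated neurites intermediate width,
    short and wavy.
    """
    position = tuple(float(p) for p in position)
    if amplitude is None:
        amplitude = float(rng.uniform(0.75, 1.05))
    g = {}
    if family == "lewy_body":
        g = {
            "radius": float(rng.uniform(19, 26)),
            "axis_ratio": float(rng.uniform(0.8, 1.0)),
            "angle": float(rng.uniform(0, np.pi)),
        }
    elif family == "axon":
        length = float(rng.uniform(90, 130))
        pts = _random_curve(rng, position, rng.uniform(0, 2 * np.pi),
                            length, curviness=0.12)
        w = float(rng.uniform(2, 4))
        g = {"points": pts - pts.mean(0) + np.asarray(position),
             "widths": [w] * len(pts)}
    elif family == "dendrite":
        length = float(rng.uniform(50, 90))
        pts = _random_curve(rng, position, rng.uniform(0, 2 * np.pi),
                            length, curviness=0.2)
        w0 = float(rng.uniform(6, 9))
        widths = np.linspace(w0, max(w0 * 0.3, 2.0), len(pts))
        g = {"points": pts - pts.mean(0) + np.asarray(position),
             "widths": list(widths)}
    elif family == "undifferentiated_neurite":
        length = float(rng.uniform(50, 75))
        pts = _random_curve(rng, position, rng.uniform(0, 2 * np.pi),
                            length, curviness=0.3)
        w = float(rng.uniform(3, 5))
        g = {"points": pts - pts.mean(0) + np.asarray(position),
             "widths": [w] * len(pts)}
    elif family == "multiple_lewy_bodies":
        n = int(rng.integers(2, 5))
        centers = [np.asarray(position, dtype=float)]
        radii = [float(rng.uniform(9, 13))]
        for _ in range(n - 1):
            theta = rng.uniform(0, 2 * np.pi)
            r_new = float(rng.uniform(9, 13))
            gap = float(rng.uniform(3, 6))
            dist = radii[0] + r_new + gap
            centers.append(centers[0] + dist * np.array([np.sin(theta), np.cos(theta)]))
            radii.append(r_new)
        g = {"centers": [tuple(c) for c in centers], "radii": radii}
    elif family == "artifact":
        n = int(rng.integers(8, 16))
        centers = [
            tuple(np.asarray(position) + rng.uniform(-30, 30, size=2))
            for _ in range(n)
        ]
        g = {"centers": centers, "radii": [float(rng.uniform(1, 2.2)) for _ in range(n)]}
    elif family == "microglia":
        n_branch = int(rng.integers(2, 5))
        branches, widths = [], []
        for _ in range(n_branch):
            pts = _random_curve(rng, position, rng.uniform(0, 2 * np.pi),
                                float(rng.uniform(20, 40)), curviness=0.3, n_ctrl=4)
            branches.append(pts)
            widths.append(float(rng.uniform(2, 3)))
        g = {
            "soma_radius": float(rng.uniform(5, 9)),
            "branch_points": branches,
            "branch_widths": widths,
        }
        # microglial DAB staining is strong and variable; the spread makes
        # channel-bleed artifacts cross the stain threshold gradually as
        # the contamination fraction rises
        if amplitude is None or amplitude < 1.1:
            amplitude = float(rng.uniform(1.2, 2.4))
    else:
        raise ValueError(f"unknown shape family {family!r}")
    return ObjectSpec(family, position, amplitude, g)


def sample_scene(
    n_objects: int,
    tile_size: int = 256,
    seed: int = 0,
    families=AGGREGATE_FAMILIES,
    n_dab: int = 0,
    contamination: float = 0.0,
    noise_sd: float = 2.0,
    min_separation: float = 30.0,
    margin: int = 40,
) -> SceneSpec:
    """Sample a scene of well-separated aggregates (plus optional microglia
    distractors) with pairwise boundary distance > ``min_separation``."""
    rng = np.random.default_rng(seed)
    placed_coords = []
    objects = []
    attempts = 0
    while len(objects) < n_objects and attempts < n_objects * 200:
        attempts += 1
        fam = families[int(rng.integers(len(families)))]
        pos = rng.uniform(margin, tile_size - margin, size=2)
        obj = sample_object(rng, fam, pos)
        rr, cc = rasterize_object(obj, tile_size)
        if len(rr) == 0:
            continue
        coords = np.stack([rr, cc], axis=1)
        if any(min_set_distance(c, coords) <= min_separation for c in placed_coords):
            continue
        objects.append(obj)
        placed_coords.append(coords)
    dabs = []
    attempts = 0
    dab_sep = max(min_separation * 0.5, 10.0)
    while len(dabs) < n_dab and attempts < n_dab * 500:
        attempts += 1
        pos = rng.uniform(margin, tile_size - margin, size=2)
        obj = sample_object(rng, "microglia", pos)
        rr, cc = rasterize_object(obj, tile_size)
        coords = np.stack([rr, cc], axis=1)
        if any(min_set_distance(c, coords) <= dab_sep for c in placed_coords):
            continue
        dabs.append(obj)
        placed_coords.append(coords)
    return SceneSpec(
        tile_size=tile_size,
        objects=objects,
        dab_objects=dabs,
        contamination=contamination,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering

def render_tile(spec: SceneSpec, white_point: float = 255.0):
    """Render a scene to an :class:`RGBTile` plus its :class:`GroundTruth`.

    Deterministic for a fixed spec (the spec's seed drives background
    texture, nuclei placement and pixel noise).
    """
    size = spec.tile_size
    rng = np.random.default_rng(spec.seed)

    H_hema = np.full((size, size), spec.background_od)
    if spec.background_texture_od > 0:
        tex = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=12)
        sd = tex.std()
        if sd > 0:
            H_hema += spec.background_texture_od * tex / sd
        H_hema = np.clip(H_hema, 0.0, None)
    n_nuclei = spec.n_nuclei
    if n_nuclei is None:
        n_nuclei = max(int(round(10 * (size / 256) ** 2)), 0)
    for _ in range(n_nuclei):
        pos = rng.uniform(0, size, size=2)
        rr, cc = _disk_coords(pos, rng.uniform(3, 5), size)
        H_hema[rr, cc] += rng.uniform(0.25, 0.45)

    H_alk = np.zeros((size, size))
    H_dab = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    records = []
    overlapping = []
    for i, obj in enumerate(spec.objects, start=1):
        rr, cc = rasterize_object(obj, size)
        if len(rr) == 0:
            continue
        H_alk[rr, cc] = np.maximum(H_alk[rr, cc], obj.amplitude)
        prev = np.unique(labels[rr, cc])
        for p in prev:
            if p > 0:
                overlapping.append((int(p), i))
        labels[rr, cc] = i
        coords = np.stack([rr, cc], axis=1)
        records.append(
            ObjectRecord(
                label=i,
                shape_family=obj.shape_family,
                area_px=len(rr),
                centroid=(float(rr.mean()), float(cc.mean())),
                max_feret_px=feret_bruteforce(coords),
                coords=coords,
            )
        )
    for obj in spec.dab_objects:
        rr, cc = rasterize_object(obj, size)
        # DAB deposition fades toward the rim; keeps a ring of moderate
        # pure-brown OD even for intensely stained microglia
        m = np.zeros((size, size), dtype=bool)
        m[rr, cc] = True
        core = binary_erosion(m, iterations=2)
        rim = m & ~core
        H_dab[core] = np.maximum(H_dab[core], obj.amplitude)
        H_dab[rim] = np.maximum(H_dab[rim], 0.55 * obj.amplitude)

    # dense chromogen deposits largely displace the nuclear counterstain,
    # which also gives the unmixing near-pure pixels of each stain
    occupancy = np.clip(H_alk + H_dab, 0.0, 1.0)
    H_hema = H_hema * (1.0 - 0.9 * occupancy)

    H_alk_rendered = H_alk + spec.contamination * H_dab
    H_true = np.stack([H_hema, H_alk_rendered, H_dab])
    od = np.einsum("cs,shw->hwc", spec.stain_basis.W, H_true)
    pixels = white_point * 10.0 ** (-od)
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
    pixels = np.clip(pixels, 0.0, white_point)
    tile = RGBTile(pixels, white_point=white_point)
    gt = GroundTruth(labels=labels, records=records, H_true=H_true,
                     overlapping_labels=overlapping)
    return tile, gt


# ---------------------------------------------------------------------------
# threshold fixture

def _bar_plus_block(origin, bar_len, block_rows):
    """Pixel set: a 1-px horizontal bar of ``bar_len`` pixels (Feret =
    bar_len - 1) plus rows of filler pixels chosen inside the ball that
    keeps the bar endpoints the farthest pair."""
    r0, c0 = origin
    coords = [(r0, c0 + j) for j in range(bar_len)]
    for dr, cols in block_rows:
        coords.extend((r0 + dr, c0 + j) for j in cols)
    return coords


def _lens_500_feret_32(center):
    """Exactly 500 pixels with maximum Feret diameter exactly 32: a disk of
    radius 16 restricted to |row offset| <= 7 (459 px) plus 41 pixels on the
    rows at offset +-8, all within distance 32 of both bar extremes."""
    r0, c0 = center
    coords = []
    for i in range(-7, 8):
        jmax = int(np.floor(np.sqrt(256 - i * i)))
        coords.extend((r0 + i, c0 + j) for j in range(-jmax, jmax + 1))
    coords.extend((r0 + 8, c0 + j) for j in range(-10, 11))
    coords.extend((r0 - 8, c0 + j) for j in range(-10, 10))
    return coords


def make_threshold_fixture(white_point: float = 255.0):
    """Deterministic tile exercising the Ts/Td/TF boundary conventions.

    Five magenta objects, left-aligned so vertical gaps are exact minimum
    distances, alternating 15 and 25 px:

    ======  =====  ======  =================================
    object  area   Feret   fate under (Ts, Td, TF)=(100,20,33)
    ======  =====  ======  =================================
    D       500    80.0    kept
    A       50     10.0    removed (area < 100)
    B       99     80.0    removed (area < 100)
    C       100    33.0    kept (both boundaries sit exactly on keep side)
    E       500    32.0    removed (Feret < 33)
    ======  =====  ======  =================================

    The 15-px gaps sit next to A and B, which the area filter removes
    before label association, so no merges occur among survivors. The
    expected surviving label set is computed here by direct application of
    the filter rules to the constructed pixel sets, independent of the
    instance-processing implementation.
    """
    size = 256
    shapes = {}
    # D: area 500, feret 80 (bar of 81 at row 30, cols 20..100)
    shapes["D"] = _bar_plus_block(
        (30, 20), 81,
        [(k, range(1, 80)) for k in range(1, 6)] + [(6, range(1, 25))],
    )
    # A: area 50, feret 10 (bar of 11 at row 51)
    shapes["A"] = _bar_plus_block(
        (51, 20), 11,
        [(k, range(1, 10)) for k in range(1, 5)] + [(5, range(4, 7))],
    )
    # B: area 99, feret 80 (bar of 81 at row 81)
    shapes["B"] = _bar_plus_block((81, 20), 81, [(1, range(1, 19))])
    # C: area 100, feret 33 (bar of 34 at row 97)
    shapes["C"] = _bar_plus_block(
        (97, 20), 34, [(k, range(2, 24)) for k in range(1, 4)]
    )
    # E: area 500, feret 32
    shapes["E"] = _lens_500_feret_32((133, 36))

    order = ["D", "A", "B", "C", "E"]
    H_alk = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    records = []
    for i, name in enumerate(order, start=1):
        coords = np.asarray(shapes[name], dtype=np.int64)
        H_alk[coords[:, 0], coords[:, 1]] = 1.0
        labels[coords[:, 0], coords[:, 1]] = i
        records.append(
            ObjectRecord(
                label=i,
                shape_family="fixture",
                area_px=len(coords),
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                max_feret_px=feret_bruteforce(coords),
                coords=coords,
            )
        )

    expected = _apply_filter_rules(records, Ts=100, Td=20, TF=33)

    H_hema = np.full((size, size), 0.25)
    H_dab = np.zeros((size, size))
    H_true = np.stack([H_hema, H_alk, H_dab])
    basis = StainBasis(REFERENCE_OD_VECTORS.copy())
    od = np.einsum("cs,shw->hwc", basis.W, H_true)
    pixels = np.clip(white_point * 10.0 ** (-od), 0.0, white_point)
    tile = RGBTile(pixels, white_point=white_point)
    gt = GroundTruth(labels=labels, records=records, H_true=H_true,
                     expected_surviving=expected)
    return tile, gt


def _apply_filter_rules(records, Ts, Td, TF):
    """Spell out the post-processing rules on ground-truth records:
    strict area removal, transitive distance-<=Td merging among survivors,
    strict Feret removal on merged groups. Brute-force throughout."""
    survivors = [r for r in records if r.area_px >= Ts]
    parent = {r.label: r.label for r in survivors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(survivors):
        for b in survivors[i + 1:]:
            if min_set_distance(a.coords, b.coords) <= Td:
                parent[find(a.label)] = find(b.label)
    groups = {}
    for r in survivors:
        groups.setdefault(find(r.label), []).append(r)
    expected = set()
    for members in groups.values():
        coords = np.concatenate([m.coords for m in members])
        if feret_bruteforce(coords) >= TF:
            expected.update(m.label for m in members)
    return expected


# ---------------------------------------------------------------------------
# crop families

def make_crop_families(n_per_class: int, seed: int = 0, crop_size: int = 256):
    """Labeled 256x256 (by default) crops, one centered object per crop,
    ``n_per_class`` per shape family, with within-family jitter.

    Returns ``(crops, labels, manifest)`` where crops is a float array
    ``(6 * n_per_class, crop_size, crop_size, 3)``, labels the family names
    aligned with crops, and manifest a pandas DataFrame (crop_id, label).
    """
    import pandas as pd

    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for family in AGGREGATE_FAMILIES:
        for j in range(n_per_class):
            obj = sample_object(rng, family, (crop_size / 2, crop_size / 2))
            spec = SceneSpec(
                tile_size=crop_size,
                objects=[obj],
                noise_sd=2.0,
                n_nuclei=max(int(round(4 * (crop_size / 256) ** 2)), 1),
                seed=int(rng.integers(2**31 - 1)),
            )
            tile, _ = render_tile(spec)
            crops.append(tile.pixels)
            labels.append(family)
    crops = np.stack(crops)
    manifest = pd.DataFrame(
        {"crop_id": np.arange(len(labels)), "label": labels}
    )
    return crops, np.asarray(labels), manifest
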