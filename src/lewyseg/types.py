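"""Core value types passed between pipeline stages.

The pipeline operates on brightfield immunohistochemistry tiles in which
three chromogens absorb light according to the Beer-Lambert law:
hematoxylin (blue nuclear counterstain), alkaline phosphatase (magenta,
marking alpha-synuclein aggregates) and DAB (brown, marking microglia).
Everything downstream of the raw tile is expressed either in optical
density (OD, linear in stain concentration) or as per-pixel probabilities
and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidWhitePointError

#: OD unit vectors used to name SNMF columns, and as the ground-truth basis
#: of the synthetic generator's renderer. Order: hematoxylin, alkaline
#: phosphatase, DAB. Mutually > 20 degrees apart so unmixing is well posed.
STAIN_NAMES = ("hematoxylin", "alkaline_phosphatase", "dab")


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


REFERENCE_OD_VECTORS = np.stack(
    [
        _unit([0.65, 0.70, 0.29]),   # hematoxylin: absorbs red+green -> blue
        _unit([0.15, 0.95, 0.27]),   # alkaline phosphatase: absorbs green -> magenta
        _unit([0.27, 0.57, 0.78]),   # DAB: broad absorption -> brown
    ],
    axis=1,
)  # shape (3, 3); columns are stains


@dataclass
class RGBTile:
    """One brightfield tile.

    pixels are stored as floats in [0, white_point]; ``white_point`` is the
    intensity of unstained background (255 for 8-bit scans) and
    ``pixel_size_um`` the physical pixel pitch.
    """

    pixels: np.ndarray
    white_point: float = 255.0
    pixel_size_um: float = 0.45

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.white_point <= 0:
            raise InvalidWhitePointError(
                f"white_point must be positive, got {self.white_point}"
            )
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if min(self.pixels.shape[:2]) < 16:
            raise ValueError("tile must be at least 16 x 16")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class OpticalDensityImage:
    """Per-pixel optical density, H x W x 3, nonnegative."""

    od: np.ndarray

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)

    @property
    def shape(self):
        return self.od.shape[:2]


@dataclass
class StainBasis:
    """Stain color basis W: a 3x3 matrix whose unit-norm columns are OD
    vectors, labeled by ``stain_names`` after identity assignment."""

    W: np.ndarray
    stain_names: tuple = STAIN_NAMES

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (3, 3):
            raise ValueError("W must be 3x3")

    def column(self, name: str) -> np.ndarray:
        return self.W[:, self.stain_names.index(name)]


@dataclass
class ConcentrationMaps:
    """Stain concentration maps H: one row per stain, flattened pixels."""

    H: np.ndarray
    stain_names: tuple = STAIN_NAMES

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)

    @property
    def alkaline_row_index(self) -> int:
        return self.stain_names.index("alkaline_phosphatase")


@dataclass
class StainProbabilityMap:
    """Normalized alkaline-phosphatase concentration in [0, 1]; the
    ``normalizer`` used for scaling is kept for reproducibility."""

    H_alkaline: np.ndarray
    normalizer: float

    def __post_init__(self):
        self.H_alkaline = np.asarray(self.H_alkaline, dtype=float)


@dataclass
class BinaryMask:
    """A boolean mask plus the pipeline stage that produced it."""

    mask: np.ndarray
    provenance: str = "stain"  # stain | attention | refined | combined

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self):
        return self.mask.shape
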