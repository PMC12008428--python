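"""Core imaging containers: B-scan image, ROI mask, discretized ROI.

All pixel grids are row-major (row, col); physical spacing is given per
axis in millimetres. Gray-level discretization uses the fixed-bin-width
scheme common to radiomics engines: level = floor((x - min)/w) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InputError(ValueError):
    """Raised when an image/mask/parameter violates an operation contract."""


@dataclass
class BScanImage:
    """A single 2D OCT B-scan.

    Parameters
    ----------
    pixels : (H, W) array
        Intensity grid. 8-bit integers as read from disk; real-valued
        after filtering.
    spacing_mm : (float, float)
        Physical size of one pixel along (row, col), in mm.
    id : str
        Eye/image identifier.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (0.011, 0.011)
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 8:
            raise InputError("image must be 2D with H, W >= 8")
        if min(self.spacing_mm) <= 0:
            raise InputError("pixel spacing must be positive")


@dataclass
class ROIMask:
    """Binary region-of-interest mask, same shape as its image.

    A mask must be nonempty; texture extraction additionally requires
    at least 16 foreground pixels (enforced at extraction time, since
    tiny masks are legitimate as intermediate annotation artifacts).
    """

    MIN_EXTRACTION_PIXELS = 16

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise InputError("mask must be 2D")
        if not self.pixels.any():
            raise InputError("mask must be nonempty")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DiscretizedROI:
    """Gray-level discretization of a masked image.

    ``levels`` holds integer levels 1..Ng inside the mask and 0 outside.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_width: float
    # edges of the bins actually used, handy for first-order entropy
    bin_edges: np.ndarray = field(default=None, repr=False)

    @property
    def in_mask(self) -> np.ndarray:
        """1-D array of in-mask levels."""
        return self.levels[self.mask]


def discretize(image, mask, bin_width: float = 25.0) -> DiscretizedROI:
    """Fixed-bin-width gray-level discretization of the masked region.

    level = floor((x - min_in_mask)/bin_width) + 1; Ng = max level.
    Constant regions collapse to a single level.
    """
    px = np.asarray(image.pixels if isinstance(image, BScanImage) else image, dtype=float)
    m = np.asarray(mask.pixels if isinstance(mask, ROIMask) else mask).astype(bool)
    if px.shape != m.shape:
        raise InputError("image and mask shapes differ")
    if not m.any():
        raise InputError("empty mask")
    if not bin_width > 0:
        raise InputError("bin_width must be > 0")
    vals = px[m]
    lo = vals.min()
    lev = np.zeros(px.shape, dtype=np.int64)
    lev[m] = np.floor((px[m] - lo) / bin_width).astype(np.int64) + 1
    ng = int(lev[m].max())
    edges = lo + bin_width * np.arange(ng + 1)
    return DiscretizedROI(levels=lev, mask=m, ng=ng, bin_width=float(bin_width), bin_edges=edges)
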