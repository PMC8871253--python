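"""ROI rasterization and per-ROI gray-level normalization.

All texture features downstream are computed on quantized gray levels
obtained by clipping the ROI histogram to the mean +/- 3 SD band and
rescaling linearly onto integer levels ``1..Ng``.  Normalization is
performed per ROI (not per image): the statistics mu and sigma are
estimated from the masked pixels only, so nothing outside the ROI can
influence any feature value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import DataError, GeometryError

__all__ = [
    "GrayImage",
    "PolygonROI",
    "NormalizedROI",
    "rasterize",
    "normalize_mu3sigma",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with explicit bit depth.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Non-negative integer gray values, row-major.
    bit_depth : int
        Number of bits per pixel; every value must be < ``2**bit_depth``.
    """

    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DataError(f"image must be 2-D, got shape {px.shape}")
        if px.size and (px.min() < 0 or px.max() >= 2 ** self.bit_depth):
            raise DataError(
                f"pixel values outside [0, 2^{self.bit_depth}) for the stated bit depth"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PolygonROI:
    """A simple polygon in pixel coordinates, ``vertices[k] = (x, y)``.

    x is the column coordinate and y the row coordinate; the polygon is
    closed implicitly (last vertex connects back to the first).
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def area(self) -> float:
        """Signed shoelace area, absolute value."""
        v = self.as_array()
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))

    def translated(self, dx: float, dy: float) -> "PolygonROI":
        return PolygonROI(tuple((x + dx, y + dy) for x, y in self.vertices))


@dataclass
class NormalizedROI:
    """Quantized gray levels on a boolean mask.

    ``levels`` holds integers in ``[1, ng]`` at mask positions and 0
    elsewhere; ``mu``/``sigma`` are the original ROI mean and SD used
    for the clip-and-rescale.
    """

    mask: np.ndarray
    levels: np.ndarray
    ng: int
    mu: float
    sigma: float

    def masked_levels(self) -> np.ndarray:
        """1-D array of the in-mask levels."""
        return self.levels[self.mask]


def rasterize(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask over an image grid.

    A pixel at (row r, col c) belongs to the mask when its center
    ``(c + 0.5, r + 0.5)`` lies inside the polygon (even-odd rule).

    Parameters
    ----------
    roi : PolygonROI
    shape : (rows, cols)

    Returns
    -------
    ndarray of bool, shape ``shape``

    Raises
    ------
    GeometryError
        If the polygon is degenerate (zero area), lies outside the
        image bounds, or covers no pixel center.
    """
    rows, cols = shape
    if roi.area() <= 0.0:
        raise GeometryError("degenerate polygon (zero area)")
    v = roi.as_array()
    if v[:, 0].min() < 0 or v[:, 1].min() < 0 or v[:, 0].max() > cols or v[:, 1].max() > rows:
        raise GeometryError("polygon extends outside the image bounds")
    path = MplPath(np.vstack([v, v[:1]]), closed=True)  # explicit ring closure
    cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    # radius=0: pure even-odd inside test on pixel centers
    mask = path.contains_points(pts).reshape(rows, cols)
    if not mask.any():
        raise GeometryError("polygon covers no pixel center (empty mask)")
    return mask


def normalize_mu3sigma(
    image: GrayImage | np.ndarray, mask: np.ndarray, ng: int = 64
) -> NormalizedROI:
    """Clip the ROI histogram to mu +/- 3 sigma and quantize to ``ng`` levels.

    mu and sigma are the mean and (population) SD of the masked pixels.
    Values are clipped to ``[mu - 3 sigma, mu + 3 sigma]`` and mapped
    linearly onto integer levels ``1..ng``::

        level = 1 + floor((clip(v) - (mu - 3 sigma)) / (6 sigma) * ng)

    with the upper edge closed (``v = mu + 3 sigma`` maps to ``ng``).
    A constant ROI (sigma = 0) maps every pixel to ``ceil(ng / 2)`` and
    emits a warning.

    Returns
    -------
    NormalizedROI
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if px.shape != mask.shape:
        raise DataError("image and mask shapes differ")
    if not mask.any():
        raise DataError("empty mask")
    if ng < 2:
        raise DataError("ng must be >= 2")
    vals = px[mask].astype(float)
    mu = float(vals.mean())
    sigma = float(vals.std())  # population SD over the ROI
    levels = np.zeros(px.shape, dtype=np.int64)
    if sigma == 0.0:
        warnings.warn("constant ROI (sigma = 0); mapping all pixels to the mid level")
        levels[mask] = int(np.ceil(ng / 2))
    else:
        lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
        clipped = np.clip(vals, lo, hi)
        lv = 1 + np.floor((clipped - lo) / (6.0 * sigma) * ng).astype(np.int64)
        levels[mask] = np.minimum(lv, ng)  # close the upper edge
    return NormalizedROI(mask=mask, levels=levels, ng=ng, mu=mu, sigma=sigma)
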