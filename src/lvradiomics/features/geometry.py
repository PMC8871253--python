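"""Shape descriptors of the binary ROI mask (98 values).

The geometry family is intensity-independent: every descriptor is a
function of the mask alone.  The classical texture-analysis programs
this naming scheme comes from do not publish closed-form definitions
for their geometry descriptors, so the definitions below are documented
reconstructions, versioned with the manifest:

``GeoF``          mask area in pixels.
``GeoPerim``      perimeter (skimage convention, line through border
                  pixel centers).
``GeoConvP``      perimeter of the convex hull image.
``GeoEl``         elongation: ratio of major to minor second-moment
                  axis lengths, computed on unit-square pixels (each
                  pixel contributes 1/12 to both axis variances), so a
                  w x h rectangle gives exactly max(w,h)/min(w,h).
``GeoEcc/GeoOrient``  eccentricity and orientation (radians) of the
                  equivalent ellipse.
``GeoCompact``    4 pi A / P^2.
``GeoExtent``     A / bounding-box area; ``GeoSolidity`` A / convex area.
``GeoEqDiam``     diameter of the equal-area circle.
``GeoSxL/GeoSyL`` bounding-box width (columns) and height (rows).
``GeoMajAx/GeoMinAx``  equivalent-ellipse axis lengths.
``GeoW1..GeoW16``  Feret extents of the pixel-center cloud at angles
                  k * 180/16 degrees, plus one pixel width.
``GeoW1b..GeoW16b``  the same extents divided by the area (dimensionless
                  slenderness indices).
``GeoHu1..7``     Hu moment invariants.
``GeoEta..``/``GeoMu..``  normalized / raw central moments to order 4.
``GeoRad*``       statistics of centroid-to-boundary-pixel distances
                  (mean, SD, min, max, min/max ratio, Shannon entropy
                  of a 10-bin histogram, skewness, excess kurtosis).
``GeoPrH*/GeoPrV*``  statistics of the horizontal (row-sum) and
                  vertical (column-sum) projection profiles over the
                  occupied rows/columns.
``GeoBBoxAR``     bounding-box aspect ratio (>= 1); ``GeoFeretMax/Min/
                  Ratio`` extremes of the 16 Feret extents; ``GeoCHullA``
                  convex hull area.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..errors import DataError
from .manifest import GEOMETRY_NAMES, _MOMENT_ORDERS

__all__ = ["geometry_features"]

_N_FERET = 16


def _moments_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        return mean, float(np.sqrt(var)), float((z**3).mean()), float((z**4).mean() - 3.0)
    return mean, 0.0, 0.0, 0.0


def geometry_features(mask: np.ndarray) -> dict[str, float]:
    """Compute the 98 geometry descriptors of a boolean mask."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise DataError("empty mask")
    out: dict[str, float] = {}
    props = measure.regionprops(m.astype(np.uint8))[0]
    area = float(m.sum())
    rr, cc = np.nonzero(m)
    r_mean, c_mean = rr.mean(), cc.mean()

    perim = float(props.perimeter)
    bbox_h = float(rr.max() - rr.min() + 1)
    bbox_w = float(cc.max() - cc.min() + 1)
    convex = props.image_convex
    convex_area = float(convex.sum())
    conv_props = measure.regionprops(convex.astype(np.uint8))[0]

    out["GeoF"] = area
    out["GeoPerim"] = perim
    out["GeoConvP"] = float(conv_props.perimeter)

    # second-moment elongation on unit-square pixels: exact for rectangles
    mu20 = float(((cc - c_mean) ** 2).sum()) + area / 12.0
    mu02 = float(((rr - r_mean) ** 2).sum()) + area / 12.0
    mu11 = float(((cc - c_mean) * (rr - r_mean)).sum())
    tr, det = mu20 + mu02, mu20 * mu02 - mu11**2
    disc = max(tr**2 / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = max(tr / 2.0 - np.sqrt(disc), 1e-12)
    out["GeoEl"] = float(np.sqrt(lam1 / lam2))

    out["GeoEcc"] = float(props.eccentricity)
    out["GeoOrient"] = float(props.orientation)
    out["GeoCompact"] = float(4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
    out["GeoExtent"] = area / (bbox_h * bbox_w)
    out["GeoSolidity"] = area / convex_area
    out["GeoEqDiam"] = float(props.equivalent_diameter_area)
    out["GeoSxL"] = bbox_w
    out["GeoSyL"] = bbox_h
    out["GeoMajAx"] = float(props.axis_major_length)
    out["GeoMinAx"] = float(props.axis_minor_length)

    # Feret extents of the pixel-center cloud at evenly spaced angles
    pts = np.column_stack([cc, rr]).astype(float)
    ferets = []
    for k in range(_N_FERET):
        theta = np.pi * k / _N_FERET
        proj = pts @ np.array([np.cos(theta), np.sin(theta)])
        ferets.append(float(proj.max() - proj.min() + 1.0))
    for k, w in enumerate(ferets, start=1):
        out[f"GeoW{k}"] = w
    for k, w in enumerate(ferets, start=1):
        out[f"GeoW{k}b"] = w / area

    hu = props.moments_hu
    for k in range(7):
        out[f"GeoHu{k + 1}"] = float(hu[k])

    # central and normalized central moments to order 4 (pixel centers)
    dx = cc - c_mean
    dyv = rr - r_mean
    mu_all = {}
    for order in _MOMENT_ORDERS:
        p, q = int(order[0]), int(order[1])
        mu_all[order] = float((dx**p * dyv**q).sum())
    for order in _MOMENT_ORDERS:
        p, q = int(order[0]), int(order[1])
        out[f"GeoEta{order}"] = mu_all[order] / area ** (1.0 + (p + q) / 2.0)
    for order in _MOMENT_ORDERS:
        out[f"GeoMu{order}"] = mu_all[order]

    # radial distances from centroid to boundary pixels
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    boundary = m & ~interior
    br, bc = np.nonzero(boundary)
    rad = np.sqrt((br - r_mean) ** 2 + (bc - c_mean) ** 2)
    rmean, rsd, rskew, rkurt = _moments_stats(rad)
    out["GeoRadMean"] = rmean
    out["GeoRadSD"] = rsd
    out["GeoRadMin"] = float(rad.min())
    out["GeoRadMax"] = float(rad.max())
    out["GeoRadRatio"] = float(rad.min() / rad.max()) if rad.max() > 0 else 1.0
    hist, _ = np.histogram(rad, bins=10)
    p_r = hist[hist > 0] / hist.sum()
    out["GeoRadEntropy"] = float(-(p_r * np.log(p_r)).sum())
    out["GeoRadSkew"] = rskew
    out["GeoRadKurt"] = rkurt

    # projection profiles over occupied rows / columns
    prof_h = m.sum(axis=1)[m.any(axis=1)].astype(float)
    prof_v = m.sum(axis=0)[m.any(axis=0)].astype(float)
    hm, hs, hsk, hk = _moments_stats(prof_h)
    vm, vs, vsk, vk = _moments_stats(prof_v)
    out.update(
        GeoPrHMean=hm, GeoPrHSD=hs, GeoPrHSkew=hsk, GeoPrHKurt=hk,
        GeoPrVMean=vm, GeoPrVSD=vs, GeoPrVSkew=vsk, GeoPrVKurt=vk,
    )

    out["GeoBBoxAR"] = max(bbox_w, bbox_h) / min(bbox_w, bbox_h)
    out["GeoFeretMax"] = max(ferets)
    out["GeoFeretMin"] = min(ferets)
    out["GeoFeretRatio"] = max(ferets) / min(ferets)
    out["GeoCHullA"] = convex_area

    assert tuple(out) == GEOMETRY_NAMES, "geometry names out of sync with manifest"
    return out
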