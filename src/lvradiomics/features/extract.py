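"""Full feature-vector extraction for one (image, ROI) pair.

Quantization depth is family-specific (configurable through the
manifest): 64 levels for co-occurrence and run-length statistics, 256
for histogram, gradient, autoregressive and wavelet statistics.
Features that are undefined for a particular ROI (e.g. a wavelet scale
larger than the ROI bounding box) are reported as NaN and handled by
the screening stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..imaging import GrayImage, PolygonROI, normalize_mu3sigma, rasterize
from .geometry import geometry_features
from .manifest import (
    FeatureManifest,
    RLM_DIRECTIONS,
    default_manifest,
    glcm_offsets,
    offset_name,
)
from . import texture

__all__ = ["extract_all", "RadiomicsExtractor"]


def extract_all(
    image: GrayImage | np.ndarray,
    roi: PolygonROI | np.ndarray,
    manifest: FeatureManifest | None = None,
) -> pd.Series:
    """Extract the full feature vector for one ROI.

    Parameters
    ----------
    image : GrayImage or raw pixel matrix
    roi : PolygonROI, or a precomputed boolean mask
    manifest : defaults to ``manifest_v1`` (377 features)

    Returns
    -------
    pandas.Series indexed by manifest feature names.
    """
    manifest = manifest or default_manifest()
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if isinstance(roi, PolygonROI):
        mask = rasterize(roi, px.shape)
    else:
        mask = np.asarray(roi, dtype=bool)

    norm64 = normalize_mu3sigma(px, mask, ng=64)
    norm256 = normalize_mu3sigma(px, mask, ng=256)

    values: dict[str, float] = {}
    values.update(texture.histogram_features(norm256.levels, mask))
    values.update(texture.gradient_features(norm256.levels, mask))
    for dx, dy in glcm_offsets():
        prefix = offset_name(dx, dy)
        try:
            P = texture.glcm(norm64.levels, mask, (dx, dy))
            stats = texture.glcm_features(P)
        except Exception:
            stats = {k: float("nan") for k in texture.GLCM_STATS}
        values.update({f"{prefix}{k}": v for k, v in stats.items()})
    for dname, step in RLM_DIRECTIONS.items():
        stats = texture.rlm_features(norm64.levels, mask, step)
        values.update({f"{dname}_{k}": v for k, v in stats.items()})
    values.update(texture.ar_features(norm256.levels, mask))
    values.update(texture.wavelet_features(norm256.levels, mask))
    values.update(geometry_features(mask))

    out = pd.Series([values[n] for n in manifest.names], index=manifest.names, dtype=float)
    return out


class RadiomicsExtractor:
    """Stateless transformer turning (image, ROI) pairs into a feature table.

    sklearn-compatible: ``fit`` is a no-op, ``transform`` maps a list of
    ``(GrayImage, PolygonROI)`` pairs (or ``(pixels, mask)`` pairs) to a
    DataFrame with one manifest-named column per feature.
    """

    def __init__(self, manifest: FeatureManifest | None = None):
        self.manifest = manifest

    def get_params(self, deep: bool = True) -> dict:
        return {"manifest": self.manifest}

    def set_params(self, **params) -> "RadiomicsExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "RadiomicsExtractor":
        self.manifest_ = self.manifest or default_manifest()
        return self

    def transform(self, X, subject_ids=None) -> pd.DataFrame:
        if not hasattr(self, "manifest_"):
            self.fit()
        rows = [extract_all(img, roi, self.manifest_) for img, roi in X]
        idx = subject_ids if subject_ids is not None else range(len(rows))
        return pd.DataFrame(rows, index=pd.Index(idx, name="subject_id"))

    def fit_transform(self, X, y=None, **kw) -> pd.DataFrame:
        return self.fit(X, y).transform(X, **kw)
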