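"""The versioned feature manifest.

The default manifest (``manifest_v1``) enumerates exactly 377 named
features across seven families:

====================  =====  =========================================
family                count  layout
====================  =====  =========================================
histogram                 9  Mean .. Perc99
gradient                  5  GrMean .. GrNonZeros
cooccurrence            220  11 statistics x 20 offsets
                             (d,0), (0,d), (d,d), (d,-d) for d = 1..5
runlength                20  5 statistics x 4 directions
ar_model                  5  Teta1..Teta4, Sigma
wavelet                  20  4 subbands x 5 scales
geometry                 98  shape descriptors of the binary mask
====================  =====  =========================================

Co-occurrence names follow the ``S(dx,dy)Stat`` convention (dx =
column offset, dy = row offset; rows grow downward), run-length names
the ``Horzl_/Vertl_/45dgr_/135dr_`` prefixes, and wavelet names the
``WavEnXX_s-k`` pattern, matching the naming scheme used by classical
texture-analysis software.  Geometry descriptor names are reconstructed
(documented in :mod:`lvradiomics.features.geometry`); their definitions
are versioned with the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

__all__ = [
    "FeatureSpec",
    "FeatureManifest",
    "default_manifest",
    "GLCM_STATS",
    "RLM_STATS",
    "RLM_DIRECTIONS",
    "HISTOGRAM_NAMES",
    "GRADIENT_NAMES",
    "AR_NAMES",
    "WAVELET_SUBBANDS",
    "WAVELET_SCALES",
    "GEOMETRY_NAMES",
]

GLCM_STATS = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)

RLM_STATS = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
# direction name -> (dy, dx) unit step
RLM_DIRECTIONS = {
    "Horzl": (0, 1),
    "Vertl": (1, 0),
    "45dgr": (-1, 1),
    "135dr": (-1, -1),
}

HISTOGRAM_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc01",
    "Perc10",
    "Perc50",
    "Perc90",
    "Perc99",
)

GRADIENT_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")

AR_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")

WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")
WAVELET_SCALES = (1, 2, 3, 4, 5)

_MOMENT_ORDERS = ("20", "11", "02", "30", "21", "12", "03", "40", "31", "22", "13", "04")

GEOMETRY_NAMES = (
    # basic shape scalars
    "GeoF", "GeoPerim", "GeoConvP", "GeoEl", "GeoEcc", "GeoOrient",
    "GeoCompact", "GeoExtent", "GeoSolidity", "GeoEqDiam",
    "GeoSxL", "GeoSyL", "GeoMajAx", "GeoMinAx",
    # Feret extents at 16 angles and their area-normalized versions
    *[f"GeoW{k}" for k in range(1, 17)],
    *[f"GeoW{k}b" for k in range(1, 17)],
    # Hu invariants
    *[f"GeoHu{k}" for k in range(1, 8)],
    # normalized and raw central moments up to order 4
    *[f"GeoEta{o}" for o in _MOMENT_ORDERS],
    *[f"GeoMu{o}" for o in _MOMENT_ORDERS],
    # radial (centroid-to-boundary) distance statistics
    "GeoRadMean", "GeoRadSD", "GeoRadMin", "GeoRadMax",
    "GeoRadRatio", "GeoRadEntropy", "GeoRadSkew", "GeoRadKurt",
    # projection-profile statistics
    "GeoPrHMean", "GeoPrHSD", "GeoPrHSkew", "GeoPrHKurt",
    "GeoPrVMean", "GeoPrVSD", "GeoPrVSkew", "GeoPrVKurt",
    # global extent descriptors
    "GeoBBoxAR", "GeoFeretMax", "GeoFeretMin", "GeoFeretRatio", "GeoCHullA",
)


def glcm_offsets() -> list[tuple[int, int]]:
    """The 20 (dx, dy) offsets: 5 distances x 4 directions."""
    offs = []
    for d in range(1, 6):
        offs.extend([(d, 0), (0, d), (d, d), (d, -d)])
    return offs


def offset_name(dx: int, dy: int) -> str:
    return f"S({dx},{dy})"


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, named feature list with per-feature family and parameters."""

    version: str
    features: tuple[FeatureSpec, ...]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.family] = out.get(f.family, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "features": [
                    {"name": f.name, "family": f.family, "parameters": f.parameters}
                    for f in self.features
                ],
            },
            indent=1,
        )


def default_manifest() -> FeatureManifest:
    """Build ``manifest_v1`` (377 features)."""
    feats: list[FeatureSpec] = []
    for n in HISTOGRAM_NAMES:
        feats.append(FeatureSpec(n, "histogram", {"ng": 256}))
    for n in GRADIENT_NAMES:
        feats.append(FeatureSpec(n, "gradient", {"ng": 256}))
    for dx, dy in glcm_offsets():
        for stat in GLCM_STATS:
            feats.append(
                FeatureSpec(
                    f"{offset_name(dx, dy)}{stat}",
                    "cooccurrence",
                    {"dx": dx, "dy": dy, "ng": 64},
                )
            )
    for dname, step in RLM_DIRECTIONS.items():
        for stat in RLM_STATS:
            feats.append(
                FeatureSpec(f"{dname}_{stat}", "runlength", {"step": list(step), "ng": 64})
            )
    for n in AR_NAMES:
        feats.append(FeatureSpec(n, "ar_model", {"ng": 256}))
    for band in WAVELET_SUBBANDS:
        for s in WAVELET_SCALES:
            feats.append(FeatureSpec(f"WavEn{band}_s-{s}", "wavelet", {"scale": s, "ng": 256}))
    for n in GEOMETRY_NAMES:
        feats.append(FeatureSpec(n, "geometry"))
    m = FeatureManifest(version="manifest_v1", features=tuple(feats))
    assert len(m) == 377, f"manifest_v1 must have 377 features, got {len(m)}"
    return m
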