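"""Synthetic two-class cohort generator (images + ROIs + clinical table).

The generator emulates the statistical structure the analysis assumes:
two groups (hypertensive ``HTN`` vs normotensive controls ``NC``) whose
left-ventricle ROIs differ in size, elongation and spatial texture
heterogeneity, together with a clinical table whose marginals follow
the study population (septum width, age, BMI, sex, diabetes,
dyslipidemia).

A per-subject latent "remodeling" variable ``u ~ N(0, 1)`` drives both
the septum width and, attenuated by coupling constants, the ROI size,
elongation and texture correlation length.  This encodes the premise
that septum thickening and myocardial texture change are two faces of
the same structural process, which is what makes an image-derived score
correlate with septum width *within* as well as between groups.

Images are 16-bit grayscale; the ROI interior carries a Gaussian random
field (white noise smoothed to the class correlation length, rescaled
to the class noise SD) on top of a base mean; the background is a
darker, mildly noisy field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ParameterError
from .imaging import GrayImage, PolygonROI, rasterize

__all__ = [
    "TextureParams",
    "GeometryParams",
    "SeptumModel",
    "CohortSpec",
    "ClinicalRecord",
    "generate_image",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

GROUP_HTN = "HTN"
GROUP_NC = "NC"


@dataclass(frozen=True)
class TextureParams:
    """ROI texture: base gray level, noise SD (gray levels), correlation
    length in pixels (1 = white noise)."""

    base_mean: float = 1200.0
    noise_sd: float = 120.0
    corr_length: float = 2.0


@dataclass(frozen=True)
class GeometryParams:
    """ROI size (pixels) and second-moment elongation (dimensionless)."""

    area_mean: float = 2500.0
    area_sd: float = 700.0
    elong_mean: float = 1.6
    elong_sd: float = 0.4


@dataclass(frozen=True)
class SeptumModel:
    """Normal model of interventricular septum width (mm), truncated > 0."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ClinicalRecord:
    subject_id: str
    group: str
    sex: str
    age: float
    bmi: float
    diabetes: bool
    dyslipidemia: bool
    septum_width: float


#: clinical marginals per group (study-population calibration)
_CLINICAL = {
    GROUP_HTN: dict(p_female=35 / 83, age=(65.63, 10.23), bmi=(28.4, 6.1),
                    p_diabetes=18 / 83, p_dyslipidemia=18 / 83),
    GROUP_NC: dict(p_female=45 / 75, age=(55.59, 12.42), bmi=(25.5, 4.9),
                   p_diabetes=4 / 75, p_dyslipidemia=10 / 75),
}


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort.

    ``latent_rho`` is the correlation between the latent remodeling
    variable and the geometric deviations; ``latent_kappa`` the
    log-scale sensitivity of the texture correlation length to the
    latent variable.  Setting both class parameter sets equal (see
    :meth:`null`) removes every injected effect.
    """

    n_htn: int = 83
    n_nc: int = 75
    seed: int = 0
    image_size: int = 160
    texture_htn: TextureParams = TextureParams(noise_sd=130.0, corr_length=2.8)
    texture_nc: TextureParams = TextureParams(noise_sd=110.0, corr_length=2.0)
    geometry_htn: GeometryParams = GeometryParams(3495.0, 1246.0, 2.17, 0.82)
    geometry_nc: GeometryParams = GeometryParams(2515.0, 736.0, 1.55, 0.48)
    septum_htn: SeptumModel = SeptumModel(10.01, 2.7)
    septum_nc: SeptumModel = SeptumModel(8.15, 1.66)
    latent_rho: float = 0.5
    latent_kappa: float = 0.15

    def __post_init__(self) -> None:
        if self.n_htn < 2 or self.n_nc < 2:
            raise ParameterError("need at least 2 subjects per class")
        if self.image_size < 64:
            raise ParameterError("image_size must be >= 64")
        for g in (self.geometry_htn, self.geometry_nc):
            if g.area_sd <= 0 or g.elong_sd <= 0:
                raise ParameterError("geometry SDs must be > 0")
        for s in (self.septum_htn, self.septum_nc):
            if s.sd <= 0:
                raise ParameterError("septum SD must be > 0")

    @classmethod
    def calibrated(cls, n_htn: int = 83, n_nc: int = 75, seed: int = 0,
                   image_size: int = 160) -> "CohortSpec":
        """The default study-calibrated spec (effect injection on)."""
        return cls(n_htn=n_htn, n_nc=n_nc, seed=seed, image_size=image_size)

    @classmethod
    def null(cls, n_htn: int = 83, n_nc: int = 75, seed: int = 0,
             image_size: int = 160) -> "CohortSpec":
        """No injected effect: both classes share pooled parameters."""
        tex = TextureParams(noise_sd=120.0, corr_length=2.4)
        geo = GeometryParams(3030.0, 1050.0, 1.88, 0.70)
        sep = SeptumModel(9.13, 2.40)
        return cls(
            n_htn=n_htn, n_nc=n_nc, seed=seed, image_size=image_size,
            texture_htn=tex, texture_nc=tex,
            geometry_htn=geo, geometry_nc=geo,
            septum_htn=sep, septum_nc=sep,
            latent_rho=0.0, latent_kappa=0.0,
        )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_N_VERTICES = 24
_RADIAL_JITTER = 0.07
_BACKGROUND_MEAN = 400.0
_BACKGROUND_SD = 40.0


def _fits(area: float, elong: float, size: int) -> bool:
    """Conservative check that the perturbed ellipse stays inside the image."""
    a_max = np.sqrt(area * elong / np.pi) * 1.2 + 3.0
    return a_max <= size / 2.0 - 1.0


def _blob_polygon(cx: float, cy: float, area: float, elong: float,
                  rot: float, jitter: np.ndarray) -> PolygonROI:
    """Star-shaped (hence simple) polygon approximating a perturbed ellipse."""
    a = np.sqrt(area * elong / np.pi)
    b = np.sqrt(area / (elong * np.pi))
    theta = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    phi = theta - rot
    r_ell = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    r = r_ell * (1.0 + jitter)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return PolygonROI(tuple(zip(xs.tolist(), ys.tolist())))


def _smooth_circular(x: np.ndarray) -> np.ndarray:
    return 0.25 * np.roll(x, 1) + 0.5 * x + 0.25 * np.roll(x, -1)


def _render(texture: TextureParams, area: float, elong: float, size: int,
            rng: np.random.Generator) -> tuple[GrayImage, PolygonROI]:
    """Render one image/ROI pair at fully resolved per-subject parameters."""
    jitter = _RADIAL_JITTER * _smooth_circular(rng.standard_normal(_N_VERTICES))
    rot = rng.uniform(0.0, np.pi)
    cx = size / 2.0 + rng.uniform(-3.0, 3.0)
    cy = size / 2.0 + rng.uniform(-3.0, 3.0)
    roi = _blob_polygon(cx, cy, area, elong, rot, jitter)
    v = roi.as_array()
    if (v[:, 0].min() < 1 or v[:, 1].min() < 1
            or v[:, 0].max() > size - 1 or v[:, 1].max() > size - 1):
        raise GeometryError(
            f"ROI (area {area:.0f}, elongation {elong:.2f}) does not fit in a "
            f"{size}x{size} image"
        )
    mask = rasterize(roi, (size, size))

    field = rng.standard_normal((size, size))
    if texture.corr_length > 1.0:
        field = gaussian_filter(field, sigma=(texture.corr_length - 1.0) / 2.0,
                                mode="reflect")
    sd = field.std()
    if sd > 0 and texture.noise_sd > 0:
        field = field / sd * texture.noise_sd
    else:
        field = np.zeros_like(field)
    bg = _BACKGROUND_MEAN + _BACKGROUND_SD * rng.standard_normal((size, size))
    px = np.where(mask, texture.base_mean + field, bg)
    px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    return GrayImage(px, bit_depth=16), roi


def generate_image(texture_params: TextureParams, geometry_params: GeometryParams,
                   rng: np.random.Generator, size: int = 128
                   ) -> tuple[GrayImage, PolygonROI]:
    """Draw ROI area/elongation from the geometry model and render one image."""
    if size < 64:
        raise ParameterError("image_size must be >= 64")
    if not _fits(geometry_params.area_mean, geometry_params.elong_mean, size):
        raise GeometryError("mean ROI geometry does not fit inside the image")
    for _ in range(200):
        area = _truncate_normal(rng, geometry_params.area_mean, geometry_params.area_sd,
                                600.0, 0.33 * size * size)
        elong = _truncate_normal(rng, geometry_params.elong_mean, geometry_params.elong_sd,
                                 1.02, 5.0)
        if _fits(area, elong, size):
            break
    else:
        area, elong = geometry_params.area_mean, geometry_params.elong_mean
    return _render(texture_params, area, elong, size, rng)


def _truncate_normal(rng: np.random.Generator, mean: float, sd: float,
                     lo: float, hi: float) -> float:
    """Rejection-sample N(mean, sd) restricted to [lo, hi] (clip fallback)."""
    for _ in range(100):
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def _make_subject(sid: str, group: str, spec: CohortSpec,
                  rng: np.random.Generator) -> tuple[GrayImage, PolygonROI, ClinicalRecord]:
    tex = spec.texture_htn if group == GROUP_HTN else spec.texture_nc
    geo = spec.geometry_htn if group == GROUP_HTN else spec.geometry_nc
    sep = spec.septum_htn if group == GROUP_HTN else spec.septum_nc
    marg = _CLINICAL[group]
    rho, kappa = spec.latent_rho, spec.latent_kappa
    res = np.sqrt(max(1.0 - rho * rho, 0.0))
    area_hi = 0.33 * spec.image_size**2

    # septum truncation at 0 redraws the latent u alone; geometry
    # feasibility redraws only the residual noise, so the septum marginal
    # stays exactly the class's truncated normal
    for _ in range(100):
        u = rng.standard_normal()
        septum = sep.mean + sep.sd * u
        if septum > 0:
            break
    else:
        u, septum = 0.0, sep.mean
    for _ in range(100):
        elong = geo.elong_mean + geo.elong_sd * (rho * u + res * rng.standard_normal())
        if 1.02 <= elong <= 5.0:
            break
    else:
        elong = float(np.clip(geo.elong_mean + geo.elong_sd * rho * u, 1.02, 5.0))
    for _ in range(100):
        area = geo.area_mean + geo.area_sd * (rho * u + res * rng.standard_normal())
        if 600.0 <= area <= area_hi and _fits(area, elong, spec.image_size):
            break
    else:
        # largest feasible area for this elongation
        size = spec.image_size
        fit_cap = np.pi * ((size / 2.0 - 4.0) / 1.2) ** 2 / elong
        area = float(np.clip(geo.area_mean + geo.area_sd * rho * u, 600.0,
                             min(area_hi, fit_cap)))
    tex_subject = dataclasses.replace(tex, corr_length=tex.corr_length * float(np.exp(kappa * u)))
    image, roi = _render(tex_subject, area, elong, spec.image_size, rng)

    age = _truncate_normal(rng, *marg["age"], 18.0 + 1e-9, 100.0)
    bmi = _truncate_normal(rng, *marg["bmi"], 12.0, 60.0)
    rec = ClinicalRecord(
        subject_id=sid,
        group=group,
        sex="F" if rng.random() < marg["p_female"] else "M",
        age=round(age, 2),
        bmi=round(bmi, 2),
        diabetes=bool(rng.random() < marg["p_diabetes"]),
        dyslipidemia=bool(rng.random() < marg["p_dyslipidemia"]),
        septum_width=round(float(septum), 3),
    )
    return image, roi, rec


def generate_cohort(spec: CohortSpec) -> list[tuple[GrayImage, PolygonROI, ClinicalRecord]]:
    """Generate the full cohort, reproducibly from ``spec.seed``.

    Returns ``n_htn + n_nc`` triples, HTN subjects first.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n_htn):
        cohort.append(_make_subject(f"HTN_{i + 1:03d}", GROUP_HTN, spec, rng))
    for i in range(spec.n_nc):
        cohort.append(_make_subject(f"NC_{i + 1:03d}", GROUP_NC, spec, rng))
    return cohort


# --------------------------------------------------------------------------
# on-disk formats: 16-bit TIFF, ROI vertex JSON, clinical CSV
# --------------------------------------------------------------------------

def write_cohort(cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "rois").mkdir(parents=True, exist_ok=True)
    records = []
    for image, roi, rec in cohort:
        tifffile.imwrite(outdir / "images" / f"{rec.subject_id}.tif", image.pixels)
        with open(outdir / "rois" / f"{rec.subject_id}.json", "w") as fh:
            json.dump({"vertices": [list(v) for v in roi.vertices]}, fh)
        records.append(dataclasses.asdict(rec))
    pd.DataFrame(records).to_csv(outdir / "clinical.csv", index=False)


def load_cohort(outdir: str | Path) -> list[tuple[GrayImage, PolygonROI, ClinicalRecord]]:
    outdir = Path(outdir)
    clinical = pd.read_csv(outdir / "clinical.csv")
    cohort = []
    for row in clinical.itertuples(index=False):
        rec = ClinicalRecord(
            subject_id=row.subject_id, group=row.group, sex=row.sex,
            age=float(row.age), bmi=float(row.bmi), diabetes=bool(row.diabetes),
            dyslipidemia=bool(row.dyslipidemia), septum_width=float(row.septum_width),
        )
        px = tifffile.imread(outdir / "images" / f"{rec.subject_id}.tif")
        with open(outdir / "rois" / f"{rec.subject_id}.json") as fh:
            verts = json.load(fh)["vertices"]
        cohort.append((GrayImage(px, 16), PolygonROI(tuple(map(tuple, verts))), rec))
    return cohort
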