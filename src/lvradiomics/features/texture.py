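"""Gray-level texture statistics on masked, quantized ROIs.

All operations take the integer level matrix produced by
:func:`lvradiomics.imaging.normalize_mu3sigma` together with its boolean
mask.  Pairs and runs that would cross the mask boundary are discarded /
truncated, so no background pixel ever contributes.  Entropies use the
natural logarithm with the convention ``0 * ln 0 = 0``.
"""

from __future__ import annotations

import numpy as np

from ..errors import DataError
from .manifest import (
    AR_NAMES,
    GLCM_STATS,
    GRADIENT_NAMES,
    HISTOGRAM_NAMES,
    RLM_STATS,
    WAVELET_SCALES,
    WAVELET_SUBBANDS,
)

__all__ = [
    "glcm",
    "glcm_features",
    "rlm_features",
    "histogram_features",
    "gradient_features",
    "ar_features",
    "wavelet_features",
]


# --------------------------------------------------------------------------
# co-occurrence
# --------------------------------------------------------------------------

def glcm(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Parameters
    ----------
    levels : int matrix with values in ``[1, ng]`` on the mask
    mask : boolean matrix
    offset : (dx, dy) pixel displacement; dx = column shift, dy = row
        shift (rows grow downward).

    Returns
    -------
    (ng, ng) matrix ``P`` with ``P.sum() == 1``; ``P[i-1, j-1]`` is the
    probability of the ordered level pair (i, j).  Each unordered pair
    is accumulated in both directions, so ``P`` is symmetric.

    Raises
    ------
    DataError
        If no level pair fits inside the mask for this offset.
    """
    dx, dy = offset
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    rows, cols = levels.shape
    ng = int(levels[mask].max()) if mask.any() else 0

    r0 = max(0, -dy)
    r1 = rows - max(0, dy)
    c0 = max(0, -dx)
    c1 = cols - max(0, dx)
    if r1 <= r0 or c1 <= c0:
        raise DataError(f"offset {offset} larger than the image")
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    if not valid.any():
        raise DataError(f"no co-occurring pair inside the mask for offset {offset}")
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.zeros((ng, ng), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    counts += counts.T  # symmetric accumulation
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Eleven Haralick-family statistics of a normalized co-occurrence matrix.

    Levels are indexed 1..ng.  ``Correlat`` is defined as 0 when either
    marginal has zero variance (constant ROI).
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # marginal (symmetric: px == py)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    # difference distribution p_{x-y}(k), k = 0..ng-1
    k_diff = np.abs(ii - jj)
    p_diff = np.bincount(k_diff.ravel(), weights=P.ravel(), minlength=ng)
    # sum distribution p_{x+y}(k), k = 2..2 ng
    k_sum = ii + jj
    p_sum = np.bincount(k_sum.ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]
    ks = np.arange(2, 2 * ng + 1)
    kd = np.arange(ng)

    def _ent(p):
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum())

    sum_avg = float((ks * p_sum).sum())
    out = {
        "AngScMom": float((P**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlat": 0.0
        if var <= 0
        else float((((ii - mu) * (jj - mu) * P).sum()) / var),
        "SumOfSqs": var,
        "InvDfMom": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumVarnc": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "SumEntrp": _ent(p_sum),
        "Entropy": _ent(P.ravel()),
        "DifVarnc": float(((kd - (kd * p_diff).sum()) ** 2 * p_diff).sum()),
        "DifEntrp": _ent(p_diff),
    }
    assert tuple(out) == GLCM_STATS
    return out


# --------------------------------------------------------------------------
# run length
# --------------------------------------------------------------------------

def _direction_lines(levels: np.ndarray, mask: np.ndarray, step: tuple[int, int]):
    """Yield (values, in_mask) 1-D arrays for every scan line of a direction."""
    dy, dx = step[0], step[1]
    if (dy, dx) == (0, 1):  # horizontal
        for r in range(levels.shape[0]):
            yield levels[r, :], mask[r, :]
    elif (dy, dx) == (1, 0):  # vertical
        for c in range(levels.shape[1]):
            yield levels[:, c], mask[:, c]
    elif (dy, dx) == (-1, 1):  # 45 degrees: anti-diagonals, up-right
        flipped_l = levels[::-1, :]
        flipped_m = mask[::-1, :]
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield flipped_l.diagonal(off), flipped_m.diagonal(off)
    elif (dy, dx) == (-1, -1):  # 135 degrees: main diagonals, up-left
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield levels.diagonal(off), mask.diagonal(off)
    else:  # pragma: no cover
        raise DataError(f"unsupported run direction {step}")


def _runs(levels: np.ndarray, mask: np.ndarray, step) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode all scan lines; returns (run_levels, run_lengths).

    Runs are maximal stretches of a constant level whose pixels all lie
    inside the mask; a mask gap or a line boundary terminates a run.
    """
    pieces = []
    for vals, inm in _direction_lines(levels, mask, step):
        v = np.where(inm, vals, -1)
        pieces.append(v)
        pieces.append(np.array([-1]))  # line separator
    flat = np.concatenate(pieces)
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(flat)]])
    run_levels = flat[starts]
    run_lengths = ends - starts
    keep = run_levels > 0
    return run_levels[keep], run_lengths[keep]


def rlm_features(levels: np.ndarray, mask: np.ndarray, step: tuple[int, int]) -> dict[str, float]:
    """Five run-length statistics for one scan direction.

    ``step`` is the (dy, dx) unit vector of the direction (see
    :data:`lvradiomics.features.manifest.RLM_DIRECTIONS`).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("empty mask")
    run_levels, run_lengths = _runs(np.asarray(levels), mask, step)
    n_runs = len(run_lengths)
    n_pix = int(mask.sum())
    gl_sums = np.bincount(run_levels)  # runs per gray level
    rl_sums = np.bincount(run_lengths)  # runs per length
    out = {
        "ShrtREmp": float((1.0 / run_lengths.astype(float) ** 2).sum() / n_runs),
        "LngREmph": float((run_lengths.astype(float) ** 2).sum() / n_runs),
        "GLevNonU": float((gl_sums.astype(float) ** 2).sum() / n_runs),
        "RLNonUni": float((rl_sums.astype(float) ** 2).sum() / n_runs),
        "Fraction": n_runs / n_pix,
    }
    assert tuple(out) == RLM_STATS
    return out


# --------------------------------------------------------------------------
# histogram
# --------------------------------------------------------------------------

def _nearest_rank_percentile(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: value at rank ceil(q/100 * n) (1-based)."""
    n = len(sorted_vals)
    rank = max(1, int(np.ceil(q / 100.0 * n)))
    return float(sorted_vals[rank - 1])


def histogram_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """First-order statistics of the in-mask level distribution.

    Variance uses the population convention; skewness and kurtosis are
    the standardized third moment and excess fourth moment, defined as 0
    for a constant ROI.  Percentiles use the nearest-rank convention.
    """
    vals = np.asarray(levels)[np.asarray(mask, dtype=bool)].astype(float)
    if vals.size == 0:
        raise DataError("empty mask")
    mean = float(vals.mean())
    var = float(vals.var())
    if var > 0:
        z = (vals - mean) / np.sqrt(var)
        skew, kurt = float((z**3).mean()), float((z**4).mean() - 3.0)
    else:
        skew = kurt = 0.0
    s = np.sort(vals)
    out = {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Perc01": _nearest_rank_percentile(s, 1),
        "Perc10": _nearest_rank_percentile(s, 10),
        "Perc50": _nearest_rank_percentile(s, 50),
        "Perc90": _nearest_rank_percentile(s, 90),
        "Perc99": _nearest_rank_percentile(s, 99),
    }
    assert tuple(out) == HISTOGRAM_NAMES
    return out


# --------------------------------------------------------------------------
# gradient
# --------------------------------------------------------------------------

def _interior(mask: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighbors are all inside the mask."""
    m = np.asarray(mask, dtype=bool)
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    return interior


def gradient_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Statistics of the central-difference gradient magnitude.

    The gradient is evaluated only on interior pixels (all four
    4-neighbors in the mask); ``GrNonZeros`` is the fraction of those
    pixels with a non-zero gradient.  Returns NaNs when the mask has no
    interior pixel.
    """
    lv = np.asarray(levels, dtype=float)
    interior = _interior(mask)
    if not interior.any():
        return {n: float("nan") for n in GRADIENT_NAMES}
    gx = np.zeros_like(lv)
    gy = np.zeros_like(lv)
    gx[:, 1:-1] = (lv[:, 2:] - lv[:, :-2]) / 2.0
    gy[1:-1, :] = (lv[2:, :] - lv[:-2, :]) / 2.0
    mag = np.sqrt(gx**2 + gy**2)[interior]
    mean = float(mag.mean())
    var = float(mag.var())
    if var > 0:
        z = (mag - mean) / np.sqrt(var)
        skew, kurt = float((z**3).mean()), float((z**4).mean() - 3.0)
    else:
        skew = kurt = 0.0
    out = {
        "GrMean": mean,
        "GrVariance": var,
        "GrSkewness": skew,
        "GrKurtosis": kurt,
        "GrNonZeros": float((mag > 0).mean()),
    }
    assert tuple(out) == GRADIENT_NAMES
    return out


# --------------------------------------------------------------------------
# autoregressive model
# --------------------------------------------------------------------------

#: causal neighborhood: left, upper-left, upper, upper-right (dy, dx)
_AR_NEIGHBORS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))


def ar_features(levels: np.ndarray, mask: np.ndarray, min_support: int = 20) -> dict[str, float]:
    """First-order causal autoregressive model parameters.

    Each in-mask pixel whose four causal neighbors (left, upper-left,
    upper, upper-right) are also in-mask contributes one least-squares
    equation on mean-centered levels; ``Sigma`` is the residual SD.
    Returns NaNs when fewer than ``min_support`` pixels qualify.
    """
    lv = np.asarray(levels, dtype=float)
    m = np.asarray(mask, dtype=bool)
    rows, cols = lv.shape
    center = np.zeros_like(m)
    center[1:-1, 1:-1] = m[1:-1, 1:-1]
    support = center.copy()
    for dy, dx in _AR_NEIGHBORS:
        shifted = np.zeros_like(m)
        shifted[
            max(0, -dy) : rows - max(0, dy), max(0, -dx) : cols - max(0, dx)
        ] = m[max(0, dy) : rows - max(0, -dy), max(0, dx) : cols - max(0, -dx)]
        support &= shifted
    n = int(support.sum())
    if n < min_support:
        return {k: float("nan") for k in AR_NAMES}
    mu = lv[m].mean()
    y = lv[support] - mu
    X = np.empty((n, 4))
    rr, cc = np.nonzero(support)
    for k, (dy, dx) in enumerate(_AR_NEIGHBORS):
        X[:, k] = lv[rr + dy, cc + dx] - mu
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    out = dict(zip(AR_NAMES, [*map(float, theta), float(resid.std())]))
    return out


# --------------------------------------------------------------------------
# wavelet
# --------------------------------------------------------------------------

def wavelet_features(levels: np.ndarray, mask: np.ndarray, max_scale: int = 5) -> dict[str, float]:
    """Haar subband energies at dyadic scales 1..``max_scale``.

    At each scale the current approximation is split into 2x2 blocks
    (zero-padded to even size); a coefficient is kept only if its full
    spatial support lies inside the mask.  Energy is the mean squared
    coefficient over the kept positions.  ``LH`` is the subband that is
    high-pass along rows (responds to horizontal stripes), ``HL``
    high-pass along columns.  Scales with no fully-supported block are
    reported as NaN.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise DataError("empty mask")
    rr, cc = np.nonzero(m)
    a = np.where(m, np.asarray(levels, dtype=float), 0.0)[
        rr.min() : rr.max() + 1, cc.min() : cc.max() + 1
    ]
    mcur = m[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    out = {f"WavEn{b}_s-{s}": float("nan") for b in WAVELET_SUBBANDS for s in WAVELET_SCALES}
    for s in range(1, max_scale + 1):
        if a.shape[0] % 2:
            a = np.vstack([a, np.zeros((1, a.shape[1]))])
            mcur = np.vstack([mcur, np.zeros((1, mcur.shape[1]), dtype=bool)])
        if a.shape[1] % 2:
            a = np.hstack([a, np.zeros((a.shape[0], 1))])
            mcur = np.hstack([mcur, np.zeros((mcur.shape[0], 1), dtype=bool)])
        a00, a01 = a[0::2, 0::2], a[0::2, 1::2]
        a10, a11 = a[1::2, 0::2], a[1::2, 1::2]
        ll = (a00 + a01 + a10 + a11) / 2.0
        hl = (a00 - a01 + a10 - a11) / 2.0  # high-pass along columns
        lh = (a00 + a01 - a10 - a11) / 2.0  # high-pass along rows
        hh = (a00 - a01 - a10 + a11) / 2.0
        valid = mcur[0::2, 0::2] & mcur[0::2, 1::2] & mcur[1::2, 0::2] & mcur[1::2, 1::2]
        if valid.any():
            for band, coef in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
                out[f"WavEn{band}_s-{s}"] = float((coef[valid] ** 2).mean())
        a, mcur = ll, valid
        if not mcur.any():
            break
    return out
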