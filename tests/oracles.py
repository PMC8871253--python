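"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the defining
formulas (explicit loops, no vectorization, no reuse of package code)
so that agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- polygon

def point_in_polygon_evenodd(x: float, y: float, vertices) -> bool:
    """Classic even-odd ray cast (horizontal ray to +x)."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_rasterize(vertices, shape):
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            mask[r, c] = point_in_polygon_evenodd(c + 0.5, r + 0.5, vertices)
    return mask


# ---------------------------------------------------------------- GLCM

def brute_glcm(levels, mask, offset):
    """Symmetric normalized co-occurrence counts by explicit pair loops."""
    dx, dy = offset
    rows, cols = levels.shape
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def brute_glcm_stats(P):
    ng = P.shape[0]
    asm = con = ent = idm = ssq = 0.0
    mu = 0.0
    px = P.sum(axis=1)
    for i in range(ng):
        mu += (i + 1) * px[i]
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            asm += p * p
            con += (i - j) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            ssq += (i + 1 - mu) ** 2 * p
            if p > 0:
                ent -= p * math.log(p)
    var = 0.0
    for i in range(ng):
        var += (i + 1 - mu) ** 2 * px[i]
    cor = 0.0
    if var > 0:
        for i in range(ng):
            for j in range(ng):
                cor += (i + 1 - mu) * (j + 1 - mu) * P[i, j]
        cor /= var
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i, j]
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    dmean = sum(k * v for k, v in p_diff.items())
    dif_var = sum((k - dmean) ** 2 * v for k, v in p_diff.items())
    dif_ent = -sum(v * math.log(v) for v in p_diff.values() if v > 0)
    return {
        "AngScMom": asm, "Contrast": con, "Correlat": cor, "SumOfSqs": var,
        "InvDfMom": idm, "SumAverg": sum_avg, "SumVarnc": sum_var,
        "SumEntrp": sum_ent, "Entropy": ent, "DifVarnc": dif_var, "DifEntrp": dif_ent,
    }


# ---------------------------------------------------------------- RLM

def _lines_for_direction(shape, step):
    """Enumerate all scan lines (lists of (r, c)) for a direction."""
    rows, cols = shape
    dy, dx = step
    lines = []
    if (dy, dx) == (0, 1):
        for r in range(rows):
            lines.append([(r, c) for c in range(cols)])
    elif (dy, dx) == (1, 0):
        for c in range(cols):
            lines.append([(r, c) for r in range(rows)])
    elif (dy, dx) == (-1, 1):  # up-right
        for s in range(rows + cols - 1):
            line = [(r, s - r) for r in range(rows - 1, -1, -1) if 0 <= s - r < cols]
            if line:
                lines.append(line)
    elif (dy, dx) == (-1, -1):  # up-left == down-right reversed
        for d in range(-(rows - 1), cols):
            line = [(r, r + d) for r in range(rows) if 0 <= r + d < cols]
            if line:
                lines.append(line)
    return lines


def brute_rlm_stats(levels, mask, step):
    runs = []  # (gray level, length)
    for line in _lines_for_direction(levels.shape, step):
        cur_level, cur_len = None, 0
        for r, c in line:
            if mask[r, c] and levels[r, c] == cur_level:
                cur_len += 1
            else:
                if cur_level is not None and cur_len > 0:
                    runs.append((cur_level, cur_len))
                if mask[r, c]:
                    cur_level, cur_len = levels[r, c], 1
                else:
                    cur_level, cur_len = None, 0
        if cur_level is not None and cur_len > 0:
            runs.append((cur_level, cur_len))
    n_runs = len(runs)
    n_pix = int(mask.sum())
    by_level = {}
    by_len = {}
    for g, ln in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_len[ln] = by_len.get(ln, 0) + 1
    return {
        "ShrtREmp": sum(1.0 / ln**2 for _, ln in runs) / n_runs,
        "LngREmph": sum(float(ln**2) for _, ln in runs) / n_runs,
        "GLevNonU": sum(v**2 for v in by_level.values()) / n_runs,
        "RLNonUni": sum(v**2 for v in by_len.values()) / n_runs,
        "Fraction": n_runs / n_pix,
    }


# ---------------------------------------------------------------- histogram

def brute_histogram_stats(values):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    if var > 0:
        skew = sum(((x - mean) / var**0.5) ** 3 for x in v) / n
        kurt = sum(((x - mean) / var**0.5) ** 4 for x in v) / n - 3.0
    else:
        skew = kurt = 0.0

    def perc(q):
        rank = max(1, math.ceil(q / 100.0 * n))
        return v[rank - 1]

    return {
        "Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt,
        "Perc01": perc(1), "Perc10": perc(10), "Perc50": perc(50),
        "Perc90": perc(90), "Perc99": perc(99),
    }


# ---------------------------------------------------------------- gradient

def brute_gradient_stats(levels, mask):
    rows, cols = levels.shape
    mags = []
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            if (mask[r, c] and mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]):
                gx = (float(levels[r, c + 1]) - float(levels[r, c - 1])) / 2.0
                gy = (float(levels[r + 1, c]) - float(levels[r - 1, c])) / 2.0
                mags.append(math.hypot(gx, gy))
    if not mags:
        return {k: float("nan") for k in
                ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")}
    n = len(mags)
    mean = sum(mags) / n
    var = sum((x - mean) ** 2 for x in mags) / n
    if var > 0:
        skew = sum(((x - mean) / var**0.5) ** 3 for x in mags) / n
        kurt = sum(((x - mean) / var**0.5) ** 4 for x in mags) / n - 3.0
    else:
        skew = kurt = 0.0
    return {
        "GrMean": mean, "GrVariance": var, "GrSkewness": skew,
        "GrKurtosis": kurt, "GrNonZeros": sum(1 for x in mags if x > 0) / n,
    }


# ---------------------------------------------------------------- AR model

def brute_ar_stats(levels, mask, min_support=20):
    """Normal-equation solution of the causal AR least squares."""
    rows, cols = levels.shape
    neigh = ((0, -1), (-1, -1), (-1, 0), (-1, 1))
    eqs = []
    mu = float(np.mean([float(levels[r, c]) for r in range(rows)
                        for c in range(cols) if mask[r, c]]))
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            if mask[r, c] and all(mask[r + dy, c + dx] for dy, dx in neigh):
                x = [float(levels[r + dy, c + dx]) - mu for dy, dx in neigh]
                eqs.append((x, float(levels[r, c]) - mu))
    if len(eqs) < min_support:
        return {k: float("nan") for k in ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")}
    X = np.array([e[0] for e in eqs])
    y = np.array([e[1] for e in eqs])
    theta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    resid = y - X @ theta
    sigma = float(np.sqrt(np.mean(resid**2) - np.mean(resid) ** 2))
    return {
        "Teta1": float(theta[0]), "Teta2": float(theta[1]),
        "Teta3": float(theta[2]), "Teta4": float(theta[3]), "Sigma": sigma,
    }


# ---------------------------------------------------------------- wavelet

def brute_wavelet_stats(levels, mask, max_scale=5):
    """Direct Haar transform by explicit 2x2 block recursion on the bbox."""
    rr, cc = np.nonzero(mask)
    a = np.where(mask, levels.astype(float), 0.0)[
        rr.min(): rr.max() + 1, cc.min(): cc.max() + 1]
    m = mask[rr.min(): rr.max() + 1, cc.min(): cc.max() + 1].copy()
    out = {f"WavEn{b}_s-{s}": float("nan")
           for b in ("LL", "LH", "HL", "HH") for s in range(1, 6)}
    for s in range(1, max_scale + 1):
        h_pad = a.shape[0] + a.shape[0] % 2
        w_pad = a.shape[1] + a.shape[1] % 2
        ap = np.zeros((h_pad, w_pad))
        mp = np.zeros((h_pad, w_pad), dtype=bool)
        ap[: a.shape[0], : a.shape[1]] = a
        mp[: m.shape[0], : m.shape[1]] = m
        nr, nc = h_pad // 2, w_pad // 2
        ll = np.zeros((nr, nc))
        valid = np.zeros((nr, nc), dtype=bool)
        bands = {b: [] for b in ("LL", "LH", "HL", "HH")}
        for i in range(nr):
            for j in range(nc):
                blk = ap[2 * i: 2 * i + 2, 2 * j: 2 * j + 2]
                ok = mp[2 * i: 2 * i + 2, 2 * j: 2 * j + 2].all()
                llv = (blk[0, 0] + blk[0, 1] + blk[1, 0] + blk[1, 1]) / 2.0
                ll[i, j] = llv
                valid[i, j] = ok
                if ok:
                    bands["LL"].append(llv)
                    bands["HL"].append((blk[0, 0] - blk[0, 1] + blk[1, 0] - blk[1, 1]) / 2.0)
                    bands["LH"].append((blk[0, 0] + blk[0, 1] - blk[1, 0] - blk[1, 1]) / 2.0)
                    bands["HH"].append((blk[0, 0] - blk[0, 1] - blk[1, 0] + blk[1, 1]) / 2.0)
        if bands["LL"]:
            for b in bands:
                out[f"WavEn{b}_s-{s}"] = float(np.mean(np.array(bands[b]) ** 2))
        a, m = ll, valid
        if not m.any():
            break
    return out


# ---------------------------------------------------------------- ROC

def brute_auc(scores, labels, positive=1):
    """Pair-counting AUC with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
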