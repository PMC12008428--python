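"""Independent brute-force oracles for texture features and ARI.

Everything here is written as plain loops straight from the matrix
definitions — no shared code with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

DIRS = ((0, 1), (1, 0), (1, 1), (1, -1))


# ------------------------------------------------------------------ GLCM

def glcm_counts(levels, mask, ng, direction):
    h, w = levels.shape
    dr, dc = direction
    mat = [[0.0] * ng for _ in range(ng)]
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                mat[i][j] += 1
                mat[j][i] += 1
    return np.array(mat)


def glcm_features_oracle(levels, mask, ng):
    per_dir = []
    for d in DIRS:
        mat = glcm_counts(levels, mask, ng, d)
        s = mat.sum()
        if s == 0:
            continue
        p = mat / s
        idx = np.arange(1, ng + 1)
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mux = sum(i * px[i - 1] for i in idx)
        muy = sum(j * py[j - 1] for j in idx)
        sigx = math.sqrt(sum((i - mux) ** 2 * px[i - 1] for i in idx))
        sigy = math.sqrt(sum((j - muy) ** 2 * py[j - 1] for j in idx))
        pdiff = np.zeros(ng)
        psum = np.zeros(2 * ng - 1)
        for i in idx:
            for j in idx:
                pdiff[abs(i - j)] += p[i - 1, j - 1]
                psum[i + j - 2] += p[i - 1, j - 1]
        feats = {}
        feats["Autocorrelation"] = sum(i * j * p[i - 1, j - 1] for i in idx for j in idx)
        feats["JointAverage"] = mux
        for power, name in ((2, "ClusterTendency"), (3, "ClusterShade"),
                            (4, "ClusterProminence")):
            feats[name] = sum((i + j - mux - muy) ** power * p[i - 1, j - 1]
                              for i in idx for j in idx)
        feats["Contrast"] = sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
        feats["Correlation"] = ((feats["Autocorrelation"] - mux * muy) / (sigx * sigy)
                                if sigx > 0 and sigy > 0 else 1.0)
        da = sum(k * pdiff[k] for k in range(ng))
        feats["DifferenceAverage"] = da
        feats["DifferenceEntropy"] = -sum(v * math.log2(v) for v in pdiff if v > 0)
        feats["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
        feats["JointEnergy"] = float((p**2).sum())
        hxy = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
        feats["JointEntropy"] = hxy
        hxy1 = -sum(p[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
                    for i in idx for j in idx
                    if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
        hxy2 = -sum(px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
                    for i in idx for j in idx if px[i - 1] * py[j - 1] > 0)
        hx = -sum(v * math.log2(v) for v in px if v > 0)
        hy = -sum(v * math.log2(v) for v in py if v > 0)
        dmax = max(hx, hy)
        feats["Imc1"] = (hxy - hxy1) / dmax if dmax > 0 else 0.0
        feats["Imc2"] = (math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
                         if hxy2 >= hxy else 0.0)
        feats["Idm"] = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx)
        if ng > 1:
            q = np.zeros((ng, ng))
            for i in idx:
                for j in idx:
                    q[i - 1, j - 1] = sum(
                        p[i - 1, k - 1] * p[j - 1, k - 1] / (px[i - 1] * py[k - 1])
                        for k in idx if px[i - 1] > 0 and py[k - 1] > 0)
            ev = sorted(abs(np.linalg.eigvals(q)))
            feats["MCC"] = math.sqrt(max(0.0, ev[-2])) if len(ev) > 1 else 1.0
        else:
            feats["MCC"] = 1.0
        feats["Idmn"] = sum(p[i - 1, j - 1] / (1 + ((i - j) / ng) ** 2)
                            for i in idx for j in idx)
        feats["Id"] = sum(p[i - 1, j - 1] / (1 + abs(i - j)) for i in idx for j in idx)
        feats["Idn"] = sum(p[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in idx for j in idx)
        feats["InverseVariance"] = sum(p[i - 1, j - 1] / (i - j) ** 2
                                       for i in idx for j in idx if i != j)
        feats["MaximumProbability"] = float(p.max())
        feats["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
        feats["SumEntropy"] = -sum(v * math.log2(v) for v in psum if v > 0)
        feats["SumSquares"] = sum((i - mux) ** 2 * px[i - 1] for i in idx)
        per_dir.append(feats)
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ------------------------------------------------------------------ GLRLM

def glrlm_runs(levels, mask, direction):
    """Enumerate (level, length) runs by walking each line pixel by pixel."""
    h, w = levels.shape
    dr, dc = direction
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                if cur is not None and levels[r, c] == cur:
                    length += 1
                else:
                    if cur is not None:
                        runs.append((cur, length))
                    cur, length = levels[r, c], 1
            else:
                if cur is not None:
                    runs.append((cur, length))
                cur, length = None, 0
            r, c = r + dr, c + dc
        if cur is not None:
            runs.append((cur, length))
    return runs


def _rl_oracle(entries, ng, n_px, kind):
    """entries: list of (level, size); kind in {'Run','Zone'}."""
    nr = len(entries)
    lmax = max(s for _, s in entries)
    p = np.zeros((ng, lmax))
    for lv, s in entries:
        p[lv - 1, s - 1] += 1
    mat = p.copy()
    p = p / nr
    feats = {}
    i = np.arange(1, ng + 1)
    j = np.arange(1, lmax + 1)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = sum(ii * pg[ii - 1] for ii in i)
    mu_j = sum(jj * pl[jj - 1] for jj in j)
    def S(fn):
        return sum(fn(ii, jj) * p[ii - 1, jj - 1] for ii in i for jj in j)
    short = "ShortRun" if kind == "Run" else "SmallArea"
    long_ = "LongRun" if kind == "Run" else "LargeArea"
    lnu = "RunLengthNonUniformity" if kind == "Run" else "SizeZoneNonUniformity"
    pct = "RunPercentage" if kind == "Run" else "ZonePercentage"
    lv_ = "RunVariance" if kind == "Run" else "ZoneVariance"
    ent = "RunEntropy" if kind == "Run" else "ZoneEntropy"
    g = "Run" if kind == "Run" else "Zone"
    feats[short + "Emphasis"] = S(lambda a, b: 1 / b**2)
    feats[long_ + "Emphasis"] = S(lambda a, b: b**2)
    feats["GrayLevelNonUniformity"] = sum(mat[ii - 1].sum() ** 2 for ii in i) / nr
    feats["GrayLevelNonUniformityNormalized"] = sum(mat[ii - 1].sum() ** 2 for ii in i) / nr**2
    feats[lnu] = sum(mat[:, jj - 1].sum() ** 2 for jj in j) / nr
    feats[lnu + "Normalized"] = sum(mat[:, jj - 1].sum() ** 2 for jj in j) / nr**2
    feats[pct] = nr / n_px
    feats["GrayLevelVariance"] = S(lambda a, b: (a - mu_i) ** 2)
    feats[lv_] = S(lambda a, b: (b - mu_j) ** 2)
    feats[ent] = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
    feats["LowGrayLevel" + g + "Emphasis" if kind == "Run" else "LowGrayLevelZoneEmphasis"] = \
        S(lambda a, b: 1 / a**2)
    feats["HighGrayLevel" + g + "Emphasis" if kind == "Run" else "HighGrayLevelZoneEmphasis"] = \
        S(lambda a, b: a**2)
    feats[short + "LowGrayLevelEmphasis"] = S(lambda a, b: 1 / (a**2 * b**2))
    feats[short + "HighGrayLevelEmphasis"] = S(lambda a, b: a**2 / b**2)
    feats[long_ + "LowGrayLevelEmphasis"] = S(lambda a, b: b**2 / a**2)
    feats[long_ + "HighGrayLevelEmphasis"] = S(lambda a, b: a**2 * b**2)
    return feats


def glrlm_features_oracle(levels, mask, ng):
    n_px = int(mask.sum())
    per_dir = []
    for d in DIRS:
        runs = glrlm_runs(levels, mask, d)
        if runs:
            per_dir.append(_rl_oracle(runs, ng, n_px, "Run"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ------------------------------------------------------------------ GLSZM

def glszm_zones(levels, mask):
    """8-connected equal-level zones by explicit flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                lv = levels[r, c]
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                                    and not seen[r2, c2] and levels[r2, c2] == lv):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((int(lv), size))
    return zones


def glszm_features_oracle(levels, mask, ng):
    zones = glszm_zones(levels, mask)
    return _rl_oracle(zones, ng, int(mask.sum()), "Zone")


# ------------------------------------------------------------------ GLDM

def gldm_features_oracle(levels, mask, ng, alpha=0):
    h, w = levels.shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 1  # the pixel itself
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                            and abs(int(levels[r2, c2]) - int(levels[r, c])) <= alpha):
                        dep += 1
            entries.append((int(levels[r, c]), dep))
    nz = len(entries)
    dmax = max(d for _, d in entries)
    p = np.zeros((ng, dmax))
    for lv, d in entries:
        p[lv - 1, d - 1] += 1
    mat = p.copy()
    p = p / nz
    i = np.arange(1, ng + 1)
    j = np.arange(1, dmax + 1)
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mu_i = sum(ii * pg[ii - 1] for ii in i)
    mu_j = sum(jj * pd_[jj - 1] for jj in j)
    def S(fn):
        return sum(fn(ii, jj) * p[ii - 1, jj - 1] for ii in i for jj in j)
    return {
        "SmallDependenceEmphasis": S(lambda a, b: 1 / b**2),
        "LargeDependenceEmphasis": S(lambda a, b: b**2),
        "GrayLevelNonUniformity": sum(mat[ii - 1].sum() ** 2 for ii in i) / nz,
        "DependenceNonUniformity": sum(mat[:, jj - 1].sum() ** 2 for jj in j) / nz,
        "DependenceNonUniformityNormalized":
            sum(mat[:, jj - 1].sum() ** 2 for jj in j) / nz**2,
        "GrayLevelVariance": S(lambda a, b: (a - mu_i) ** 2),
        "DependenceVariance": S(lambda a, b: (b - mu_j) ** 2),
        "DependenceEntropy": -sum(v * math.log2(v) for v in p.ravel() if v > 0),
        "LowGrayLevelEmphasis": S(lambda a, b: 1 / a**2),
        "HighGrayLevelEmphasis": S(lambda a, b: a**2),
        "SmallDependenceLowGrayLevelEmphasis": S(lambda a, b: 1 / (a**2 * b**2)),
        "SmallDependenceHighGrayLevelEmphasis": S(lambda a, b: a**2 / b**2),
        "LargeDependenceLowGrayLevelEmphasis": S(lambda a, b: b**2 / a**2),
        "LargeDependenceHighGrayLevelEmphasis": S(lambda a, b: a**2 * b**2),
    }


# ------------------------------------------------------------------ NGTDM

def ngtdm_features_oracle(levels, mask, ng):
    h, w = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        nbrs.append(int(levels[r2, c2]))
            if not nbrs:
                continue
            lv = int(levels[r, c])
            n_i[lv - 1] += 1
            s_i[lv - 1] += abs(lv - sum(nbrs) / len(nbrs))
    npx = n_i.sum()
    p_i = n_i / npx
    present = [i for i in range(1, ng + 1) if n_i[i - 1] > 0]
    ngp = len(present)
    ps = sum(p_i[i - 1] * s_i[i - 1] for i in present)
    coarse = 1 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p_i[i - 1] * p_i[j - 1] * (i - j) ** 2
                        for i in present for j in present) / (ngp * (ngp - 1))
                    * sum(s_i) / npx)
        den = sum(abs(i * p_i[i - 1] - j * p_i[j - 1]) for i in present for j in present)
        busy = ps / den if den > 0 else 0.0
        cplx = sum(abs(i - j) * (p_i[i - 1] * s_i[i - 1] + p_i[j - 1] * s_i[j - 1])
                   / (p_i[i - 1] + p_i[j - 1]) for i in present for j in present) / npx
        stot = sum(s_i)
        strength = (sum((p_i[i - 1] + p_i[j - 1]) * (i - j) ** 2
                        for i in present for j in present) / stot if stot > 0 else 0.0)
    else:
        contrast = busy = cplx = strength = 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy,
            "Complexity": cplx, "Strength": strength}


# ------------------------------------------------------------------ ARI

def ari_oracle(a, b):
    """O(n^2) explicit pair classification."""
    a, b = list(a), list(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa:
            n10 += 1
        elif sb:
            n01 += 1
        else:
            n00 += 1
    total = n * (n - 1) / 2
    index = n11
    exp = (n11 + n10) * (n11 + n01) / total
    mx = 0.5 * ((n11 + n10) + (n11 + n01))
    if mx == exp:
        return 1.0
    return (index - exp) / (mx - exp)


def first_order_oracle(x, area_per_px=1.0, bin_width=25.0):
    """Direct per-formula first-order statistics on a 1-D sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = x.sum() / n
    var = ((x - mean) ** 2).sum() / n
    sd = math.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    lo = x.min()
    lev = np.floor((x - lo) / bin_width).astype(int)
    counts = np.bincount(lev)
    p = counts[counts > 0] / n
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum() * area_per_px),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(lo),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - lo),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(math.sqrt((x**2).mean())),
        "Skewness": float((((x - mean) / sd) ** 3).mean()) if sd > 0 else 0.0,
        "Kurtosis": float((((x - mean) / sd) ** 4).mean()) if sd > 0 else 0.0,
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }
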