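"""Gray-level texture matrices and their features.

Five families over a discretized ROI:

* GLCM  — symmetric co-occurrence at distance 1 over the 4 unique 2D
  directions, normalized per direction, features averaged over
  directions (24 features incl. Imc1/Imc2/MCC).
* GLRLM — run lengths of equal level per direction, 4 directions
  averaged (standard 16-feature set).
* GLSZM — 8-connected zones of equal level (16 features).
* GLDM  — gray-level dependence: for each pixel, the dependence size is
  1 + the number of 8-neighbors (in-mask) whose level differs by at
  most alpha (14 features).
* NGTDM — neighboring gray tone difference (5 features); a pixel
  contributes if it has at least one in-mask 8-neighbor.

Degenerate single-level ROIs return documented constants rather than
NaN (e.g. GLCM Correlation = 1, NGTDM Coarseness = 1e6) so that
downstream z-scoring is not poisoned.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .image import DiscretizedROI

_EPS = np.finfo(float).eps

DIRECTIONS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))

COARSENESS_CONSTANT = 1e6  # flagged value when sum(p_i * s_i) == 0


# --------------------------------------------------------------------------- GLCM

def glcm_matrices(disc: DiscretizedROI) -> np.ndarray:
    """(4, Ng, Ng) symmetric co-occurrence counts, one slice per direction."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    h, w = lev.shape
    out = np.zeros((4, ng, ng))
    for d, (dr, dc) in enumerate(DIRECTIONS_2D):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = lev[r0:r1, c0:c1]
        b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ma = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        i, j = a[ma] - 1, b[ma] - 1
        np.add.at(out[d], (i, j), 1)
        np.add.at(out[d], (j, i), 1)
    return out


def glcm_features(disc: DiscretizedROI) -> dict[str, float]:
    ng = disc.ng
    mats = glcm_matrices(disc)
    idx = np.arange(1, ng + 1, dtype=float)
    ii = idx[:, None] * np.ones((1, ng))
    jj = ii.T
    per_dir: list[dict[str, float]] = []
    for mat in mats:
        s = mat.sum()
        if s == 0:
            continue
        p = mat / s
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mux = float((idx * px).sum())
        muy = float((idx * py).sum())
        sigx = float(np.sqrt(((idx - mux) ** 2 * px).sum()))
        sigy = float(np.sqrt(((idx - muy) ** 2 * py).sum()))
        # diagonal / cross-diagonal distributions
        k_diff = np.arange(ng, dtype=float)          # |i-j| = 0..Ng-1
        p_diff = np.zeros(ng)
        k_sum = np.arange(2, 2 * ng + 1, dtype=float)  # i+j = 2..2Ng
        p_sum = np.zeros(2 * ng - 1)
        for a in range(ng):
            for b in range(ng):
                p_diff[abs(a - b)] += p[a, b]
                p_sum[a + b] += p[a, b]
        nz = p > 0
        hxy = float(-(p[nz] * np.log2(p[nz])).sum())
        pxy = px[:, None] * py[None, :]
        nz1 = (p > 0) & (pxy > 0)
        hxy1 = float(-(p[nz1] * np.log2(pxy[nz1])).sum())
        nz2 = pxy > 0
        hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
        hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
        hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
        dmax = max(hx, hy)
        imc1 = (hxy - hxy1) / dmax if dmax > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
        # MCC: sqrt of second largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k))
        if ng > 1:
            valid_k = py > 0
            pi = np.where(px > 0, px, 1.0)
            pk = p[:, valid_k] / py[valid_k][None, :]
            q = (p[:, valid_k] / pi[:, None]) @ pk.T
            ev = np.sort(np.abs(np.linalg.eigvals(q)))
            mcc = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) > 1 else 1.0
        else:
            mcc = 1.0
        da = float((k_diff * p_diff).sum())
        corr = ((ii * jj * p).sum() - mux * muy) / (sigx * sigy) if sigx > 0 and sigy > 0 else 1.0
        cplus = ii + jj - mux - muy
        nz_offdiag = ii != jj
        per_dir.append({
            "Autocorrelation": float((ii * jj * p).sum()),
            "JointAverage": mux,
            "ClusterProminence": float((cplus**4 * p).sum()),
            "ClusterShade": float((cplus**3 * p).sum()),
            "ClusterTendency": float((cplus**2 * p).sum()),
            "Contrast": float(((ii - jj) ** 2 * p).sum()),
            "Correlation": float(corr),
            "DifferenceAverage": da,
            "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
            "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
            "JointEnergy": float((p**2).sum()),
            "JointEntropy": hxy,
            "Imc1": imc1,
            "Imc2": imc2,
            "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
            "MCC": mcc,
            "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
            "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
            "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
            "InverseVariance": float((p[nz_offdiag] / (ii - jj)[nz_offdiag] ** 2).sum()),
            "MaximumProbability": float(p.max()),
            "SumAverage": float((k_sum * p_sum).sum()),
            "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
            "SumSquares": float(((idx - mux) ** 2 * px).sum()),
        })
    if not per_dir:
        per_dir = [{k: 0.0 for k in GLCM_NAMES}]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "MCC", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


# --------------------------------------------------------------------------- GLRLM

def _lines(lev: np.ndarray, mask: np.ndarray, direction):
    """Yield (levels, valid) 1-D arrays along a direction."""
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(lev.shape[0]):
            yield lev[r], mask[r]
    elif (dr, dc) == (1, 0):
        for c in range(lev.shape[1]):
            yield lev[:, c], mask[:, c]
    elif (dr, dc) == (1, 1):
        h, w = lev.shape
        for off in range(-h + 1, w):
            yield np.diagonal(lev, off), np.diagonal(mask, off)
    else:  # (1, -1): anti-diagonals
        fl, fm = lev[:, ::-1], mask[:, ::-1]
        h, w = lev.shape
        for off in range(-h + 1, w):
            yield np.diagonal(fl, off), np.diagonal(fm, off)


def _run_lengths(values: np.ndarray, valid: np.ndarray):
    """Run-length encode the valid segments of one line."""
    v = np.asarray(values)
    ok = np.asarray(valid)
    n = len(v)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i + 1
        while j < n and ok[j] and v[j] == v[i]:
            j += 1
        yield int(v[i]), j - i
        i = j


def glrlm_matrices(disc: DiscretizedROI, max_len: int | None = None) -> np.ndarray:
    """(4, Ng, Lmax) run-length counts per direction."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    lmax = max_len or max(lev.shape)
    out = np.zeros((4, ng, lmax))
    for d, direction in enumerate(DIRECTIONS_2D):
        for vals, ok in _lines(lev, mask, direction):
            for level, length in _run_lengths(vals, ok):
                out[d, level - 1, length - 1] += 1
    return out


def _rl_features(mat: np.ndarray, n_px: int, prefix: str) -> dict[str, float]:
    """Shared run-length/size-zone feature formulas.

    ``prefix`` selects the naming family: 'Run' or 'Zone'/'Area'.
    """
    nr = mat.sum()
    if nr == 0:
        return {}
    p = mat / nr
    ng, nl = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nl + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)   # gray-level marginal
    pl = p.sum(axis=0)   # length/size marginal
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, nl + 1) * pl).sum())
    nz = p > 0
    ent = float(-(p[nz] * np.log2(p[nz])).sum())
    rg = mat.sum(axis=1)
    rl = mat.sum(axis=0)
    if prefix == "Run":
        names = {
            "short": "ShortRunEmphasis", "long": "LongRunEmphasis",
            "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
            "lnu": "RunLengthNonUniformity", "lnun": "RunLengthNonUniformityNormalized",
            "pct": "RunPercentage", "glv": "GrayLevelVariance", "lv": "RunVariance",
            "ent": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
            "hgl": "HighGrayLevelRunEmphasis",
            "sl": "ShortRunLowGrayLevelEmphasis", "sh": "ShortRunHighGrayLevelEmphasis",
            "ll": "LongRunLowGrayLevelEmphasis", "lh": "LongRunHighGrayLevelEmphasis",
        }
    else:
        names = {
            "short": "SmallAreaEmphasis", "long": "LargeAreaEmphasis",
            "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
            "lnu": "SizeZoneNonUniformity", "lnun": "SizeZoneNonUniformityNormalized",
            "pct": "ZonePercentage", "glv": "GrayLevelVariance", "lv": "ZoneVariance",
            "ent": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
            "hgl": "HighGrayLevelZoneEmphasis",
            "sl": "SmallAreaLowGrayLevelEmphasis", "sh": "SmallAreaHighGrayLevelEmphasis",
            "ll": "LargeAreaLowGrayLevelEmphasis", "lh": "LargeAreaHighGrayLevelEmphasis",
        }
    return {
        names["short"]: float((p / j**2).sum()),
        names["long"]: float((p * j**2).sum()),
        names["gln"]: float((rg**2).sum() / nr),
        names["glnn"]: float((rg**2).sum() / nr**2),
        names["lnu"]: float((rl**2).sum() / nr),
        names["lnun"]: float((rl**2).sum() / nr**2),
        names["pct"]: float(nr / n_px),
        names["glv"]: float((p * (i - mu_i) ** 2).sum()),
        names["lv"]: float((p * (j - mu_j) ** 2).sum()),
        names["ent"]: ent,
        names["lgl"]: float((p / i**2).sum()),
        names["hgl"]: float((p * i**2).sum()),
        names["sl"]: float((p / (i**2 * j**2)).sum()),
        names["sh"]: float((p * i**2 / j**2).sum()),
        names["ll"]: float((p * j**2 / i**2).sum()),
        names["lh"]: float((p * i**2 * j**2).sum()),
    }


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    mats = glrlm_matrices(disc)
    n_px = int(disc.mask.sum())
    per_dir = [f for f in (_rl_features(m, n_px, "Run") for m in mats) if f]
    if not per_dir:
        return {}
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


GLRLM_NAMES = tuple(
    _rl_features(np.ones((2, 2)), 4, "Run").keys()
)


# --------------------------------------------------------------------------- GLSZM

def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """(Ng, Smax) zone-size counts; zones are 8-connected equal-level components."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    n_px = int(mask.sum())
    out = np.zeros((ng, n_px))
    for level in np.unique(lev[mask]):
        lab = measure.label((lev == level) & mask, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            out[level - 1, s - 1] += 1
    return out


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    mat = glszm_matrix(disc)
    return _rl_features(mat, int(disc.mask.sum()), "Zone")


GLSZM_NAMES = tuple(_rl_features(np.ones((2, 2)), 4, "Zone").keys())


# --------------------------------------------------------------------------- GLDM

def gldm_matrix(disc: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """(Ng, Dmax) dependence counts; dependence = 1 + #similar in-mask 8-neighbors."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    h, w = lev.shape
    counts = np.zeros(lev.shape, dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            a = lev[r0:r1, c0:c1]
            b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            both = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            sim = both & (np.abs(a - b) <= alpha)
            counts[r0:r1, c0:c1] += sim
    dep = counts[mask] + 1
    lv = lev[mask]
    out = np.zeros((ng, 9))
    np.add.at(out, (lv - 1, dep - 1), 1)
    return out


def gldm_features(disc: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    mat = gldm_matrix(disc, alpha)
    nz_tot = mat.sum()
    p = mat / nz_tot
    ng, nd = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nd + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, nd + 1) * pd).sum())
    nz = p > 0
    rg = mat.sum(axis=1)
    rd = mat.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((rg**2).sum() / nz_tot),
        "DependenceNonUniformity": float((rd**2).sum() / nz_tot),
        "DependenceNonUniformityNormalized": float((rd**2).sum() / nz_tot**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
)


# --------------------------------------------------------------------------- NGTDM

def ngtdm_table(disc: DiscretizedROI):
    """Return (n_i, p_i, s_i) arrays over levels 1..Ng.

    s_i sums |i - mean of in-mask 8-neighbors| over contributing pixels;
    pixels with no in-mask neighbor do not contribute and are excluded
    from the pixel count.
    """
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    h, w = lev.shape
    nsum = np.zeros(lev.shape)
    ncnt = np.zeros(lev.shape)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            nb_mask = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            nb_lev = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            nsum[r0:r1, c0:c1] += nb_lev * nb_mask
            ncnt[r0:r1, c0:c1] += nb_mask
    valid = mask & (ncnt > 0)
    diff = np.zeros(lev.shape)
    diff[valid] = np.abs(lev[valid] - nsum[valid] / ncnt[valid])
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = lev[valid]
    np.add.at(n_i, lv - 1, 1)
    np.add.at(s_i, lv - 1, diff[valid])
    n_tot = n_i.sum()
    p_i = n_i / n_tot if n_tot > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(disc)
    npx = n_i.sum()
    present = n_i > 0
    ngp = int(present.sum())
    i = np.arange(1, disc.ng + 1, dtype=float)
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CONSTANT
    if ngp > 1 and npx > 0:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        d2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * d2).sum()) / (ngp * (ngp - 1)) \
            * float(s_i.sum()) / npx
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        pssum = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        complexity = float((np.abs(ip[:, None] - ip[None, :]) * pssum
                            / (pp[:, None] + pp[None, :])).sum()) / npx
        s_tot = float(s_i.sum())
        strength = float(((pp[:, None] + pp[None, :]) * d2).sum()) / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
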