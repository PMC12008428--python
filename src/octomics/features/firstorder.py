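"""First-order intensity statistics over the masked region (18 features).

Histogram-based features (Entropy, Uniformity) use the same
fixed-bin-width discretization as the texture matrices. Variance is the
population variance; Skewness and Kurtosis are the standardized third
and fourth moments (Kurtosis is not excess-corrected). On a constant
region the standardized moments are undefined and are returned as 0,
which keeps downstream z-scoring well behaved.
"""

from __future__ import annotations

import numpy as np

from .image import BScanImage, InputError, ROIMask, discretize

FIRST_ORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(image, mask, bin_width: float = 25.0,
                         spacing_mm=None) -> dict[str, float]:
    """Compute the 18 first-order features on the in-mask intensities."""
    px = np.asarray(image.pixels if isinstance(image, BScanImage) else image, dtype=float)
    if spacing_mm is None:
        spacing_mm = image.spacing_mm if isinstance(image, BScanImage) else (1.0, 1.0)
    m = np.asarray(mask.pixels if isinstance(mask, ROIMask) else mask).astype(bool)
    if px.shape != m.shape:
        raise InputError("image and mask shapes differ")
    if not m.any():
        raise InputError("empty mask")
    x = px[m]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew = kurt = 0.0  # flagged constant-region convention

    disc = discretize(px, m, bin_width)
    p = np.bincount(disc.in_mask)[1:] / n
    p_nz = p[p > 0]

    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(np.sum(x**2) * spacing_mm[0] * spacing_mm[1]),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p_nz**2)),
    }
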