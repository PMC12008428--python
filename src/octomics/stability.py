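"""Clustering robustness: bootstrap ARI and incremental noise injection.

The bootstrap procedure mirrors the full pipeline: each replicate
resamples eyes with replacement, refits z-scoring, PCA (fixed number of
components) and K-means from scratch, and compares replicate labels
with the original partition restricted to the resampled eyes
(duplicates counted with multiplicity). The Adjusted Rand Index is the
pair-counting chance-corrected agreement; being permutation-invariant,
no label matching is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting ARI via the contingency-table closed form."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise InputError("labelings must have equal length")
    n = a.size
    if n < 2:
        raise InputError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_nij = comb(cont, 2).sum()
    sum_ai = comb(cont.sum(axis=1), 2).sum()
    sum_bj = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_ai * sum_bj / total
    max_index = 0.5 * (sum_ai + sum_bj)
    if max_index == expected:
        return 1.0
    return float((sum_nij - expected) / (max_index - expected))


@dataclass
class StabilityReport:
    ari_samples: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    noise_curve: list = field(default_factory=list)  # (sigma, mean ARI, SD)
    n_failed: int = 0


def _cluster_table(table: pd.DataFrame, n_pcs: int, k: int, seed: int) -> np.ndarray:
    """z-score -> PCA -> K-means; the unit pipeline used by the resamplers."""
    from .clustering import kmeans
    from .reduction import fit_pca, project, zscore_features

    z = zscore_features(table)
    model = fit_pca(z)
    npc = min(n_pcs, model.loadings.shape[1])
    scores = project(model, z, npc)
    return kmeans(scores, k, seed=seed).labels


def bootstrap_stability(table: pd.DataFrame, n_pcs: int = 16, k: int = 4,
                        B: int = 500, seed: int | None = None,
                        unique_instances: bool = False) -> StabilityReport:
    """Bootstrap ARI of the z-score -> PCA -> K-means pipeline.

    ``unique_instances`` compares on deduplicated resampled eyes instead
    of with multiplicity.
    """
    if B <= 0:
        raise InputError("B must be positive")
    if len(table) < k:
        raise InputError("need at least k rows")
    rng = np.random.default_rng(seed)
    n = len(table)
    original = _cluster_table(table, n_pcs, k, seed=int(rng.integers(0, 2**31 - 1)))
    aris = []
    failed = 0
    x = table.reset_index(drop=True)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < k:
            failed += 1
            log.warning("bootstrap replicate with < k distinct rows skipped")
            continue
        if unique_instances:
            idx = np.unique(idx)
        rep = x.iloc[idx]
        try:
            rep_labels = _cluster_table(rep, n_pcs, k, seed=int(rng.integers(0, 2**31 - 1)))
        except Exception as exc:
            failed += 1
            log.warning("bootstrap replicate failed: %s", exc)
            continue
        aris.append(adjusted_rand_index(rep_labels, original[idx]))
    aris = np.asarray(aris)
    lo, hi = np.percentile(aris, [2.5, 97.5]) if len(aris) else (np.nan, np.nan)
    return StabilityReport(ari_samples=aris, mean=float(aris.mean()),
                           sd=float(aris.std(ddof=1)) if len(aris) > 1 else 0.0,
                           ci_low=float(lo), ci_high=float(hi), n_failed=failed)


def noise_sensitivity(data, sigma_grid, reps: int = 20, domain: str = "feature",
                      n_pcs: int = 16, k: int = 4, seed: int | None = None,
                      extraction_config=None):
    """ARI against the clean partition under increasing Gaussian noise.

    domain='feature': noise is added to the z-scored feature table.
    domain='image': noise (on the [0, 1] intensity scale) is added to
    each eye's image, features are re-extracted, and the pipeline is
    re-run; ``data`` must then be a list of synthetic eyes.
    """
    sigma_grid = list(sigma_grid)
    if any(s < 0 for s in sigma_grid) or sorted(sigma_grid) != sigma_grid:
        raise InputError("sigma_grid must be non-negative and ascending")
    rng = np.random.default_rng(seed)
    from .features import BScanImage, extract_table
    from .reduction import zscore_features

    if domain == "image":
        clean_table = extract_table(data, extraction_config)
    elif domain == "feature":
        clean_table = zscore_features(data)
    else:
        raise InputError("domain must be 'image' or 'feature'")
    clean_seed = int(rng.integers(0, 2**31 - 1))
    clean_labels = _cluster_table(clean_table, n_pcs, k, seed=clean_seed)
    curve = []
    for sigma in sigma_grid:
        vals = []
        for _ in range(reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            if sigma == 0:
                # identical data + identical seed: the pipeline is deterministic
                noisy, rep_seed = clean_table, clean_seed
            elif domain == "feature":
                noisy = clean_table + rng.normal(0.0, sigma, clean_table.shape)
            else:
                noisy_eyes = []
                for eye in data:
                    px = eye.image.pixels.astype(float) / 255.0
                    px = np.clip(px + rng.normal(0.0, sigma, px.shape), 0, 1)
                    img = BScanImage(pixels=np.round(px * 255).astype(np.uint8),
                                     spacing_mm=eye.image.spacing_mm, id=eye.image.id)
                    noisy_eyes.append(type(eye)(eye.eye_id, eye.true_class, img,
                                                eye.mask, eye.clinical, eye.endpoints))
                noisy = extract_table(noisy_eyes, extraction_config)
            labels = _cluster_table(noisy, n_pcs, k, seed=rep_seed)
            vals.append(adjusted_rand_index(labels, clean_labels))
        vals = np.asarray(vals)
        curve.append((float(sigma), float(vals.mean()),
                      float(vals.std(ddof=1)) if len(vals) > 1 else 0.0))
    return curve
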