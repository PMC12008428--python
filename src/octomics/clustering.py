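"""Hybrid K-means / Ward clustering in PC-score space with k selection.

k is chosen two ways and cross-checked: the elbow of the within-cluster
sum-of-squares curve (maximum second forward difference), and
Monti-style consensus clustering — repeated subsampling, K-means on
each subsample, co-assignment frequencies among co-sampled pairs, and
the relative change Delta(k) of the area under the consensus CDF. The
"hybrid" partition is K-means initialized at the Ward centroids, with
cross-method agreement reported as an Adjusted Rand Index.

Cluster labels are canonicalized to 1..k by decreasing cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .stability import adjusted_rand_index

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # 1..k, size-ordered
    k: int
    method: str
    inertia: float = float("nan")
    extras: dict = field(default_factory=dict)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by decreasing cluster size."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[v] for v in labels], dtype=int)


def kmeans(scores: np.ndarray, k: int, seed: int | None = None,
           n_init: int = 10) -> ClusterAssignment:
    """K-means++ with n_init restarts, best by inertia."""
    x = np.asarray(scores, dtype=float)
    if not 1 <= k <= len(x):
        raise InputError("require 1 <= k <= n")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return ClusterAssignment(labels=_canonicalize(km.labels_ + 1), k=k,
                             method="kmeans", inertia=float(km.inertia_))


def ward_hclust(scores: np.ndarray, k: int) -> ClusterAssignment:
    """Agglomerative Ward clustering (Euclidean), tree cut at k."""
    x = np.asarray(scores, dtype=float)
    if not 1 <= k <= len(x):
        raise InputError("require 1 <= k <= n")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(labels=_canonicalize(labels), k=k, method="ward",
                             extras={"linkage_height": float(z[-1, 2])})


def hybrid_cluster(scores: np.ndarray, k: int, seed: int | None = None) -> ClusterAssignment:
    """Ward centroids initialize a single K-means run; final labels from K-means."""
    x = np.asarray(scores, dtype=float)
    if k == 1:
        return ClusterAssignment(labels=np.ones(len(x), dtype=int), k=1, method="hybrid",
                                 inertia=float(((x - x.mean(0)) ** 2).sum()))
    ward = ward_hclust(x, k)
    centroids = np.vstack([x[ward.labels == c].mean(axis=0) for c in range(1, k + 1)])
    km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=seed).fit(x)
    labels = _canonicalize(km.labels_ + 1)
    ari_vs_ward = adjusted_rand_index(labels, ward.labels)
    return ClusterAssignment(labels=labels, k=k, method="hybrid",
                             inertia=float(km.inertia_),
                             extras={"ari_vs_ward": float(ari_vs_ward)})


def elbow_select_k(scores: np.ndarray, k_max: int = 10,
                   seed: int | None = None):
    """Elbow of the WSS curve: argmax of the second forward difference of
    log(WSS).

    The log scale makes the curvature measure invariant to the overall
    dispersion, so the detected levelling-off point does not default to
    k=2 whenever the first split removes the most raw variance.
    Evaluates k = 1..k_max; the candidate range is k = 2..k_max-1.
    Ties return the smallest k with a low-confidence flag.
    """
    if k_max < 3:
        raise InputError("k_max must be >= 3")
    x = np.asarray(scores, dtype=float)
    wss = {kk: kmeans(x, kk, seed=seed).inertia for kk in range(1, k_max + 1)}
    eps = max(1e-12, 1e-12 * wss[1])
    lw = {kk: np.log(max(v, eps)) for kk, v in wss.items()}
    d2 = {kk: lw[kk - 1] - 2 * lw[kk] + lw[kk + 1] for kk in range(2, k_max)}
    best = max(d2.values())
    candidates = [kk for kk, v in d2.items() if np.isclose(v, best, rtol=1e-9, atol=1e-12)]
    k = min(candidates)
    low_confidence = len(candidates) > 1 or best <= 0
    return k, {"wss": wss, "second_diff": d2, "low_confidence": low_confidence}


@dataclass
class ConsensusCurve:
    k_values: list[int]
    area: dict                    # k -> A(k)
    delta: dict                   # k -> relative change Delta(k)
    consensus: dict               # k -> (n, n) consensus matrix
    low_confidence: bool = False


def consensus_select_k(scores: np.ndarray, k_range=range(2, 7),
                       n_resamples: int = 100, subsample_frac: float = 0.8,
                       seed: int | None = None, delta_threshold: float = 0.1):
    """Monti-style consensus clustering over a k range.

    For each k, items are repeatedly subsampled (without replacement)
    and clustered with K-means; the consensus matrix holds co-cluster
    frequencies among co-sampled pairs. A(k) is the area under the
    empirical CDF of off-diagonal consensus entries; Delta(k) is the
    relative change of A. The chosen k is the largest k whose Delta(k)
    still exceeds ``delta_threshold``, i.e. the last k that buys a
    substantial consensus gain before the Delta curve levels off (if
    none qualifies, the k with the largest Delta is returned).
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 20:
        raise InputError("consensus clustering needs n >= 20")
    if n_resamples < 10:
        log.warning("n_resamples < 10: consensus estimate is low-confidence")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    k_values = list(k_range)
    area, delta, consensus = {}, {}, {}
    for k in k_values:
        co = np.zeros((n, n))
        cnt = np.zeros((n, n))
        done = 0
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(idx)) < k:
                log.warning("subsample smaller than k; skipped")
                continue
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(0, 2**31 - 1))).fit(x[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            co[np.ix_(idx, idx)] += same
            cnt[np.ix_(idx, idx)] += 1
            done += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            cmat = np.where(cnt > 0, co / np.where(cnt > 0, cnt, 1), 0.0)
        np.fill_diagonal(cmat, 1.0)
        consensus[k] = cmat
        iu = np.triu_indices(n, k=1)
        vals = cmat[iu]
        # area under the empirical CDF on [0, 1] equals 1 - mean
        area[k] = float(1.0 - vals.mean())
        if done < n_resamples:
            log.info("k=%d: %d/%d resamples used", k, done, n_resamples)
    for i, k in enumerate(k_values):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[k_values[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    qualifying = [k for k in k_values if delta[k] >= delta_threshold]
    k_opt = max(qualifying) if qualifying else max(delta, key=delta.get)
    curve = ConsensusCurve(k_values=k_values, area=area, delta=delta,
                           consensus=consensus,
                           low_confidence=n_resamples < 10)
    return k_opt, curve
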