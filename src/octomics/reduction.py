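"""Standardization and PCA with permutation-calibrated component retention.

Horn's parallel analysis: observed eigenvalues of the z-scored feature
covariance are compared with the 95th percentile of eigenvalues from
null tables obtained by independently permuting each column (which
preserves every marginal exactly while destroying correlation).
Components are retained while the observed eigenvalue of the k-th
leading component exceeds its null percentile; retention stops at the
first failure (the standard Horn convention). A Gaussian-noise null is
available as an alternative.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class PCModel:
    loadings: np.ndarray          # (n_features, n_components), orthonormal columns
    eigenvalues: np.ndarray       # descending, >= 0
    explained_variance_fraction: np.ndarray
    n_retained: int
    column_means: np.ndarray
    column_sds: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        meta = {
            "n_retained": int(self.n_retained),
            "feature_names": list(self.feature_names),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "loadings": self.loadings.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh)


def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (sample SD); zero-variance columns are dropped."""
    if len(table) < 2:
        raise InputError("need at least 2 rows to standardize")
    sds = table.std(axis=0, ddof=1)
    dead = sds[~(sds > 0)].index.tolist()
    if dead:
        log.warning("dropping %d zero-variance columns: %s", len(dead), dead[:5])
    kept = table.drop(columns=dead)
    return (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)


def _eigvals_desc(z: np.ndarray) -> np.ndarray:
    cov = np.cov(z, rowvar=False, ddof=1)
    ev = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    return np.clip(ev, 0.0, None)


def fit_pca(z_table: pd.DataFrame) -> PCModel:
    """Eigendecomposition of the sample covariance of a z-scored table.

    Component sign is fixed so the largest-magnitude loading of each
    component is positive, making the decomposition reproducible.
    """
    z = np.asarray(z_table, dtype=float)
    cov = np.cov(z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        imax = np.argmax(np.abs(evecs[:, k]))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    names = list(z_table.columns) if isinstance(z_table, pd.DataFrame) else []
    return PCModel(
        loadings=evecs, eigenvalues=evals, explained_variance_fraction=frac,
        n_retained=evecs.shape[1],
        column_means=np.asarray(z_table.mean(axis=0)) if isinstance(z_table, pd.DataFrame)
        else z.mean(axis=0),
        column_sds=np.asarray(z_table.std(axis=0, ddof=1)) if isinstance(z_table, pd.DataFrame)
        else z.std(axis=0, ddof=1),
        feature_names=names,
    )


@dataclass
class ParallelAnalysisResult:
    n_retained: int
    observed: np.ndarray
    null_percentiles: np.ndarray
    percentile: float
    n_perm: int

    def __int__(self) -> int:
        return self.n_retained


def parallel_analysis(z_table: pd.DataFrame, n_perm: int = 1000,
                      percentile: float = 95.0, seed: int | None = None,
                      null: str = "permutation") -> ParallelAnalysisResult:
    """Horn's parallel analysis on a z-scored table.

    null='permutation' permutes each column independently;
    null='gaussian' draws fresh standard-normal tables of the same shape.
    """
    if n_perm < 100:
        warnings.warn("parallel analysis with n_perm < 100 is poorly calibrated",
                      stacklevel=2)
    z = np.asarray(z_table, dtype=float)
    n, p = z.shape
    rng = np.random.default_rng(seed)
    observed = _eigvals_desc(z)
    null_ev = np.empty((n_perm, p))
    for r in range(n_perm):
        if null == "permutation":
            perm = np.empty_like(z)
            for j in range(p):
                perm[:, j] = z[rng.permutation(n), j]
        elif null == "gaussian":
            perm = rng.standard_normal((n, p))
        else:
            raise InputError(f"unknown null scheme {null!r}")
        null_ev[r] = _eigvals_desc(perm)
    thresholds = np.percentile(null_ev, percentile, axis=0)
    keep = observed > thresholds
    n_retained = 0
    for flag in keep:  # leading consecutive components only
        if flag:
            n_retained += 1
        else:
            break
    return ParallelAnalysisResult(n_retained=n_retained, observed=observed,
                                  null_percentiles=thresholds,
                                  percentile=percentile, n_perm=n_perm)


def project(model: PCModel, table: pd.DataFrame, n_components: int) -> np.ndarray:
    """Scores of (possibly new) rows on the leading components.

    New rows are standardized with the model's stored means/SDs.
    """
    if n_components > model.loadings.shape[1]:
        raise InputError("n_components exceeds available components")
    x = np.asarray(table, dtype=float)
    if x.shape[1] != model.loadings.shape[0]:
        raise InputError("feature schema mismatch")
    sds = np.where(model.column_sds > 0, model.column_sds, 1.0)
    z = (x - model.column_means) / sds
    return z @ model.loadings[:, :n_components]
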