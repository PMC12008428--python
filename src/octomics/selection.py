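"""Three-stage feature selection: collinearity pruning, ANOVA screen, Boruta.

Stage 1 greedily removes one member of every feature pair whose
absolute Pearson correlation exceeds a threshold (default 0.8): the
pair with the highest |r| is resolved first, dropping the member with
the larger mean absolute correlation to all other retained features
(ties broken by column order). Stage 2 keeps features whose one-way
ANOVA across cluster labels is significant (raw P by default, optional
Benjamini-Hochberg). Stage 3 is the canonical Boruta all-relevant
wrapper: each iteration appends an independently permuted "shadow" copy
of every undecided feature, fits a random forest, scores a hit when a
real feature's impurity importance exceeds the best shadow, and decides
features by two-sided binomial tests with Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


def prune_collinear(table: pd.DataFrame, r_threshold: float = 0.8) -> list[str]:
    """Greedy collinearity pruning; no retained pair exceeds the threshold."""
    if len(table) < 2:
        raise InputError("need at least 2 rows")
    cols = list(table.columns)
    corr = table.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_threshold:
            break
        mean_i = sub[i, alive].mean()
        mean_j = sub[j, alive].mean()
        # drop the member more correlated with everything else; ties -> later column
        drop = i if (mean_i > mean_j or (mean_i == mean_j and i > j)) else j
        alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def anova_filter(table: pd.DataFrame, group_labels, alpha: float = 0.05,
                 fdr: bool = False) -> list[str]:
    """One-way fixed-effects F-test per feature across group labels."""
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise InputError("need at least 2 groups")
    sizes = [np.sum(groups == g) for g in uniq]
    if min(sizes) < 2:
        raise InputError("every group needs at least 2 members")
    pvals = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        samples = [v[groups == g] for g in uniq]
        if np.ptp(v) == 0:
            pvals[col] = 1.0  # F = 0 for a constant feature
            continue
        try:
            pvals[col] = float(stats.f_oneway(*samples).pvalue)
        except Exception:
            pvals[col] = np.nan
            log.warning("ANOVA undefined for feature %s", col)
    names = [c for c in pvals if np.isfinite(pvals[c])]
    ps = np.array([pvals[c] for c in names])
    if fdr:
        reject, _, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    else:
        reject = ps < alpha
    return [c for c, r in zip(names, reject) if r]


@dataclass
class BorutaResult:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    importance_history: pd.DataFrame   # iterations x (features + "shadow_max")
    n_iterations: int

    @property
    def decisions(self) -> dict:
        out = {f: "confirmed" for f in self.confirmed}
        out.update({f: "tentative" for f in self.tentative})
        out.update({f: "rejected" for f in self.rejected})
        return out


def boruta(table: pd.DataFrame, binary_target, max_iter: int = 500,
           seed: int | None = None, rf_trees: int = 500,
           alpha: float = 0.05, min_iter_before_test: int = 5) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features."""
    y = np.asarray(binary_target)
    if len(np.unique(y)) != 2:
        raise InputError("target must be binary")
    if len(table) < 20:
        raise InputError("need at least 20 rows")
    rng = np.random.default_rng(seed)
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    hits = dict.fromkeys(cols, 0)
    status = dict.fromkeys(cols, "undecided")
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        active = [c for c in cols if status[c] != "rejected"]
        if not any(status[c] == "undecided" for c in cols):
            break
        xa = table[active].to_numpy(dtype=float)
        shadows = xa.copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = shadows[rng.permutation(n), j]
        design = np.hstack([xa, shadows])
        rf = RandomForestClassifier(n_estimators=rf_trees,
                                    random_state=int(rng.integers(0, 2**31 - 1)),
                                    n_jobs=1)
        rf.fit(design, y)
        imp = rf.feature_importances_
        real_imp = dict(zip(active, imp[:len(active)]))
        shadow_max = float(imp[len(active):].max())
        history.append({**real_imp, "shadow_max": shadow_max})
        for c in active:
            if status[c] == "undecided" and real_imp[c] > shadow_max:
                hits[c] += 1
        undecided = [c for c in cols if status[c] == "undecided"]
        if it >= min_iter_before_test and undecided:
            m = len(undecided)
            for c in undecided:
                p_hi = stats.binom.sf(hits[c] - 1, it, 0.5)
                p_lo = stats.binom.cdf(hits[c], it, 0.5)
                if p_hi < alpha / m:
                    status[c] = "confirmed"
                elif p_lo < alpha / m:
                    status[c] = "rejected"
    hist = pd.DataFrame(history)
    # resolve leftovers as tentative
    confirmed = [c for c in cols if status[c] == "confirmed"]
    tentative = [c for c in cols if status[c] == "undecided"]
    rejected = [c for c in cols if status[c] == "rejected"]
    return BorutaResult(confirmed=confirmed, tentative=tentative, rejected=rejected,
                        importance_history=hist, n_iterations=it)


@dataclass
class SelectionResult:
    stage1_retained: list[str]
    stage2_retained: list[str]
    stage3: BorutaResult
    parameters: dict

    @property
    def confirmed(self) -> list[str]:
        return self.stage3.confirmed


def select_features(table: pd.DataFrame, cluster_labels, outcome,
                    r_threshold: float = 0.8, alpha: float = 0.05,
                    fdr: bool = False, boruta_iter: int = 500,
                    rf_trees: int = 500, seed: int | None = None) -> SelectionResult:
    """Run the full cascade for one outcome; stages are nested by construction."""
    stage1 = prune_collinear(table, r_threshold)
    stage2 = anova_filter(table[stage1], cluster_labels, alpha=alpha, fdr=fdr)
    stage3 = boruta(table[stage2], outcome, max_iter=boruta_iter, seed=seed,
                    rf_trees=rf_trees) if stage2 else BorutaResult(
        [], [], [], pd.DataFrame(), 0)
    return SelectionResult(
        stage1_retained=stage1, stage2_retained=stage2, stage3=stage3,
        parameters={"r_threshold": r_threshold, "alpha": alpha, "fdr": fdr,
                    "boruta_iter": boruta_iter, "rf_trees": rf_trees, "seed": seed})
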