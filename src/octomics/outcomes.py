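"""Study endpoints, logistic outcome models, and cluster-comparison statistics.

Endpoints
---------
* Residual DME: after three anti-VEGF injections the central macular
  thickness (CMT) reduction falls below a band-dependent threshold —
  < 10% for baseline <= 400 um, < 15% for 401-500, < 20% for 501-600,
  < 25% above 600. Worsening edema (negative reduction) is residual in
  every band. RDME = residual OR short-term recurrence within 6 months.
* Poor vision: 6-month BCVA <= 20/63, i.e. logMAR >= log10(63/20);
  the boundary belongs to the poor-vision class.

Models
------
Univariate and backward-stepwise multivariable logistic regression
(Wald-based removal at stay_p), odds ratios with 95% Wald CIs; Table-1
style cluster comparisons (Shapiro-Wilk, Kruskal-Wallis with Dunn
post-hoc, chi-square/Fisher); two-way mixed-effects consistency
single-measure ICC for intra-rater reliability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


class InputError(ValueError):
    pass


POOR_VISION_LOGMAR = math.log10(63.0 / 20.0)


# ------------------------------------------------------------------ endpoints

def snellen_to_logmar(numerator: int, denominator: int) -> float:
    """Snellen fraction -> logMAR: log10(denominator/numerator)."""
    if numerator <= 0 or denominator <= 0:
        raise InputError("Snellen components must be positive")
    return math.log10(denominator / numerator)


def classify_residual_dme(cmt_baseline_um: float, cmt_post_um: float) -> bool:
    """Band-dependent insufficient-reduction rule for residual DME."""
    if cmt_baseline_um <= 0 or cmt_post_um <= 0:
        raise InputError("CMT must be positive")
    reduction = (cmt_baseline_um - cmt_post_um) / cmt_baseline_um
    if cmt_baseline_um <= 400:
        thr = 0.10
    elif cmt_baseline_um <= 500:
        thr = 0.15
    elif cmt_baseline_um <= 600:
        thr = 0.20
    else:
        thr = 0.25
    return bool(reduction < thr)


def rdme_label(residual: bool, recurrence_within_6mo: bool) -> bool:
    return bool(residual or recurrence_within_6mo)


def dichotomize_bcva(logmar_6mo: float, threshold_logmar: float = POOR_VISION_LOGMAR) -> bool:
    """True (poor vision) iff logMAR >= threshold; boundary is poor."""
    if not np.isfinite(logmar_6mo):
        raise InputError("logMAR must be finite")
    return bool(logmar_6mo >= threshold_logmar)


# ------------------------------------------------------------------ regression

@dataclass
class RegressionRow:
    feature: str
    beta: float
    se: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    separation_flag: bool = False


@dataclass
class RegressionResult:
    stage: str                      # "univariate" | "multivariate"
    rows: list[RegressionRow] = field(default_factory=list)

    @property
    def retained_features(self) -> list[str]:
        return [r.feature for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows]).set_index("feature") \
            if self.rows else pd.DataFrame(
                columns=["beta", "se", "p", "odds_ratio", "ci_low", "ci_high",
                         "separation_flag"])


def _wald_row(name: str, beta: float, se: float, flagged: bool = False) -> RegressionRow:
    z = beta / se if se > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return RegressionRow(
        feature=name, beta=beta, se=se, p=float(p),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        separation_flag=flagged,
    )


def _fit_logit(x: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(x, has_constant="add"))
    return model.fit(disp=0, maxiter=200)


def univariate_logistic(feature: np.ndarray, outcome: np.ndarray,
                        name: str = "feature") -> RegressionRow:
    """Single-predictor ML logistic fit with Wald OR and 95% CI."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(feature, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InputError("outcome must be binary with both classes present")
    try:
        res = _fit_logit(x.reshape(-1, 1), y)
        beta, se = float(res.params[1]), float(res.bse[1])
        flagged = (not res.mle_retvals.get("converged", True)) or abs(beta) > 20 or se > 50
    except Exception:
        # perfect separation or non-convergence
        sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
        beta, se, flagged = float(sign * np.inf), float("inf"), True
    if flagged:
        log.warning("possible separation in univariate logistic for %s", name)
    return _wald_row(name, beta, se, flagged)


def backward_stepwise_logistic(table: pd.DataFrame, outcome: np.ndarray,
                               entry_p: float = 0.1,
                               stay_p: float = 0.05) -> RegressionResult:
    """Univariate entry screen (P < entry_p) then Wald backward elimination.

    At each step the largest-P predictor with P >= stay_p is removed;
    the final model retains only predictors with Wald P < stay_p.
    """
    y = np.asarray(outcome, dtype=float)
    entrants = []
    for col in table.columns:
        row = univariate_logistic(table[col].to_numpy(), y, col)
        if row.p < entry_p and not row.separation_flag:
            entrants.append(col)
    if not entrants:
        log.warning("no candidate passed the univariate entry criterion")
        return RegressionResult(stage="multivariate", rows=[])
    current = list(entrants)
    while current:
        x = table[current].to_numpy(dtype=float)
        try:
            res = _fit_logit(x, y)
        except Exception:
            # drop the most collinear/offending column and retry
            current.pop()
            continue
        pvals = {c: 2 * stats.norm.sf(abs(res.params[i + 1] / res.bse[i + 1]))
                 for i, c in enumerate(current)}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= stay_p and len(current) > 0:
            current.remove(worst)
            if not current:
                return RegressionResult(stage="multivariate", rows=[])
        else:
            rows = [_wald_row(c, float(res.params[i + 1]), float(res.bse[i + 1]))
                    for i, c in enumerate(current)]
            return RegressionResult(stage="multivariate", rows=rows)
    return RegressionResult(stage="multivariate", rows=[])


# ------------------------------------------------------------------ Table-1 stats

def dunn_posthoc(values: np.ndarray, groups: np.ndarray, p_adjust: str = "bonferroni"):
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N-1)).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    out = {}
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = math.sqrt(base_var * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        if p_adjust == "bonferroni":
            p = min(1.0, p * m)
        out[(a, b)] = {"z": float(z), "p": float(p)}
    return out


def odds_ratio_2x2(a: int, b: int, c: int, d: int):
    """Cross-product OR for a 2x2 table [[a, b], [c, d]] with Woolf 95% CI."""
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, (orr * math.exp(-1.96 * se), orr * math.exp(1.96 * se))


def compare_clusters(clinical: pd.DataFrame, labels: np.ndarray,
                     continuous: list[str] | None = None,
                     categorical: list[str] | None = None) -> pd.DataFrame:
    """Per-variable cluster comparison table.

    Continuous: Shapiro-Wilk, Kruskal-Wallis, Dunn pairwise
    (Bonferroni), median (IQR) per cluster. Categorical: chi-square,
    or Fisher exact for 2x2 tables with any expected cell < 5 (larger
    sparse tables keep chi-square and are flagged).
    """
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise InputError("need at least two clusters")
    if continuous is None:
        continuous = [c for c in clinical.columns
                      if pd.api.types.is_numeric_dtype(clinical[c])
                      and clinical[c].nunique() > 6]
    if categorical is None:
        categorical = [c for c in clinical.columns if c not in continuous]
    rows = []
    for col in continuous:
        v = clinical[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.any():
            log.warning("variable %s all-missing; skipped", col)
            continue
        v, g = v[ok], labels[ok]
        sw_p = float(stats.shapiro(v).pvalue) if 3 <= len(v) <= 5000 else np.nan
        samples = [v[g == k] for k in ks]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(v) == 0:
            kw_stat, kw_p = 0.0, 1.0
            dunn = {}
        else:
            kw_stat, kw_p = stats.kruskal(*samples)
            dunn = dunn_posthoc(v, g) if kw_p < 0.05 else {}
        summary = {f"cluster{k}": f"{np.median(s):.2f} ({np.percentile(s, 25):.2f}, "
                                  f"{np.percentile(s, 75):.2f})"
                   for k, s in zip(ks, samples)}
        rows.append({"variable": col, "type": "continuous", "test": "kruskal-wallis",
                     "statistic": float(kw_stat), "p": float(kw_p),
                     "shapiro_p": sw_p, "pairwise": dunn, **summary})
    for col in categorical:
        tab = pd.crosstab(clinical[col], labels)
        if tab.size == 0:
            continue
        obs = tab.to_numpy()
        chi2, chi_p, _, expected = stats.chi2_contingency(obs)
        small = bool((expected < 5).any())
        test, p, statv, flag = "chi-square", float(chi_p), float(chi2), ""
        if small and obs.shape == (2, 2):
            _, p = stats.fisher_exact(obs)
            test, statv = "fisher-exact", np.nan
        elif small:
            flag = "small_expected_cells"
        summary = {f"cluster{k}": "/".join(str(x) for x in tab[k])
                   for k in tab.columns}
        rows.append({"variable": col, "type": "categorical", "test": test,
                     "statistic": statv, "p": float(p), "shapiro_p": np.nan,
                     "pairwise": flag, **summary})
    return pd.DataFrame(rows).set_index("variable")


# ------------------------------------------------------------------ ICC

def icc_intra_rater(measurements_t1, measurements_t2):
    """Intra-rater ICC(3,1): two-way mixed effects, consistency, single measure.

    Accepts paired 1-D arrays or 2-D tables (subjects x features; each
    subject-feature pair is one target). Returns (icc, (lo, hi)).
    """
    import pingouin as pg

    a = np.asarray(measurements_t1, dtype=float).ravel()
    b = np.asarray(measurements_t2, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputError("paired measurement tables must match")
    if a.size < 3:
        raise InputError("need at least 3 paired measurements")
    long = pd.DataFrame({
        "target": np.tile(np.arange(a.size), 2),
        "rater": np.repeat(["t1", "t2"], a.size),
        "score": np.concatenate([a, b]),
    })
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate F on exact ties
        res = pg.intraclass_corr(long, targets="target", raters="rater",
                                 ratings="score")
    sel = res[res["Type"].isin(["ICC3", "ICC(C,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))
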