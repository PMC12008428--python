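"""Published reference-cohort outcome counts and the arithmetic on them.

The pipeline in this package re-implements the analysis of a published
two-center cohort of 234 anti-VEGF-treated DME eyes stratified into
four radiomic clusters. The cluster-by-outcome counts reported for that
cohort are embedded here as plain data so the cohort-level outcome
rates and the cluster-4-versus-rest odds ratio can be recomputed and
used as fixed points in tests; no patient-level data is included.
"""

from __future__ import annotations

from .outcomes import odds_ratio_2x2

CLUSTER_SIZES = {1: 122, 2: 45, 3: 32, 4: 35}
N_EYES = 234
N_PATIENTS = 131

# (yes, no) counts per cluster
RDME_COUNTS = {1: (72, 50), 2: (31, 14), 3: (19, 13), 4: (12, 23)}
POOR_VISION_COUNTS = {1: (70, 52), 2: (27, 18), 3: (21, 11), 4: (10, 25)}


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded to the two decimals the reference tables print."""
    return round(100.0 * numerator / denominator, 2)


def cohort_outcome_percentages() -> dict[str, float]:
    """Recompute every outcome rate from the embedded counts."""
    rdme_yes = sum(v[0] for v in RDME_COUNTS.values())
    poor_yes = sum(v[0] for v in POOR_VISION_COUNTS.values())
    out = {
        "overall_rdme_percent": percent(rdme_yes, N_EYES),
        "overall_poor_vision_percent": percent(poor_yes, N_EYES),
    }
    for k, (yes, no) in RDME_COUNTS.items():
        out[f"cluster{k}_rdme_percent"] = percent(yes, yes + no)
    for k, (yes, no) in POOR_VISION_COUNTS.items():
        out[f"cluster{k}_poor_vision_percent"] = percent(yes, yes + no)
        out[f"cluster{k}_good_vision_percent"] = percent(no, yes + no)
    return out


def cluster4_vs_rest_rdme_odds_ratio():
    """2x2 cross-product OR (cluster 4 vs clusters 1-3) with Woolf 95% CI."""
    a, b = RDME_COUNTS[4]                     # cluster 4: yes, no
    c = sum(RDME_COUNTS[k][0] for k in (1, 2, 3))
    d = sum(RDME_COUNTS[k][1] for k in (1, 2, 3))
    return odds_ratio_2x2(a, b, c, d)
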