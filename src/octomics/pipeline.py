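"""One-command pipeline: simulate/load -> extract -> reduce -> cluster ->
stability -> selection -> outcome models, with provenance and a report.

A single master seed deterministically derives every stage seed, so a
rerun with the same configuration reproduces all numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import consensus_select_k, elbow_select_k, hybrid_cluster
from .features import ExtractionConfig, extract_table
from .outcomes import backward_stepwise_logistic, compare_clusters, univariate_logistic
from .reduction import fit_pca, parallel_analysis, project, zscore_features
from .selection import select_features
from .stability import bootstrap_stability, noise_sensitivity
from .synthetic import SyntheticCohortConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study's defaults."""

    # simulation (used when simulate=True)
    simulate: bool = True
    cohort: SyntheticCohortConfig | None = None
    # extraction
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig.fast)
    # reduction
    n_perm: int = 1000
    pa_percentile: float = 95.0
    n_pcs_boot: int | None = None      # None -> use the parallel-analysis result
    # clustering
    k: int | None = None               # None -> auto (elbow + consensus must agree)
    k_range: tuple[int, int] = (2, 6)
    consensus_resamples: int = 100
    subsample_frac: float = 0.8
    # stability
    bootstrap_B: int = 500
    noise_sigma_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    noise_reps: int = 10
    noise_domain: str = "feature"
    # selection
    r_threshold: float = 0.8
    anova_alpha: float = 0.05
    anova_fdr: bool = False
    boruta_iter: int = 500
    rf_trees: int = 500
    # regression
    entry_p: float = 0.1
    stay_p: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        extraction = raw.pop("extraction", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = SyntheticCohortConfig(**cohort)
        if extraction:
            cfg.extraction = ExtractionConfig(**extraction)
        return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; persist CSV outputs + provenance under out_dir.

    Returns a summary dict (k chosen, ARI summary, confirmed features
    per outcome, regression tables).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    if not config.simulate:
        raise NotImplementedError("only simulated cohorts are wired into the runner; "
                                  "use the library functions for external data")
    cohort_cfg = config.cohort or SyntheticCohortConfig(seed=seeds[0])
    if config.cohort is None:
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=seeds[0])
    eyes = generate_cohort(cohort_cfg)
    from .synthetic import cohort_clinical_table
    clinical = cohort_clinical_table(eyes)
    clinical.to_csv(out / "clinical.csv")
    log.info("stage simulate: %d eyes in, %d out", cohort_cfg.n_eyes, len(eyes))

    features = extract_table(eyes, config.extraction)
    features.to_csv(out / "features.csv")
    log.info("stage extract: %d eyes x %d features", *features.shape)

    z = zscore_features(features)
    pa = parallel_analysis(z, n_perm=config.n_perm, percentile=config.pa_percentile,
                           seed=seeds[1])
    model = fit_pca(z)
    n_pcs = max(pa.n_retained, 2)
    scores = project(model, z, n_pcs)
    pd.DataFrame(scores, index=z.index,
                 columns=[f"PC{i+1}" for i in range(n_pcs)]).to_csv(out / "scores.csv")
    log.info("stage reduce: retained %d PCs (%.2f%% variance)", n_pcs,
             100 * model.explained_variance_fraction[:n_pcs].sum())

    if config.k is not None:
        k = config.k
        k_info = {"mode": "fixed"}
    else:
        k_elbow, elbow_info = elbow_select_k(scores, k_max=max(config.k_range[1] + 1, 4),
                                             seed=seeds[2])
        k_cons, curve = consensus_select_k(scores, range(config.k_range[0],
                                                         config.k_range[1] + 1),
                                           n_resamples=config.consensus_resamples,
                                           subsample_frac=config.subsample_frac,
                                           seed=seeds[2])
        if k_elbow != k_cons:
            log.warning("elbow (k=%d) and consensus (k=%d) disagree; using consensus",
                        k_elbow, k_cons)
        k = k_cons
        k_info = {"mode": "auto", "elbow": k_elbow, "consensus": k_cons,
                  "delta_area": curve.delta}
    assignment = hybrid_cluster(scores, k, seed=seeds[3])
    pd.DataFrame({"eye_id": z.index, "cluster": assignment.labels}).to_csv(
        out / "clusters.csv", index=False)

    n_pcs_boot = config.n_pcs_boot or n_pcs
    stab = bootstrap_stability(features, n_pcs=n_pcs_boot, k=k,
                               B=config.bootstrap_B, seed=seeds[4])
    noise = noise_sensitivity(z if config.noise_domain == "feature" else eyes,
                              config.noise_sigma_grid, reps=config.noise_reps,
                              domain=config.noise_domain, n_pcs=n_pcs_boot, k=k,
                              seed=seeds[4],
                              extraction_config=config.extraction)
    pd.DataFrame(noise, columns=["sigma", "mean_ari", "sd_ari"]).to_csv(
        out / "noise_curve.csv", index=False)

    summary = {
        "config_hash": _config_hash(config), "seed": config.seed,
        "version": __version__, "n_eyes": len(eyes),
        "n_features": features.shape[1], "n_pcs": n_pcs, "k": k, "k_info": k_info,
        "bootstrap_ari_mean": stab.mean, "bootstrap_ari_sd": stab.sd,
        "bootstrap_ari_ci": [stab.ci_low, stab.ci_high],
        "outcomes": {},
    }

    comparison = compare_clusters(
        clinical[["age", "dm_duration", "hba1c", "cmt_baseline_um",
                  "bcva_logmar_baseline", "sex", "dr_stage", "medication",
                  "rdme", "vision_poor"]],
        assignment.labels,
        continuous=["age", "dm_duration", "hba1c", "cmt_baseline_um",
                    "bcva_logmar_baseline"],
        categorical=["sex", "dr_stage", "medication", "rdme", "vision_poor"])
    comparison.drop(columns=["pairwise"]).to_csv(out / "table1_cluster_comparison.csv")

    for outcome in ("rdme", "vision_poor"):
        y = clinical[outcome].to_numpy()
        if len(np.unique(y)) < 2:
            log.warning("outcome %s is constant; skipping selection/regression", outcome)
            continue
        sel = select_features(features, assignment.labels, y,
                              r_threshold=config.r_threshold,
                              alpha=config.anova_alpha, fdr=config.anova_fdr,
                              boruta_iter=config.boruta_iter,
                              rf_trees=config.rf_trees, seed=seeds[5])
        candidates = sel.confirmed or sel.stage3.tentative
        uni_rows = [univariate_logistic(features[c].to_numpy(), y, c)
                    for c in candidates]
        multi = backward_stepwise_logistic(features[candidates], y,
                                           entry_p=config.entry_p,
                                           stay_p=config.stay_p) \
            if candidates else None
        pd.DataFrame([r.__dict__ for r in uni_rows]).to_csv(
            out / f"univariate_{outcome}.csv", index=False)
        if multi is not None:
            multi.to_frame().to_csv(out / f"multivariate_{outcome}.csv")
        summary["outcomes"][outcome] = {
            "stage1": len(sel.stage1_retained), "stage2": len(sel.stage2_retained),
            "confirmed": sel.confirmed,
            "final_model": multi.retained_features if multi is not None else [],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    _write_report(summary, out / "report.md")
    return summary


def _write_report(summary: dict, path) -> None:
    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{summary['config_hash']}` (seed {summary['seed']}, "
        f"octomics {summary['version']})",
        f"- cohort: {summary['n_eyes']} eyes, {summary['n_features']} features",
        f"- retained PCs: {summary['n_pcs']}; chosen k: {summary['k']} "
        f"({summary['k_info']})",
        f"- bootstrap ARI: {summary['bootstrap_ari_mean']:.3f} "
        f"± {summary['bootstrap_ari_sd']:.3f} "
        f"(95% CI {summary['bootstrap_ari_ci'][0]:.3f}–{summary['bootstrap_ari_ci'][1]:.3f})",
        "",
    ]
    for outcome, info in summary["outcomes"].items():
        lines.append(f"## Outcome: {outcome}")
        lines.append(f"- selection cascade: {info['stage1']} -> {info['stage2']} -> "
                     f"{len(info['confirmed'])} confirmed")
        lines.append(f"- confirmed: {', '.join(info['confirmed']) or '(none)'}")
        lines.append(f"- final model: {', '.join(info['final_model']) or '(empty)'}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
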