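#!/usr/bin/env python
"""Associate selected biomarkers with outcomes and build the cluster table.

Univariate logistic regression per confirmed biomarker, backward
stepwise multivariable model (entry P < 0.1, stay P < 0.05), and a
Table-1-style comparison of clinical variables across clusters
(Kruskal-Wallis/Dunn, chi-square/Fisher).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from octomics.outcomes import (
    backward_stepwise_logistic,
    compare_clusters,
    univariate_logistic,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = ROOT / "results" / "analysis"
    table = pd.read_csv(out / "features.csv", index_col=0)
    clinical = pd.read_csv(out / "clinical.csv", index_col=0).loc[table.index]
    clusters = pd.read_csv(out / "clusters.csv", index_col=0)["cluster"]
    with open(out / "selection.json") as fh:
        selection = json.load(fh)

    comparison = compare_clusters(
        clinical[["age", "dm_duration", "hba1c", "cmt_baseline_um",
                  "bcva_logmar_baseline", "sex", "dr_stage", "medication",
                  "rdme", "vision_poor"]],
        clusters.loc[table.index].to_numpy(),
        continuous=["age", "dm_duration", "hba1c", "cmt_baseline_um",
                    "bcva_logmar_baseline"],
        categorical=["sex", "dr_stage", "medication", "rdme", "vision_poor"])
    comparison.drop(columns=["pairwise"]).to_csv(out / "table1_clusters.csv")
    sig = comparison[comparison["p"] < 0.05].index.tolist()
    print(f"cluster comparison: {len(sig)} variables differ at P<0.05: {sig}")

    for outcome in ("rdme", "vision_poor"):
        cand = selection[outcome]["confirmed"] or selection[outcome]["tentative"]
        if not cand:
            print(f"{outcome}: no candidate biomarkers; skipping regression")
            continue
        y = clinical[outcome].to_numpy()
        uni = pd.DataFrame([univariate_logistic(table[c].to_numpy(), y, c).__dict__
                            for c in cand]).set_index("feature")
        uni.to_csv(out / f"univariate_{outcome}.csv")
        multi = backward_stepwise_logistic(table[cand], y)
        multi.to_frame().to_csv(out / f"multivariate_{outcome}.csv")
        print(f"{outcome}: {len(cand)} candidates -> final model "
              f"{multi.retained_features or '(empty)'}")
        for row in multi.rows:
            print(f"  {row.feature}: OR {row.odds_ratio:.2f} "
                  f"({row.ci_low:.2f}-{row.ci_high:.2f}), P = {row.p:.3g}")


if __name__ == "__main__":
    main()
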