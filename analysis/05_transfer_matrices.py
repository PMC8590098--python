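#!/usr/bin/env python
"""Cross-tissue and cross-age-bin clock transfer, concordance and overlap.

Trains one clock per tissue and per age bin (young 25-50, middle 50-75,
aged 75-100), evaluates every train/test pair (held-out on the diagonal),
and summarises how tissue-specific clocks generalise: coefficient
concordance over shared clock sites and exclusive locus-set overlaps.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import epiclock as ec
from epiclock.io import read_beta_matrix, read_sample_table

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = read_beta_matrix(BASE / "cohort" / "beta.tsv")
    samples = read_sample_table(BASE / "cohort" / "samples.tsv")
    out = BASE / "transfer"
    out.mkdir(parents=True, exist_ok=True)

    for grouping in ("tissue", "age_bin"):
        cm = ec.cross_group_matrix(
            matrix, samples, grouping, ec.TrainingConfig(seed=55, cv_folds=5)
        )
        table = cm.table("pearson_r")
        table.to_csv(out / f"cross_{grouping}_r.tsv", sep="\t")
        cm.table("rmse").to_csv(out / f"cross_{grouping}_rmse.tsv", sep="\t")
        diag = np.diag(table.to_numpy()).mean()
        off = table.to_numpy()[~np.eye(len(table), dtype=bool)].mean()
        print(f"cross-{grouping}: mean within-group r = {diag:.3f}, "
              f"mean transfer r = {off:.3f}")
        print(table.round(3).to_string())

        models = list(cm.models.values())
        conc = ec.coefficient_concordance(models, min_models_shared=2)
        conc.correlations.to_csv(out / f"concordance_{grouping}.tsv", sep="\t")
        overlaps = ec.overlap_counts(models)
        overlaps.to_csv(out / f"overlap_{grouping}.tsv", sep="\t", index=False)
        shared = overlaps.loc[overlaps["degree"] > 1, "count"].sum()
        total = overlaps["count"].sum()
        print(f"  {shared}/{total} clock loci shared by >1 group-specific clock\n")


if __name__ == "__main__":
    main()
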