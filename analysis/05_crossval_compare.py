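"""Compare the four classifiers (SVM, RF, ENET, PAM) across gene-subset
sizes under nested stratified cross-validation, and aggregate elastic-net
gene votes and summed coefficients.

Reads results/preproc and results/ranking; writes results/crossval/
{comparison.csv, comparison_summary.csv, importance.csv}.  Ranking is used
once, globally, matching the published two-step procedure; runtime-scaled
grids are noted in docs/methods.md.
"""

from pathlib import Path

import pandas as pd

from rficlass.crossval import ResamplingPlan, aggregate_gene_importance, compare_learners
from rficlass.learners import ENetLearner, NSCLearner, RFLearner, SVMLearner

IN_MATRIX = Path("results/preproc/adjusted_matrix.tsv")
IN_PHENO = Path("results/cohort/phenotypes.csv")
IN_RANKING = Path("results/ranking/ranking.csv")
OUT = Path("results/crossval")
SEED = 20240917


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    em = pd.read_csv(IN_MATRIX, sep="\t", index_col=0)
    y = pd.read_csv(IN_PHENO)["rfi_class"].to_numpy()
    ranking = pd.read_csv(IN_RANKING)

    learners = {
        "SVM": SVMLearner(exponents=range(-12, 13, 4)),
        "RF": RFLearner(n_estimators=300),
        "ENET": ENetLearner(alpha_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
                            n_lambda=12),
        "PAM": NSCLearner(),
    }
    plan = ResamplingPlan(outer_folds=10, inner_folds=5, repetitions=1,
                          seed=SEED)
    long_df, summary, reports = compare_learners(
        em, y, learners, (50, 75, 100, 125), plan, ranking=ranking
    )
    long_df.to_csv(OUT / "comparison.csv", index=False)
    summary.to_csv(OUT / "comparison_summary.csv", index=False)
    print("median AUROC by learner x subset size:")
    print(summary.pivot(index="learner", columns="subset_size",
                        values="median_auroc").round(3).to_string())

    importance = aggregate_gene_importance([r for r in reports
                                            if r.has_selection])
    importance.to_csv(OUT / "importance.csv", index=False)
    top = importance.head(10)
    print(f"\nvote ceiling {reports[0].max_votes} per report; "
          "top genes by cumulative votes:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
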