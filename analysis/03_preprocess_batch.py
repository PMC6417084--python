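"""Normalize counts (TMM + log2 CPM), detect the batch axis by PCA of the
500 most variable genes, and regress PC1 out of every gene.

Reads results/cohort/; writes results/preproc/{adjusted_matrix.tsv,
pca_association.csv} and prints the variance explained per component.
"""

from pathlib import Path

import pandas as pd

from rficlass.preprocess import (
    adjust_for_components,
    batch_association,
    normalize,
    run_pca,
    top_variable_genes,
)
from rficlass.simulate import CountMatrix

IN = Path("results/cohort")
OUT = Path("results/preproc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(IN / "counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(IN / "phenotypes.csv").rename(
        columns={"animal_id": "sample_id"}
    )
    cm = CountMatrix(counts=counts[meta["sample_id"]], meta=meta)

    em = normalize(cm)
    print(f"{em.shape[0]} genes kept after low-count filtering")
    pca = run_pca(em, top_variable_genes(em, 500))
    for i, v in enumerate(pca.var_explained[:4], start=1):
        print(f"PC{i}: {100 * v:.1f}% of variance")

    assoc = batch_association(pca, meta.set_index("sample_id")[
        ["sex", "protocol", "rfi_class"]], n_components=4)
    assoc.to_csv(OUT / "pca_association.csv", index=False)
    flagged = assoc[assoc.flagged]
    print("flagged component-covariate associations:")
    print(flagged[["component", "covariate", "kind", "statistic", "p"]]
          .to_string(index=False) if len(flagged) else "  none")

    adj = adjust_for_components(em, pca, which=(1,))
    adj.values.to_csv(OUT / "adjusted_matrix.tsv", sep="\t",
                      index_label="gene_id")
    print(f"wrote PC1-adjusted matrix to {OUT}/adjusted_matrix.tsv")


if __name__ == "__main__":
    main()
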