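"""Fit the within-sex RFI regression, contrast the high/low classes, and
report the least-squares means the phenotypic analysis is built on.

Reads results/cohort/phenotypes.csv; writes results/rfi/{phenotypes_rfi.csv,
contrast.json}.
"""

import json
from pathlib import Path

import pandas as pd

from rficlass.rfi import contrast_classes, fit_rfi

IN = Path("results/cohort/phenotypes.csv")
OUT = Path("results/rfi")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = pd.read_csv(IN)
    model = fit_rfi(pheno)
    model.table.to_csv(OUT / "phenotypes_rfi.csv", index=False)

    print("within-sex regression coefficients (kg/day per unit):")
    for sex, betas in model.betas.items():
        print(f"  {sex}: intercept {model.sex_intercepts[sex]:+.3f}, "
              + ", ".join(f"{k} {v:+.4f}" for k, v in betas.items()))

    contrast = contrast_classes(model.table)
    (OUT / "contrast.json").write_text(json.dumps(contrast.to_json_dict(),
                                                  indent=2))
    print("\nleast-squares means of RFI by class x sex:")
    print(contrast.lsmeans.to_string(index=False))
    print("\nhigh-minus-low differences (kg/day):")
    print(contrast.differences.to_string(index=False))
    print("\nF-tests:")
    print(contrast.anova.to_string())


if __name__ == "__main__":
    main()
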