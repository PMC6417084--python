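"""Residual feed intake (RFI): within-sex regression, class contrast, extremes.

RFI is the residual of daily feed intake regressed — separately within each
sex — on metabolic body weight (MBW), average daily gain (ADG) and backfat
gain (BFG):

    FI = S_sex + beta_MBW*MBW + beta_ADG*ADG + beta_BFG*BFG + RFI

Lower RFI means a more feed-efficient animal.  The feeding protocol is not a
term of the regression; it only defines the sex-by-protocol cells used when
selecting phenotypic extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from rficlass.errors import EstimabilityError, InfeasibleSelectionError, SingularFitError

COVARIATES = ("MBW", "ADG", "BFG")


@dataclass
class RFIModel:
    """Per-sex OLS fit of feed intake with residuals (= RFI) per animal."""

    sex_intercepts: dict
    betas: dict  # sex -> {covariate: coefficient}
    table: pd.DataFrame  # input table with the RFI column filled

    @property
    def residuals(self) -> pd.Series:
        return self.table["RFI"]


def _id_column(table: pd.DataFrame) -> str:
    for c in ("animal_id", "sample_id"):
        if c in table.columns:
            return c
    raise KeyError("phenotype table needs an 'animal_id' (or 'sample_id') column")


def fit_rfi(table: pd.DataFrame) -> RFIModel:
    """Fit the within-sex RFI regression and fill the RFI column.

    Equivalent to a single model with sex-specific intercepts and
    sex-by-covariate interactions, but fitted as two separate ordinary
    least-squares problems.
    """
    table = table.copy()
    cols = ["FI", *COVARIATES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"phenotype table lacks columns {missing}")
    vals = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("FI and covariates must be finite for all fitted rows")

    intercepts: dict = {}
    betas: dict = {}
    table["RFI"] = np.nan
    for sex, sub in table.groupby("sex"):
        if len(sub) < 5:
            raise ValueError(f"need >= 5 animals per sex, got {len(sub)} for sex={sex!r}")
        for cov in COVARIATES:
            if np.isclose(sub[cov].std(ddof=0), 0.0):
                raise SingularFitError(
                    f"covariate {cov!r} is constant within sex={sex!r}; fit is singular"
                )
        X = sm.add_constant(sub[list(COVARIATES)].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularFitError(f"rank-deficient design within sex={sex!r}")
        res = sm.OLS(sub["FI"].to_numpy(dtype=float), X).fit()
        intercepts[sex] = float(res.params[0])
        betas[sex] = dict(zip(COVARIATES, (float(b) for b in res.params[1:])))
        table.loc[sub.index, "RFI"] = res.resid
    return RFIModel(sex_intercepts=intercepts, betas=betas, table=table)


@dataclass
class ContrastReport:
    """Least-squares means of RFI per class x sex and the associated F-tests."""

    lsmeans: pd.DataFrame  # rfi_class, sex, mean, se, n
    differences: pd.DataFrame  # sex, diff (high - low), se
    anova: pd.DataFrame  # F-tests for class, sex, class x sex
    degenerate: bool = False  # saturated fit, zero residual df

    def to_json_dict(self) -> dict:
        return {
            "lsmeans": self.lsmeans.to_dict(orient="records"),
            "differences": self.differences.to_dict(orient="records"),
            "anova": self.anova.reset_index().to_dict(orient="records"),
            "degenerate": self.degenerate,
        }


def contrast_classes(table: pd.DataFrame) -> ContrastReport:
    """Contrast high vs low RFI classes with a class*sex linear model.

    Only rows labelled 'high' or 'low' enter the model.  Least-squares means
    equal cell means because the model is saturated in class and sex.
    """
    sub = table[table["rfi_class"].isin(["high", "low"])].copy()
    if sub["RFI"].isna().any():
        raise ValueError("RFI must be filled (run fit_rfi) before contrasting classes")
    cells = sub.groupby(["rfi_class", "sex"]).size()
    for cls in ("high", "low"):
        for sex in sub["sex"].unique():
            if (cls, sex) not in cells.index:
                raise EstimabilityError(f"empty class x sex cell: ({cls}, {sex})")

    fit = smf.ols("RFI ~ C(rfi_class) * C(sex)", data=sub).fit()
    df_resid = int(fit.df_resid)
    degenerate = df_resid == 0
    mse = float(fit.mse_resid) if not degenerate else 0.0

    rows, diffs = [], []
    for sex in sorted(sub["sex"].unique()):
        cell_stats = {}
        for cls in ("high", "low"):
            cell = sub[(sub["rfi_class"] == cls) & (sub["sex"] == sex)]["RFI"]
            n = len(cell)
            se = np.sqrt(mse / n) if not degenerate else 0.0
            cell_stats[cls] = (float(cell.mean()), n)
            rows.append(
                {"rfi_class": cls, "sex": sex, "mean": float(cell.mean()), "se": se, "n": n}
            )
        (m_hi, n_hi), (m_lo, n_lo) = cell_stats["high"], cell_stats["low"]
        se_diff = np.sqrt(mse * (1.0 / n_hi + 1.0 / n_lo)) if not degenerate else 0.0
        diffs.append({"sex": sex, "diff": m_hi - m_lo, "se": se_diff})

    if degenerate:
        anova = pd.DataFrame(
            index=["C(rfi_class)", "C(sex)", "C(rfi_class):C(sex)"],
            columns=["F", "PR(>F)"],
            dtype=float,
        )
    else:
        anova = anova_lm(fit, typ=2)
    return ContrastReport(
        lsmeans=pd.DataFrame(rows),
        differences=pd.DataFrame(diffs),
        anova=anova,
        degenerate=degenerate,
    )


def select_extremes(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Label the k lowest / k highest / k median-centered RFI animals per cell.

    Cells are sex x protocol combinations.  Within each cell, animals are
    ordered by RFI with ties broken by animal id; the first k become 'low',
    the last k 'high', and a k-wide block centered on the cell median becomes
    'mid'.  Everything else is 'unselected'.
    """
    if table["RFI"].isna().any():
        raise ValueError("RFI must be filled (run fit_rfi) before selecting extremes")
    idc = _id_column(table)
    out = table.copy()
    out["rfi_class"] = "unselected"
    for (sex, protocol), cell in table.groupby(["sex", "protocol"]):
        m = len(cell)
        if m < 3 * k:
            raise InfeasibleSelectionError(
                f"cell (sex={sex}, protocol={protocol}) has {m} animals, needs >= {3 * k}"
            )
        order = cell.sort_values(["RFI", idc], kind="mergesort")
        out.loc[order.index[:k], "rfi_class"] = "low"
        out.loc[order.index[m - k :], "rfi_class"] = "high"
        start = (m - k) // 2
        out.loc[order.index[start : start + k], "rfi_class"] = "mid"
    return out
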