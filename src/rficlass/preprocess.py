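"""Count normalization and PCA-based batch detection/removal.

Counts are normalized to log2(counts-per-million + 0.5), optionally with
trimmed-mean-of-M-values (TMM) scaling factors applied to the effective
library sizes (30% M-trim, 5% A-trim, inverse-variance weights, reference =
the library whose upper quartile is closest to the mean upper quartile).
Batch structure is detected by PCA of the most-variable genes; components
associated with known factors are regressed out of every gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rficlass.errors import SampleError
from rficlass.simulate import CountMatrix


# ---------------------------------------------------------------------------
# TMM scaling factors
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
    a_cutoff: float = -1e10,
) -> float:
    """TMM factor of one library against the reference library."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep2 = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not np.any(keep2):
        return 1.0
    if weighted:
        f = np.sum(log_r[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    else:
        f = np.mean(log_r[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, normalized to product 1."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    f75 = np.array(
        [np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair(mat[:, j], ref, lib[j], lib[ref_idx])
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    cm: CountMatrix,
    filter_min_total: int = 10,
    tmm: bool = True,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2(CPM + prior) matrix after low-count gene filtering.

    Genes with total count below ``filter_min_total`` are dropped.  With
    ``tmm=True`` the per-sample library sizes are multiplied by TMM scaling
    factors before computing counts-per-million.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (cm.counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = cm.counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero) > 0:
        raise SampleError(f"zero library size for sample(s): {list(zero.index)}")
    kept = cm.counts[cm.counts.sum(axis=1) >= filter_min_total]
    eff_lib = lib.astype(float)
    if tmm:
        eff_lib = eff_lib * tmm_factors(kept)
    cpm = kept.div(eff_lib, axis=1) * 1e6
    return np.log2(cpm + prior_count)


def top_variable_genes(em: pd.DataFrame, k: int = 500) -> pd.Index:
    """The k genes with largest per-gene variance; ties broken by gene id."""
    if k > em.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({em.shape[0]})")
    var = em.var(axis=1, ddof=1)
    # mergesort is stable, so pre-sorting by id makes ties id-ordered
    order = var.loc[sorted(var.index)].sort_values(ascending=False, kind="mergesort")
    return order.index[:k]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample-space PCA of a per-gene-centered expression submatrix."""

    components: np.ndarray  # (n_components, n_subset_genes) orthonormal loadings
    scores: pd.DataFrame  # samples x components, columns PC1, PC2, ...
    var_explained: np.ndarray  # fractions, non-increasing
    genes: pd.Index  # the gene subset the PCA was run on


def run_pca(em: pd.DataFrame, subset=None) -> PCAResult:
    """PCA of samples over a gene subset after per-gene centering (no scaling)."""
    if em.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if subset is None:
        subset = em.index
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("gene subset is empty")
    X = em.loc[subset].T.to_numpy(dtype=float)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    total = float((s**2).sum())
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        components=Vt,
        scores=pd.DataFrame(scores, index=em.columns, columns=cols),
        var_explained=var_explained,
        genes=subset,
    )


def batch_association(
    pca: PCAResult,
    covariates: pd.DataFrame,
    p_threshold: float = 0.05,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Associate each component with each covariate.

    Numeric covariates: Pearson correlation; categorical: one-way ANOVA R^2.
    A constant covariate yields an 'undefined' row instead of an exception.
    """
    if not covariates.index.equals(pca.scores.index):
        covariates = covariates.loc[pca.scores.index]
    k = n_components or pca.scores.shape[1]
    rows = []
    for pc in pca.scores.columns[:k]:
        sc = pca.scores[pc].to_numpy()
        for name in covariates.columns:
            cov = covariates[name]
            numeric = pd.api.types.is_numeric_dtype(cov)
            if cov.nunique(dropna=True) <= 1:
                rows.append(
                    {
                        "component": pc,
                        "covariate": name,
                        "kind": "undefined",
                        "statistic": np.nan,
                        "p": np.nan,
                        "flagged": False,
                    }
                )
                continue
            if numeric and cov.nunique() > 2:
                import warnings as _w

                with _w.catch_warnings():
                    # trailing components have ~zero variance; their
                    # correlations are reported as-is and never flagged
                    _w.simplefilter("ignore")
                    r, p = stats.pearsonr(sc, cov.to_numpy(dtype=float))
                stat, kind = r, "pearson_r"
            else:
                groups = [sc[(cov == level).to_numpy()] for level in cov.unique()]
                f, p = stats.f_oneway(*groups)
                gm = sc.mean()
                ss_between = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
                ss_total = float(((sc - gm) ** 2).sum())
                stat, kind = ss_between / ss_total, "anova_r2"
            rows.append(
                {
                    "component": pc,
                    "covariate": name,
                    "kind": kind,
                    "statistic": float(stat),
                    "p": float(p),
                    "flagged": bool(p < p_threshold),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AdjustedExpressionMatrix:
    """Expression residualized on selected principal-component scores."""

    values: pd.DataFrame  # genes x samples
    adjusted_for: list  # 1-based component indices


def adjust_for_components(
    em: pd.DataFrame, pca: PCAResult, which=(1,)
) -> AdjustedExpressionMatrix:
    """Replace each gene by its residual on the selected PC scores.

    ``which`` holds 1-based component indices (PC1 = 1).  The regression
    (with intercept) is applied to ALL genes, not only the PCA subset.
    """
    which = [int(w) for w in which]
    if len(which) == 0:
        raise ValueError("'which' must name at least one component")
    if min(which) < 1 or max(which) > pca.scores.shape[1]:
        raise ValueError(f"component indices {which} out of range")
    S = pca.scores.iloc[:, [w - 1 for w in which]].to_numpy()
    X = np.column_stack([np.ones(S.shape[0]), S])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("selected component scores are collinear")
    Y = em.T.to_numpy(dtype=float)  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    values = pd.DataFrame(resid.T, index=em.index, columns=em.columns)
    return AdjustedExpressionMatrix(values=values, adjusted_for=which)
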