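"""Nested stratified cross-validation with gene-importance aggregation.

The outer ten-fold loop estimates generalization; the inner ten-fold loop,
run only on each outer-training set, tunes hyperparameters by mean inner
AUROC.  The model is refit on the full outer-training set at the tuned values
and scored on the untouched outer-validation set.  Per-gene "votes" count the
fits in which a gene was selected (nonzero elastic-net coefficient or a
surviving shrunken-centroid offset); under the inner accounting a gene can be
selected at most repetitions x outer_folds x inner_folds times.  "sumbetas"
accumulates the signed coefficients (standardized-predictor scale) over the
same fits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from rficlass._seeds import stage_seed
from rficlass.learners import (
    ENetLearner,
    _binomial_deviance,
    _binomial_path,
    _lambda_path,
    _sigmoid,
    _Standardizer,
)
from rficlass.metrics import auroc, confusion_metrics, encode_labels
from rficlass.ranking import _as_xy


@dataclass(frozen=True)
class ResamplingPlan:
    outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2 or self.repetitions < 1:
            raise ValueError("folds must be >= 2 and repetitions >= 1")


def max_votes(plan: ResamplingPlan) -> int:
    """Maximum attainable per-gene vote count under the inner accounting."""
    return plan.repetitions * plan.outer_folds * plan.inner_folds


def stratified_folds(y, k: int, seed: int = 0) -> np.ndarray:
    """Fold id per sample; per-class counts differ by <= 1 across folds."""
    y = encode_labels(y)
    if int(np.bincount(y).min()) < k:
        raise ValueError(f"smallest class has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    folds = np.empty(len(y), dtype=int)
    for j, (_, test) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test] = j
    return folds


@dataclass
class NestedCVReport:
    learner: str
    plan: ResamplingPlan
    folds: pd.DataFrame  # rep, fold, params, auroc, accuracy, sensitivity, specificity
    gene_ids: pd.Index
    votes: pd.Series | None = None  # inner accounting (max reps*outer*inner)
    sumbetas: pd.Series | None = None
    votes_outer: pd.Series | None = None  # outer refits only (max reps*outer)
    sumbetas_outer: pd.Series | None = None

    @property
    def max_votes(self) -> int:
        return max_votes(self.plan)

    @property
    def has_selection(self) -> bool:
        return self.votes is not None

    def summary(self) -> dict:
        m = self.folds[["auroc", "accuracy", "sensitivity", "specificity"]]
        return {
            "learner": self.learner,
            "n_models": len(self.folds),
            **{f"mean_{c}": float(m[c].mean()) for c in m.columns},
            "median_auroc": float(m["auroc"].median()),
            "iqr_auroc": float(m["auroc"].quantile(0.75) - m["auroc"].quantile(0.25)),
        }


def _tune_generic(learner, X, y, inner_ids, grid, seed):
    """Grid search by mean inner-fold AUROC; ties keep the earlier grid entry."""
    if len(grid) == 1:
        return grid[0], float("nan")
    k = int(inner_ids.max()) + 1
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for j in range(k):
            tr, va = inner_ids != j, inner_ids == j
            model = learner.fit(X[tr], y[tr], params, seed=seed, final=False)
            scores.append(auroc(model.scores(X[va]), y[va]))
        mean_score = float(np.mean(scores))
        if mean_score > best_score + 1e-12:
            best_score, best_params = mean_score, params
    return best_params, best_score


def _collect_inner_votes(learner, X, y, inner_ids, params, seed, p):
    """Per-inner-fold selection snapshots at the tuned hyperparameters."""
    votes = np.zeros(p)
    sumb = np.zeros(p)
    any_sel = False
    for j in range(int(inner_ids.max()) + 1):
        tr = inner_ids != j
        model = learner.fit(X[tr], y[tr], params, seed=seed, final=False)
        sel = model.selected
        if sel is None:
            return None, None
        any_sel = True
        votes[sel] += 1
        coef = getattr(model, "coef_", None)
        if coef is not None:
            sumb[sel] += coef[sel]
    return (votes, sumb) if any_sel else (None, None)


def _enet_tune(learner: ENetLearner, X, y, inner_ids, seed):
    """Joint (alpha, lambda) tuning on the inner folds.

    For each alpha the lambda path is cross-validated on the inner folds and
    the one-standard-error rule picks lambda; alpha is then chosen by the
    cross-validated AUROC at its selected lambda.  Returns the tuned params
    and the per-inner-fold coefficient snapshots at the tuned values (the
    fits counted by the vote accounting).
    """
    k = int(inner_ids.max()) + 1
    scaler = _Standardizer().fit(X)
    Xs = scaler.transform(X)
    best = None  # (auroc, alpha, lam, fold_coefs)
    for alpha in learner.alpha_grid:
        lambdas = _lambda_path(Xs, y, alpha, learner.n_lambda,
                               learner.lambda_min_ratio)
        dev = np.zeros((k, len(lambdas)))
        auc = np.zeros((k, len(lambdas)))
        fold_fits = []
        for j in range(k):
            tr, va = inner_ids != j, inner_ids == j
            # looser solve for the tuning curves; the refit is done tightly
            coefs, icpts = _binomial_path(Xs[tr], y[tr], alpha, lambdas,
                                          tol=2e-5, max_iter=250)
            eta = Xs[va] @ coefs.T + icpts
            prob = _sigmoid(eta)
            for i in range(len(lambdas)):
                dev[j, i] = _binomial_deviance(prob[:, i], y[va])
                uniq = np.unique(y[va])
                auc[j, i] = auroc(prob[:, i], y[va]) if len(uniq) == 2 else np.nan
            fold_fits.append(coefs)
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(k)
        i_min = int(np.argmin(mean_dev))
        ok = np.flatnonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])
        i_sel = int(ok.min())  # most regularized within one SE
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_auc = float(np.nanmean(auc[:, i_sel]))
        if best is None or mean_auc > best[0] + 1e-12:
            best = (
                mean_auc,
                alpha,
                float(lambdas[i_sel]),
                [c[i_sel].copy() for c in fold_fits],
            )
    _, alpha, lam, fold_coefs = best
    votes = np.zeros(Xs.shape[1])
    sumb = np.zeros(Xs.shape[1])
    for coef in fold_coefs:
        nz = np.flatnonzero(coef != 0.0)
        votes[nz] += 1
        sumb[nz] += coef[nz]
    return {"alpha": alpha, "lam": lam}, votes, sumb


def compute_fold_rankings(X, y, plan: ResamplingPlan, forest_cfg) -> dict:
    """Leakage-safe rankings: one conditional-importance ranking per outer
    training set, shared by every learner/subset size run under ``plan``.

    Returns {(rep, fold): column positions ordered by decreasing importance}.
    """
    import dataclasses as _dc

    from rficlass.ranking import build_forest, conditional_importance

    Xm, gene_ids = _as_xy(X, y)
    yv = encode_labels(y)
    pos = {g: i for i, g in enumerate(gene_ids)}
    out = {}
    for rep in range(plan.repetitions):
        fold_ids = stratified_folds(yv, plan.outer_folds,
                                    seed=stage_seed(plan.seed, "folds", rep))
        for j in range(plan.outer_folds):
            tr = fold_ids != j
            fcfg = _dc.replace(
                forest_cfg, seed=stage_seed(forest_cfg.seed, "forest",
                                            rep * 1000 + j)
            )
            sub = pd.DataFrame(Xm[tr].T, index=gene_ids)
            forest = build_forest(sub, yv[tr], fcfg)
            ranked = conditional_importance(forest, sub, yv[tr])
            out[(rep, j)] = np.array([pos[g] for g in ranked["gene_id"]])
    return out


def nested_evaluate(
    learner,
    X,
    y,
    plan: ResamplingPlan,
    grid: list[dict] | None = None,
    threshold: float = 0.5,
    subset_k: int | None = None,
    fold_rankings: dict | None = None,
    outer_fold_ids: np.ndarray | None = None,
) -> NestedCVReport:
    """Run the nested loop for one learner.

    ``X`` may be a genes x samples DataFrame (or adjusted matrix) or a
    samples x features array.  Tuning sees only each outer-training set; the
    outer-validation set is untouched until metric computation.  With
    ``subset_k`` and ``fold_rankings`` (from :func:`compute_fold_rankings`),
    each outer fold restricts to the top-k genes of its own training-set
    ranking, keeping feature selection inside the training data.
    """
    Xm, gene_ids = _as_xy(X, y)
    yv = encode_labels(y)
    is_enet = isinstance(learner, ENetLearner)
    if grid is None and not is_enet:
        grid = learner.default_grid()
    if grid is not None and len(grid) == 0:
        raise ValueError("hyperparameter grid is empty")
    if subset_k is not None and fold_rankings is None:
        raise ValueError("subset_k requires fold_rankings")
    p = Xm.shape[1]

    rows = []
    votes = np.zeros(p)
    sumb = np.zeros(p)
    votes_outer = np.zeros(p)
    sumb_outer = np.zeros(p)
    selection_seen = False
    for rep in range(plan.repetitions):
        if outer_fold_ids is not None:
            fold_ids = np.asarray(outer_fold_ids)  # audit hook: fixed folds
        else:
            fold_ids = stratified_folds(yv, plan.outer_folds,
                                        seed=stage_seed(plan.seed, "folds", rep))
        for j in range(plan.outer_folds):
            te = fold_ids == j
            tr = ~te
            if subset_k is not None:
                cols = fold_rankings[(rep, j)][:subset_k]
            else:
                cols = np.arange(p)
            X_tr, y_tr = Xm[np.ix_(tr, cols)], yv[tr]
            inner_k = min(plan.inner_folds, int(np.bincount(y_tr).min()))
            if inner_k < plan.inner_folds:
                warnings.warn(
                    f"inner folds reduced to {inner_k} (small class)", stacklevel=2
                )
            inner_seed = stage_seed(plan.seed, "folds", rep * 1000 + j + 1)
            inner_ids = stratified_folds(y_tr, inner_k, seed=inner_seed)
            fit_seed = stage_seed(plan.seed, "learner", rep * 1000 + j)

            if is_enet:
                if grid is not None:
                    tuner = ENetLearner(
                        alpha_grid=[g["alpha"] for g in grid],
                        n_lambda=learner.n_lambda,
                        lambda_min_ratio=learner.lambda_min_ratio,
                    )
                else:
                    tuner = learner
                params, v, s = _enet_tune(tuner, X_tr, y_tr, inner_ids, fit_seed)
                votes[cols] += v
                sumb[cols] += s
                selection_seen = True
            else:
                params, _ = _tune_generic(learner, X_tr, y_tr, inner_ids, grid,
                                          fit_seed)
                if getattr(learner, "provides_selection", False):
                    v, s = _collect_inner_votes(
                        learner, X_tr, y_tr, inner_ids, params, fit_seed, len(cols)
                    )
                    if v is not None:
                        votes[cols] += v
                        sumb[cols] += s
                        selection_seen = True

            model = learner.fit(X_tr, y_tr, params, seed=fit_seed, final=True)
            sel = model.selected
            if sel is not None:
                votes_outer[cols[sel]] += 1
                coef = getattr(model, "coef_", None)
                if coef is not None:
                    sumb_outer[cols[sel]] += coef[sel]
            sc = model.scores(Xm[np.ix_(te, cols)])
            a = auroc(sc, yv[te])
            acc, sens, spec = confusion_metrics(sc, yv[te], threshold=threshold)
            rows.append(
                {
                    "rep": rep,
                    "fold": j,
                    "learner": learner.name,
                    "params": json.dumps(params, default=float, sort_keys=True),
                    "auroc": a,
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": spec,
                    "n_test": int(te.sum()),
                }
            )

    folds_df = pd.DataFrame(rows)
    kw: dict = {}
    if selection_seen:
        kw = dict(
            votes=pd.Series(votes, index=gene_ids, name="votes"),
            sumbetas=pd.Series(sumb, index=gene_ids, name="sumbetas"),
            votes_outer=pd.Series(votes_outer, index=gene_ids, name="votes_outer"),
            sumbetas_outer=pd.Series(sumb_outer, index=gene_ids,
                                     name="sumbetas_outer"),
        )
    return NestedCVReport(
        learner=learner.name, plan=plan, folds=folds_df, gene_ids=gene_ids, **kw
    )


def aggregate_gene_importance(reports) -> pd.DataFrame:
    """Sum votes and signed coefficients over a set of nested-CV reports."""
    reports = list(reports)
    with_sel = [r for r in reports if r.has_selection]
    if not with_sel:
        raise ValueError(
            "no report carries selection information (e.g. run the elastic net)"
        )
    gene_ids = with_sel[0].gene_ids
    votes = sum(r.votes.reindex(gene_ids, fill_value=0) for r in with_sel)
    sumb = sum(r.sumbetas.reindex(gene_ids, fill_value=0) for r in with_sel)
    out = pd.DataFrame({"gene_id": gene_ids, "votes": votes.to_numpy(),
                        "sumbetas": sumb.to_numpy()})
    return out.sort_values(["votes", "gene_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def compare_learners(
    X,
    y,
    learners: dict,
    subset_sizes,
    plan: ResamplingPlan,
    ranking: pd.DataFrame | None = None,
    rank_scope: str = "global",
    forest_cfg=None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[NestedCVReport]]:
    """Long-format learner x subset-size comparison table plus summaries.

    ``ranking`` is a (gene_id, score, rank) DataFrame used when
    ``rank_scope='global'`` (rank once on all data, as published); with
    ``rank_scope='outer'`` a fresh ranking is computed inside every outer
    training set instead (leakage-safe).  Subset size 0 or None means "all
    genes".  Returns (long table, summary with median/IQR AUROC, reports).
    """
    Xm, gene_ids = _as_xy(X, y)
    id_pos = {g: i for i, g in enumerate(gene_ids)}
    fold_rankings = None
    if rank_scope == "outer":
        if forest_cfg is None:
            raise ValueError("rank_scope='outer' requires forest_cfg")
        fold_rankings = compute_fold_rankings(X, y, plan, forest_cfg)
    elif rank_scope != "global":
        raise ValueError("rank_scope must be 'global' or 'outer'")

    long_rows, summaries, reports = [], [], []
    for name, learner in learners.items():
        for k in subset_sizes:
            if k and rank_scope == "outer":
                rep = nested_evaluate(learner, X, y, plan, subset_k=k,
                                      fold_rankings=fold_rankings)
            elif k:
                if ranking is None:
                    raise ValueError("a ranking is required for gene subsets")
                cols = [id_pos[g] for g in ranking["gene_id"].iloc[:k]]
                ids_sub = pd.Index(ranking["gene_id"].iloc[:k])
                rep = nested_evaluate(
                    learner, pd.DataFrame(Xm[:, cols].T, index=ids_sub), y, plan
                )
            else:
                rep = nested_evaluate(learner, X, y, plan)
            df = rep.folds.copy()
            df["subset_size"] = k if k else len(gene_ids)
            long_rows.append(df)
            s = rep.summary()
            s["subset_size"] = k if k else len(gene_ids)
            summaries.append(s)
            reports.append(rep)
    return pd.concat(long_rows, ignore_index=True), pd.DataFrame(summaries), reports
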