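"""Gene ranking by conditional permutation importance in a subsampling forest.

Each tree is a Gini CART tree grown on a without-replacement subsample of the
animals (default fraction 0.632) with ``mtry`` candidate features per split;
``mtry`` is chosen from a grid by out-of-sample (OOB) accuracy.  Importance of
a gene is the mean, over trees, of the OOB accuracy drop when the gene's
values are permuted — not freely, but within strata defined by the tree's
split intervals on the gene's correlated predictors (|Pearson r| above a
threshold, default 0.2).  Permuting within those strata preserves the joint
pattern with correlated genes and isolates a gene's own contribution, which
is the point of the conditional variant for strongly co-expressed predictors.

Genes that no tree splits on receive importance exactly 0: permuting a
variable a tree never consulted cannot change its predictions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from rficlass._seeds import stage_rng
from rficlass.metrics import encode_labels


def default_mtry_grid(p: int) -> list[int]:
    """Grid from 5 to floor(sqrt(p)), step max(1, floor((sqrt(p)-5)/5))."""
    hi = max(1, int(math.isqrt(p)))
    lo = 5
    if lo > hi:
        warnings.warn(
            f"mtry grid clipped: floor(sqrt(p))={hi} < 5 for p={p}", stacklevel=2
        )
        return [hi]
    step = max(1, (hi - lo) // 5)
    grid = list(range(lo, hi + 1, step))
    if grid[-1] != hi:
        grid.append(hi)
    return grid


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 1000
    mtry_grid: tuple[int, ...] | None = None  # default: 5 .. floor(sqrt(p))
    subsample_fraction: float = 0.632
    conditioning_corr_threshold: float = 0.2
    n_tune_trees: int = 100  # trees per grid value while tuning mtry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 0.0 <= self.conditioning_corr_threshold <= 1.0:
            raise ValueError("conditioning_corr_threshold must lie in [0, 1]")


@dataclass
class Forest:
    trees: list
    oob_indices: list
    mtry: int
    feature_ids: pd.Index
    oob_accuracy_: float
    mtry_scores: dict = field(default_factory=dict)
    config: ForestConfig | None = None


def _as_xy(X, y):
    """Accept genes x samples DataFrame (or adjusted matrix) or samples x features."""
    ids = None
    if hasattr(X, "values") and hasattr(X, "adjusted_for"):  # AdjustedExpressionMatrix
        X = X.values
    if isinstance(X, pd.DataFrame):
        # genes x samples orientation if the row count matches the label count
        if X.shape[1] == len(y):
            ids = X.index
            mat = X.T.to_numpy(dtype=np.float64)
        else:
            ids = X.columns
            mat = X.to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(X, dtype=np.float64)
        ids = pd.Index([f"f{i}" for i in range(mat.shape[1])])
    return mat, pd.Index(ids)


def _grow_trees(X, y, mtry, n_trees, subsample_fraction, seed_seq):
    n = X.shape[0]
    m = max(2, int(round(subsample_fraction * n)))
    trees, oobs = [], []
    all_idx = np.arange(n)
    for child in seed_seq.spawn(n_trees):
        rng = np.random.default_rng(child)
        idx = rng.choice(n, size=m, replace=False)
        tree_seed = int(child.generate_state(1)[0] % (2**31))
        clf = DecisionTreeClassifier(
            criterion="gini", max_features=mtry, random_state=tree_seed
        )
        clf.fit(X[idx], y[idx])
        trees.append(clf)
        oobs.append(np.setdiff1d(all_idx, idx, assume_unique=False))
    return trees, oobs


def _oob_accuracy(trees, oobs, X, y) -> float:
    votes = np.zeros((X.shape[0], 2))
    for tree, oob in zip(trees, oobs):
        if len(oob) == 0:
            continue
        pred = tree.predict(X[oob]).astype(int)
        votes[oob, pred] += 1
    seen = votes.sum(axis=1) > 0
    if not seen.any():
        return float("nan")
    pred = (votes[seen, 1] > votes[seen, 0]).astype(int)
    ties = votes[seen, 1] == votes[seen, 0]
    correct = (pred == y[seen]) & ~ties
    # ties count half, matching the convention used for AUROC
    return float((correct.sum() + 0.5 * ties.sum()) / seen.sum())


def build_forest(X, y, cfg: ForestConfig | None = None) -> Forest:
    """Grow the subsampling forest, tuning mtry by OOB accuracy."""
    cfg = cfg or ForestConfig()
    Xm, ids = _as_xy(X, y)
    yv = encode_labels(y)
    n, p = Xm.shape
    if len(np.unique(yv)) != 2 or min(np.bincount(yv)) < 2:
        raise ValueError("need two classes with at least 2 samples each")

    grid = list(cfg.mtry_grid) if cfg.mtry_grid else default_mtry_grid(p)
    clipped = [min(m, p) for m in grid]
    if clipped != grid:
        warnings.warn(f"mtry grid clipped to p={p}", stacklevel=2)
    grid = sorted(set(clipped))

    best_mtry, best_acc, scores = grid[0], -np.inf, {}
    if len(grid) > 1:
        for mtry in grid:
            ss = np.random.SeedSequence(cfg.seed, spawn_key=(100, mtry))
            trees, oobs = _grow_trees(
                Xm, yv, mtry, min(cfg.n_tune_trees, cfg.n_trees),
                cfg.subsample_fraction, ss,
            )
            acc = _oob_accuracy(trees, oobs, Xm, yv)
            scores[mtry] = acc
            if acc > best_acc + 1e-12:
                best_acc, best_mtry = acc, mtry
    else:
        best_mtry = grid[0]

    ss = np.random.SeedSequence(cfg.seed, spawn_key=(200,))
    trees, oobs = _grow_trees(
        Xm, yv, best_mtry, cfg.n_trees, cfg.subsample_fraction, ss
    )
    return Forest(
        trees=trees,
        oob_indices=oobs,
        mtry=best_mtry,
        feature_ids=ids,
        oob_accuracy_=_oob_accuracy(trees, oobs, Xm, yv),
        mtry_scores=scores,
        config=cfg,
    )


def _strata_keys(X_oob: np.ndarray, cond_vars, cuts_by_var) -> np.ndarray:
    """Stratum id per OOB row from the tree's split intervals on cond_vars."""
    n = X_oob.shape[0]
    if not cond_vars:
        return np.zeros(n, dtype=int)
    codes = np.zeros(n, dtype=np.int64)
    for v in cond_vars:
        bins = np.searchsorted(cuts_by_var[v], X_oob[:, v], side="right")
        codes = codes * (len(cuts_by_var[v]) + 1) + bins
    _, keys = np.unique(codes, return_inverse=True)
    return keys


def _within_stratum_permutations(values: np.ndarray, keys: np.ndarray):
    """All joint permutations of `values` permuting only within strata."""
    groups = [np.flatnonzero(keys == k) for k in np.unique(keys)]
    per_group = [list(itertools.permutations(g)) for g in groups]
    for combo in itertools.product(*per_group):
        out = values.copy()
        for g, perm in zip(groups, combo):
            out[g] = values[list(perm)]
        yield out


def conditional_importance(
    forest: Forest,
    X,
    y,
    n_permutations: int = 1,
    exact: bool = False,
    exact_limit: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank genes by conditional permutation importance.

    Returns a DataFrame (gene_id, score, rank) ordered by non-increasing
    score with ties broken by gene id.  ``exact=True`` averages over every
    within-stratum permutation (only feasible on tiny strata) instead of
    Monte-Carlo draws; it exists for verification against enumeration.
    """
    Xm, ids = _as_xy(X, y)
    yv = encode_labels(y)
    if not ids.equals(forest.feature_ids):
        raise ValueError("features do not match those the forest was built on")
    n, p = Xm.shape
    thr = forest.config.conditioning_corr_threshold if forest.config else 0.2
    base_seed = forest.config.seed if forest.config else 0
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else stage_rng(base_seed, "permutation")
    )

    mean = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xm - mean) / sd  # for on-demand correlations

    drops = np.zeros(p)
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if len(oob) == 0:
            continue
        t = tree.tree_
        used = np.unique(t.feature[t.feature >= 0])
        if len(used) == 0:
            continue
        X_oob = Xm[oob].copy()
        y_oob = yv[oob]
        acc_before = float((tree.predict(X_oob).astype(int) == y_oob).mean())
        cuts_by_var = {
            int(v): np.sort(t.threshold[t.feature == v]) for v in used
        }
        for g in used:
            g = int(g)
            others = [int(v) for v in used if v != g]
            if others:
                corr = Xs[:, others].T @ Xs[:, g] / n
                cond_vars = [v for v, r in zip(others, corr) if abs(r) > thr]
            else:
                cond_vars = []
            # empty conditioning set -> unconditional permutation (one stratum)
            keys = _strata_keys(X_oob, cond_vars, cuts_by_var)
            original = X_oob[:, g].copy()
            if exact:
                sizes = np.bincount(keys)
                total = np.prod([math.factorial(int(s)) for s in sizes])
                if total > exact_limit:
                    raise ValueError(
                        f"exact enumeration needs {total} permutations > {exact_limit}"
                    )
                accs = []
                for perm_vals in _within_stratum_permutations(original, keys):
                    X_oob[:, g] = perm_vals
                    accs.append(
                        float((tree.predict(X_oob).astype(int) == y_oob).mean())
                    )
                acc_after = float(np.mean(accs))
            else:
                accs = []
                for _ in range(n_permutations):
                    permuted = original.copy()
                    for k in np.unique(keys):
                        pos = np.flatnonzero(keys == k)
                        if len(pos) > 1:
                            permuted[pos] = original[pos[rng.permutation(len(pos))]]
                    X_oob[:, g] = permuted
                    accs.append(
                        float((tree.predict(X_oob).astype(int) == y_oob).mean())
                    )
                acc_after = float(np.mean(accs))
            X_oob[:, g] = original
            drops[g] += acc_before - acc_after

    scores = drops / len(forest.trees)
    out = pd.DataFrame({"gene_id": ids, "score": scores})
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, p + 1)
    return out


def top_k(ranked: pd.DataFrame, k: int) -> list[str]:
    """First k gene ids of a ranking (supports the 50..400 subset grid)."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the number of ranked genes ({len(ranked)})")
    return list(ranked["gene_id"].iloc[:k])
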