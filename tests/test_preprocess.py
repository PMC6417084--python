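"""Normalization, TMM factors, PCA batch detection and PC adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rficlass.errors import SampleError
from rficlass.preprocess import (
    adjust_for_components,
    batch_association,
    normalize,
    run_pca,
    tmm_factors,
    top_variable_genes,
)
from rficlass.simulate import CountMatrix, SimConfig, generate_counts


def _cm(counts: np.ndarray) -> CountMatrix:
    df = pd.DataFrame(
        counts,
        index=[f"G{i}" for i in range(counts.shape[0])],
        columns=[f"S{j}" for j in range(counts.shape[1])],
    )
    return CountMatrix(counts=df, meta=pd.DataFrame({"sample_id": df.columns}))


# ---------------------------------------------------------------------------
# normalization / TMM
# ---------------------------------------------------------------------------

def test_identical_columns_give_unit_factors_and_equal_columns():
    cm = _cm(np.tile([[10], [40], [100], [7], [0]], (1, 2)))
    f = tmm_factors(cm.counts)
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0], atol=1e-12)
    em = normalize(cm, filter_min_total=0)
    np.testing.assert_allclose(em["S0"], em["S1"], atol=1e-12)


def test_cpm_removes_depth_for_proportional_columns():
    counts = np.array([[10, 20], [90, 180]])
    em = normalize(_cm(counts), filter_min_total=0, tmm=False)
    np.testing.assert_allclose(em["S0"], em["S1"], atol=1e-12)


def _tmm_oracle(counts: pd.DataFrame) -> np.ndarray:
    """Independent recoding of the trimmed-mean-of-M-values factors."""
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    out = []
    for j in range(mat.shape[1]):
        obs, ref = mat[:, j], mat[:, ref_j]
        ok = (obs > 0) & (ref > 0)
        o, r = obs[ok], ref[ok]
        m = np.log2((o / lib[j]) / (r / lib[ref_j]))
        a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref_j]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref_j] - r) / (lib[ref_j] * r)
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            out.append(1.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        out.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    out = np.array(out)
    return out / np.exp(np.mean(np.log(out)))


def test_tmm_matches_independent_recoding():
    rng = np.random.default_rng(4)
    counts = rng.negative_binomial(5, 0.01, size=(200, 6)).astype(float)
    counts[:, 2] *= 3  # depth difference
    counts[:50, 3] *= 5  # composition difference
    df = pd.DataFrame(counts, index=[f"G{i}" for i in range(200)],
                      columns=[f"S{j}" for j in range(6)])
    np.testing.assert_allclose(tmm_factors(df).to_numpy(), _tmm_oracle(df),
                               atol=1e-8)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_tmm_matches_edger(tmp_path):
    """Cross-check the scaling factors against edgeR's calcNormFactors."""
    rng = np.random.default_rng(9)
    counts = rng.negative_binomial(4, 0.02, size=(300, 5)).astype(int)
    counts[:60, 1] *= 4
    df = pd.DataFrame(counts, index=[f"G{i}" for i in range(300)],
                      columns=[f"S{j}" for j in range(5)])
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t")
    script = tmp_path / "tmm.R"
    script.write_text(
        'x <- as.matrix(read.delim("%s", row.names=1))\n'
        "suppressMessages(library(edgeR))\n"
        "f <- calcNormFactors(x, method='TMM')\n"
        'cat(sprintf("%%.10f", f), sep="\\n")\n' % path
    )
    res = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    expected = np.array([float(v) for v in res.stdout.strip().splitlines()])
    np.testing.assert_allclose(tmm_factors(df).to_numpy(), expected, atol=1e-6)


def test_low_count_filter_and_zero_library_error():
    counts = np.array([[0, 1], [50, 60], [3, 2]])
    em = normalize(_cm(counts), filter_min_total=5, tmm=False)
    assert list(em.index) == ["G1", "G2"]
    with pytest.raises(SampleError, match="S1"):
        normalize(_cm(np.array([[3, 0], [4, 0]])), filter_min_total=0)


# ---------------------------------------------------------------------------
# top variable genes
# ---------------------------------------------------------------------------

def test_top_variable_genes_excludes_constant_and_orders():
    em = pd.DataFrame(
        {
            "S0": [1.0, 5.0, 2.0, 7.0],
            "S1": [1.0, 9.0, 2.5, 1.0],
            "S2": [1.0, 1.0, 3.0, 4.0],
        },
        index=["flat", "big", "small", "mid"],
    )
    top = top_variable_genes(em, k=3)
    assert "flat" not in top
    assert list(top) == ["big", "mid", "small"]


def test_top_variable_genes_matches_sort_oracle():
    rng = np.random.default_rng(0)
    em = pd.DataFrame(rng.normal(size=(100, 20)),
                      index=[f"G{i:03d}" for i in range(100)])
    got = list(top_variable_genes(em, k=17))
    var = em.var(axis=1)
    expected = [g for _, g in sorted(zip(-var, var.index))][:17]
    assert got == expected


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_data():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    em = pd.DataFrame(np.outer([2.0, -1.0, 0.5], t) + 5.0,
                      index=list("abc"), columns=list("wxyz"))
    pca = run_pca(em)
    assert pca.var_explained[0] == pytest.approx(1.0)
    assert np.all(pca.var_explained[1:] < 1e-12)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(2)
    em = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
    pca = run_pca(em)
    X = em.T.to_numpy() - em.T.to_numpy().mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
    np.testing.assert_allclose(pca.var_explained[: len(evals)],
                               evals / evals.sum(), atol=1e-8)
    # orthonormal loadings
    G = pca.components @ pca.components.T
    np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)


def test_pca_duplicating_samples_keeps_fractions():
    rng = np.random.default_rng(3)
    em = pd.DataFrame(rng.normal(size=(10, 8)))
    em2 = pd.concat([em, em.add_suffix("_dup", axis=1)], axis=1)
    a, b = run_pca(em), run_pca(em2)
    k = min(len(a.var_explained), len(b.var_explained))
    np.testing.assert_allclose(a.var_explained[: k - 1], b.var_explained[: k - 1],
                               atol=1e-8)


# ---------------------------------------------------------------------------
# batch association
# ---------------------------------------------------------------------------

def test_association_with_own_scores_is_perfect():
    rng = np.random.default_rng(5)
    em = pd.DataFrame(rng.normal(size=(30, 12)))
    pca = run_pca(em)
    covs = pd.DataFrame({"x": pca.scores["PC2"], "const": 1.0},
                        index=pca.scores.index)
    rep = batch_association(pca, covs)
    row = rep[(rep.component == "PC2") & (rep.covariate == "x")].iloc[0]
    assert row["statistic"] == pytest.approx(1.0)
    const_rows = rep[rep.covariate == "const"]
    assert (const_rows["kind"] == "undefined").all()
    assert not const_rows["flagged"].any()


def test_sex_flagged_on_batch_component_and_null_near_nominal():
    """With a strongly sex-correlated batch axis the leading component is
    flagged for sex in nearly every simulation, while an independent random
    covariate is flagged at about the nominal 5% rate."""
    sex_hits, null_hits = 0, 0
    n_seeds = 60
    rng = np.random.default_rng(99)
    for seed in range(n_seeds):
        cfg = SimConfig(n_samples=40, n_genes=400, class_balance=(20, 20),
                        n_signal_genes=0, signal_logfc=0.0,
                        batch_variance_frac=0.3, sex_batch_corr=0.9, seed=seed)
        cm = generate_counts(cfg)
        em = normalize(cm, tmm=False)
        pca = run_pca(em, top_variable_genes(em, 200))
        covs = pd.DataFrame(
            {"sex": cm.meta["sex"].to_numpy(),
             "noise": rng.normal(size=40)},
            index=pca.scores.index,
        )
        rep = batch_association(pca, covs, n_components=1)
        sex_hits += int(rep[(rep.covariate == "sex")]["flagged"].iloc[0])
        null_hits += int(rep[(rep.covariate == "noise")]["flagged"].iloc[0])
    assert sex_hits / n_seeds >= 0.95
    assert null_hits / n_seeds <= 0.15  # ~5% nominal, binomial slack


# ---------------------------------------------------------------------------
# PC adjustment
# ---------------------------------------------------------------------------

def test_adjustment_orthogonalizes_all_genes():
    rng = np.random.default_rng(7)
    em = pd.DataFrame(rng.normal(size=(50, 20)))
    pca = run_pca(em, em.index[:30])
    adj = adjust_for_components(em, pca, which=(1,))
    pc1 = pca.scores["PC1"].to_numpy()
    pc1 = pc1 - pc1.mean()
    for g in range(50):
        v = adj.values.iloc[g].to_numpy()
        corr = abs(v @ pc1) / (np.linalg.norm(v) * np.linalg.norm(pc1) + 1e-30)
        assert corr < 1e-10


def test_gene_equal_to_pc1_vanishes_and_oracle_matches():
    rng = np.random.default_rng(8)
    em = pd.DataFrame(rng.normal(size=(20, 15)))
    pca = run_pca(em)
    em.iloc[0] = 3.0 * pca.scores["PC1"].to_numpy() + 1.0
    pca = run_pca(em)  # recompute with the planted gene
    adj = adjust_for_components(em, pca, which=(1,))
    s = pca.scores["PC1"].to_numpy()
    X = np.column_stack([np.ones(15), s])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    for g in range(20):
        yv = em.iloc[g].to_numpy()
        np.testing.assert_allclose(adj.values.iloc[g].to_numpy(), yv - H @ yv,
                                   atol=1e-10)


def test_adjustment_idempotent():
    rng = np.random.default_rng(9)
    em = pd.DataFrame(rng.normal(size=(30, 12)))
    pca = run_pca(em)
    once = adjust_for_components(em, pca, which=(1, 2)).values
    twice = adjust_for_components(once, pca, which=(1, 2)).values
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)


def test_depth_doubling_barely_moves_pca_scores():
    cfg = SimConfig(n_samples=20, n_genes=300, class_balance=(10, 10),
                    n_signal_genes=0, batch_variance_frac=0.0, seed=12)
    cm = generate_counts(cfg)
    doubled = CountMatrix(counts=cm.counts.copy(), meta=cm.meta)
    doubled.counts.iloc[:, 0] *= 2
    a = run_pca(normalize(cm, tmm=False))
    b = run_pca(normalize(doubled, tmm=False))
    # doubling counts doubles the library size too, so CPM is unchanged
    for i in range(3):
        sa, sb = a.scores.iloc[:, i], b.scores.iloc[:, i]
        if np.corrcoef(sa, sb)[0, 1] < 0:
            sb = -sb
        assert np.max(np.abs(sa - sb)) / (np.std(sa) + 1e-30) < 0.01
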