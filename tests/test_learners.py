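"""Closed-form, oracle and contract tests for the four classifiers."""

import numpy as np
import pytest
import statsmodels.api as sm

from rficlass.learners import (
    ENetConfig,
    ENetLearner,
    NSCConfig,
    NSCLearner,
    RFLearner,
    SVMConfig,
    SVMLearner,
    _fit_binomial,
    _fit_binomial_saga,
    fit_enet,
    fit_nsc,
    fit_rf,
    fit_svm,
)


@pytest.fixture(scope="module")
def orthonormal_design():
    rng = np.random.default_rng(0)
    n, p = 40, 5
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    beta = np.array([2.0, -1.5, 1.0, 0.5, -0.25])
    y = Q @ beta + 0.1 * rng.standard_normal(n)
    return Q, y, Q.T @ y  # design, response, OLS coefficients


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def test_enet_alpha_one_is_ridge_closed_form(orthonormal_design):
    """alpha=1 must be ridge: on an orthonormal design the solution is the
    OLS coefficient shrunk by 1/(1 + 2 n lambda)."""
    Q, y, b_ols = orthonormal_design
    n, lam = len(y), 0.01
    m = fit_enet(Q, y, ENetConfig(alpha=1.0, lam=lam, family="gaussian",
                                  standardize=False))
    np.testing.assert_allclose(m.coef_, b_ols / (1 + 2 * n * lam), atol=1e-6)


def test_enet_alpha_zero_is_lasso_soft_threshold(orthonormal_design):
    Q, y, b_ols = orthonormal_design
    n, lam = len(y), 0.01
    m = fit_enet(Q, y, ENetConfig(alpha=0.0, lam=lam, family="gaussian",
                                  standardize=False))
    expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - n * lam, 0.0)
    np.testing.assert_allclose(m.coef_, expected, atol=1e-6)


def test_enet_lambda_zero_matches_unpenalized_logistic():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((80, 3))
    eta = X @ np.array([1.0, -0.5, 0.25]) + 0.2
    y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(int)
    m = fit_enet(X, y, ENetConfig(alpha=0.5, lam=0.0, standardize=False))
    oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(np.r_[m.intercept_, m.coef_], oracle.params,
                               atol=1e-4)


@pytest.mark.parametrize("alpha", [0.0, 0.35, 0.85])
def test_fista_agrees_with_saga_route(alpha):
    """The proximal-gradient solver and scikit-learn's saga minimize the
    same objective; their solutions agree at a moderate lambda."""
    rng = np.random.default_rng(2)
    n, p = 50, 60
    X = rng.standard_normal((n, p))
    y = np.array([0.0, 1.0] * 25)
    X[y == 1, :5] += 1.0
    X = (X - X.mean(0)) / X.std(0)
    lam = 0.02
    b1, i1 = _fit_binomial(X, y, alpha, lam)
    b2, i2 = _fit_binomial_saga(X, y, alpha, lam)
    np.testing.assert_allclose(b1, b2, atol=5e-4)
    assert i1 == pytest.approx(i2, abs=5e-4)


def test_lasso_selection_monotone_in_lambda_orthonormal():
    # soft-thresholding makes the selected count non-increasing in lambda on
    # an orthonormal design (the general lasso path need not be monotone)
    rng = np.random.default_rng(3)
    A = rng.standard_normal((40, 12))
    A -= A.mean(0)
    Q, _ = np.linalg.qr(A)
    beta = np.linspace(2.0, 0.1, 12)
    y = Q @ beta + 0.05 * rng.standard_normal(40)
    sizes = []
    for lam in np.geomspace(0.05, 1e-4, 12):
        m = fit_enet(Q, y, ENetConfig(alpha=0.0, lam=lam, family="gaussian",
                                      standardize=False))
        sizes.append(len(m.selected))
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))
    assert sizes[0] < 12 and sizes[-1] == 12


def test_enet_internal_cv_one_se_prefers_more_regularization():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((60, 40))
    y = np.array([0, 1] * 30)
    X[y == 1, :5] += 1.5
    m_1se = fit_enet(X, y, ENetConfig(alpha=0.0, one_se=True), seed=0)
    m_min = fit_enet(X, y, ENetConfig(alpha=0.0, one_se=False), seed=0)
    assert m_1se.lam_ >= m_min.lam_
    assert len(m_1se.selected) <= len(m_min.selected) + 2


def test_enet_single_class_rejected():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError):
        fit_enet(X, np.ones(10), ENetConfig(alpha=0.5, lam=0.1))


# ---------------------------------------------------------------------------
# nearest shrunken centroids
# ---------------------------------------------------------------------------

def test_nsc_no_shrinkage_equals_plain_nearest_centroid():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 8))
    y = np.array([0, 1] * 15)
    X[y == 1, :2] += 1.0
    model = fit_nsc(X, y, NSCConfig(delta=0.0, s0=0.0, priors="equal"))
    # plain nearest centroid on genes standardized by the pooled SD
    cent = np.stack([X[y == k].mean(0) for k in (0, 1)])
    ss = sum(((X[y == k] - cent[k]) ** 2).sum(0) for k in (0, 1))
    s = np.sqrt(ss / (len(y) - 2))
    d0 = (((X - cent[0]) / s) ** 2).sum(1)
    d1 = (((X - cent[1]) / s) ** 2).sum(1)
    np.testing.assert_array_equal(model.predict(X), (d1 < d0).astype(int))


def test_nsc_total_shrinkage_assigns_larger_prior_class():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(21, 5))
    y = np.array([0] * 9 + [1] * 12)
    model = fit_nsc(X, y, NSCConfig(delta=1e9))
    assert model.n_surviving == 0
    np.testing.assert_array_equal(model.predict(X), np.ones(21, dtype=int))


def test_nsc_toy_matches_hand_computed_shrunken_centroids():
    """3 genes x 6 samples; every quantity recomputed by hand formulas."""
    X = np.array([
        [1.0, 10.0, 5.0],
        [2.0, 11.0, 5.2],
        [3.0, 12.0, 4.8],
        [7.0, 10.5, 5.1],
        [8.0, 11.5, 4.9],
        [9.0, 12.5, 5.0],
    ])
    y = np.array([0, 0, 0, 1, 1, 1])
    delta = 1.0
    model = fit_nsc(X, y, NSCConfig(delta=delta, s0=0.5))

    n, n0, n1 = 6, 3, 3
    overall = X.mean(axis=0)
    cent = np.stack([X[:3].mean(0), X[3:].mean(0)])
    ss = ((X[:3] - cent[0]) ** 2).sum(0) + ((X[3:] - cent[1]) ** 2).sum(0)
    s = np.sqrt(ss / (n - 2))
    s0 = 0.5
    m = np.sqrt(np.array([1 / n0 - 1 / n, 1 / n1 - 1 / n]))
    d = (cent - overall) / (m[:, None] * (s + s0))
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    expected = overall + m[:, None] * (s + s0) * d_shr
    np.testing.assert_allclose(model.centroids_, expected, atol=1e-10)
    np.testing.assert_allclose(model.d_shrunk_, d_shr, atol=1e-10)


def test_nsc_surviving_genes_monotone_in_delta():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 25))
    y = np.array([0, 1] * 20)
    X[y == 1, :8] += rng.uniform(0.3, 1.5, 8)
    counts = [fit_nsc(X, y, NSCConfig(delta=d)).n_surviving
              for d in np.linspace(0, 6, 20)]
    assert all(b <= a for a, b in zip(counts, counts[1:]))
    assert counts[0] == 25


def test_nsc_zero_sd_instructs_nonzero_s0():
    X = np.zeros((8, 3))
    X[:, 0] = [0, 0, 0, 0, 1, 1, 1, 1]
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    with pytest.raises(ValueError, match="s0"):
        fit_nsc(X, y, NSCConfig(delta=0.0, s0=0.0))


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def test_svm_separable_training_accuracy():
    rng = np.random.default_rng(8)
    X = np.vstack([rng.normal(-2, 0.3, (15, 2)), rng.normal(2, 0.3, (15, 2))])
    y = np.array([0] * 15 + [1] * 15)
    m = fit_svm(X, y, SVMConfig(C=2**10, gamma=0.5))
    assert ((m.scores(X) > 0.5) == y).mean() == 1.0


def test_svm_small_gamma_approaches_linear_behavior():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 2))
    w = np.array([1.0, -2.0])
    y = (X @ w > 0).astype(int)
    rbf = fit_svm(X, y, SVMConfig(C=2**8, gamma=2**-10), probability=False)
    from sklearn.svm import LinearSVC

    lin = LinearSVC(C=10.0).fit(X, y)
    agree = (rbf.clf.predict((X - X.mean(0)) / X.std(0)) == lin.predict(X)).mean()
    assert agree >= 0.95


def test_svm_duplication_leaves_decision_function_unchanged():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(20, 3))
    y = np.array([0, 1] * 10)
    X[y == 1] += 1.0
    probe = rng.normal(size=(15, 3))
    # libsvm's slack penalty is per point: duplicating every training point
    # doubles the loss term, so the invariant pairs duplication with C/2
    a = fit_svm(X, y, SVMConfig(C=4, gamma=0.3), probability=False)
    b = fit_svm(np.vstack([X, X]), np.r_[y, y], SVMConfig(C=2, gamma=0.3),
                probability=False)
    np.testing.assert_allclose(a.decision_function(probe),
                               b.decision_function(probe), atol=1e-6)


# ---------------------------------------------------------------------------
# random forest learner
# ---------------------------------------------------------------------------

def test_rf_separating_feature_oob_accuracy():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 10))
    y = np.array([0, 1] * 30)
    X[:, 4] = y + rng.normal(0, 0.05, 60)
    m = fit_rf(X, y, {"n_estimators": 200}, seed=0)
    assert m.clf.oob_score_ >= 0.95


def test_rf_deterministic_given_seed():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(40, 8))
    y = np.array([0, 1] * 20)
    a = fit_rf(X, y, {"n_estimators": 50}, seed=3)
    b = fit_rf(X, y, {"n_estimators": 50}, seed=3)
    np.testing.assert_array_equal(a.scores(X), b.scores(X))


def test_rf_single_stump_matches_exhaustive_split():
    X = np.array([[0.0], [1.0], [4.0], [5.0]])
    y = np.array([0, 0, 1, 1])
    m = fit_rf(X, y, {"n_estimators": 1, "max_depth": 1, "bootstrap": False,
                      "max_features": 1}, seed=0)
    thr = m.clf.estimators_[0].tree_.threshold[0]
    assert thr == pytest.approx(2.5, abs=1e-6)


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("learner,params", [
    (ENetLearner(n_lambda=8, cv_folds=4), {"alpha": 0.5, "lam": 0.05}),
    (SVMLearner(), {"C": 4.0, "gamma": 0.25}),
    (RFLearner(n_estimators=60), {"max_features": "sqrt"}),
    (NSCLearner(), {"delta_rel": 0.3}),
])
def test_learner_contract_probabilities_and_row_permutation(learner, params):
    rng = np.random.default_rng(13)
    X = rng.normal(size=(30, 12))
    y = np.array([0, 1] * 15)
    X[y == 1, :3] += 1.2
    probe = rng.normal(size=(9, 12))
    m = learner.fit(X, y, params, seed=0)
    s = m.scores(probe)
    assert s.shape == (9,) and np.all((s >= 0) & (s <= 1))
    perm = rng.permutation(30)
    m2 = learner.fit(X[perm], y[perm], params, seed=0)
    np.testing.assert_allclose(m2.scores(probe), s, atol=1e-6)
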