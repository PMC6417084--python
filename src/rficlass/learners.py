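"""The four classifiers, each behind the same contract.

``learner.fit(X, y, params, seed) -> model`` and ``model.scores(X') ->``
class-1 (high-RFI) probabilities.  Hyperparameter grids follow the published
analysis: elastic-net mixing alpha over {0, 0.15, 0.25, 0.35, 0.5, 0.65,
0.75, 0.85, 1} with lambda found by internal cross-validation and the
one-standard-error rule; SVM cost and RBF gamma over powers of two with
exponents -12..12; nearest-shrunken-centroid threshold (and a per-class
threshold scale) tuned over a relative grid.

Alpha convention: alpha multiplies the RIDGE term — 0 is the lasso, 1 is
ridge regression.  (scikit-learn's ``l1_ratio`` is therefore ``1 - alpha``.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from rficlass.metrics import encode_labels

ALPHA_GRID = (0.0, 0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85, 1.0)
POW2_EXPONENTS = tuple(range(-12, 13))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _canonical_order(X: np.ndarray, y: np.ndarray):
    """Sort training rows lexicographically so fits are invariant to the
    order in which samples arrive (bootstrap draws and SMO sweeps are not)."""
    order = np.lexsort(np.vstack([X.T, y]))
    return X[order], y[order]


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        self.sd_[self.sd_ == 0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ENetConfig:
    """alpha on the ridge-weighted convention; lam is a value or 'internal-cv'."""

    alpha: float = 0.5
    lam: float | str = "internal-cv"
    alpha_grid: tuple[float, ...] = ALPHA_GRID
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    cv_folds: int = 10
    one_se: bool = True
    family: str = "binomial"
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.family not in ("binomial", "gaussian"):
            raise ValueError("family must be 'binomial' or 'gaussian'")


@dataclass
class ENetModel:
    coef_: np.ndarray  # on the (standardized) predictor scale
    intercept_: float
    lam_: float
    alpha_: float
    family: str
    scaler: _Standardizer | None
    cv_lambdas_: np.ndarray | None = None
    cv_mean_: np.ndarray | None = None
    cv_se_: np.ndarray | None = None

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.coef_ != 0.0)

    def _linpred(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X @ self.coef_ + self.intercept_

    def scores(self, X: np.ndarray) -> np.ndarray:
        eta = self._linpred(X)
        return _sigmoid(eta) if self.family == "binomial" else eta


# the penalty is lam * ((1-alpha)*sum|b| + alpha*sum b^2) with alpha weighting
# the RIDGE term; scikit-learn's (l1_ratio, C/alpha) parameterization carries a
# 1/2 on its ridge term, hence the (1+alpha) rescaling below

def _sk_mix(alpha: float) -> float:
    """Map the ridge-weighted alpha to scikit-learn's l1_ratio."""
    return (1.0 - alpha) / (1.0 + alpha)


def _lambda_path(Xs, y, alpha, n_lambda, min_ratio) -> np.ndarray:
    """Descending lambda grid from the smallest all-zero-coefficient lambda."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * max(1.0 - alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_binomial_saga(Xs, y, alpha, lam, tol=1e-8, max_iter=20000):
    """scikit-learn route to the same objective; used as a cross-check."""
    n = len(y)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=_sk_mix(alpha),
        C=1.0 / (n * lam * (1.0 + alpha)),
        tol=tol,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _fista(Xs, y, l1, l2, b, b0, tol, max_iter):
    """Accelerated proximal gradient for one penalized logistic problem.

    Minimizes (1/n) sum logloss + l1*|b|_1 + l2*|b|_2^2 with an unpenalized
    intercept; soft-thresholding produces exact zeros.
    """
    n, p = Xs.shape
    if p == 0:
        ybar = min(max(float(np.mean(y)), 1e-12), 1 - 1e-12)
        return b, float(np.log(ybar / (1.0 - ybar)))
    L = (np.linalg.norm(Xs, 2) ** 2) / (4.0 * n)
    step = 1.0 / (L + 0.25 + 2.0 * l2)
    zb, zb0, t = b.copy(), b0, 1.0
    db_prev = np.zeros_like(b)
    for it in range(max_iter):
        pr = _sigmoid(Xs @ zb + zb0)
        g = Xs.T @ (pr - y) / n + 2.0 * l2 * zb
        bn = zb - step * g
        if l1 > 0:
            bn = np.sign(bn) * np.maximum(np.abs(bn) - step * l1, 0.0)
        b0n = zb0 - step * float((pr - y).mean())
        db = bn - b
        # adaptive restart: drop momentum when successive steps disagree
        if it > 0 and float(db @ db_prev) < 0.0:
            t = 1.0
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        zb = bn + ((t - 1.0) / tn) * db
        zb0 = b0n + ((t - 1.0) / tn) * (b0n - b0)
        done = (
            it > 3
            and float(np.abs(db).max()) < tol * max(1.0, float(np.abs(bn).max()))
            and abs(b0n - b0) < tol * max(1.0, abs(b0n))
        )
        b, b0, t = bn, b0n, tn
        db_prev = db
        if done:
            break
    return b, b0


def _ridge_path_dual(Xs, y, lambdas, tol, max_iter):
    """Pure-ridge (alpha=1) path solved in the n-dimensional dual space.

    The stationarity condition b = -X^T (p - y) / (2 lam n) places the
    optimum in the row space of X, so b = X^T c with only n unknowns.
    """
    n, p = Xs.shape
    K = Xs @ Xs.T
    normK = np.linalg.norm(K, 2)
    coefs = np.empty((len(lambdas), p))
    icpts = np.empty(len(lambdas))
    c = np.zeros(n)
    b0 = 0.0
    for k, lam in enumerate(lambdas):
        step = 1.0 / (normK * (normK / (4.0 * n) + 2.0 * lam) + 0.25)
        zc, zb0, t = c.copy(), b0, 1.0
        for it in range(max_iter):
            pr = _sigmoid(K @ zc + zb0)
            g = K @ ((pr - y) / n + 2.0 * lam * zc)
            cn = zc - step * g
            b0n = zb0 - step * float(np.mean(pr - y))
            tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            dc = cn - c
            zc = cn + ((t - 1.0) / tn) * dc
            zb0 = b0n + ((t - 1.0) / tn) * (b0n - b0)
            done = it > 3 and np.max(np.abs(K @ dc)) < tol * 10.0
            c, b0, t = cn, b0n, tn
            if done:
                break
        coefs[k] = Xs.T @ c
        icpts[k] = b0
    return coefs, icpts


def _binomial_path(Xs, y, alpha, lambdas, tol=1e-7, max_iter=400):
    """Warm-started elastic-net logistic fits along a descending lambda path.

    Uses sequential strong-rule screening (candidates with large gradient at
    the previous solution) followed by a KKT check over the excluded
    features, so each subproblem involves only the plausibly active genes;
    pure ridge is dispatched to the dual-space solver.
    """
    n, p = Xs.shape
    lambdas = np.asarray(lambdas, dtype=float)
    if alpha >= 1.0:
        return _ridge_path_dual(Xs, y, lambdas, tol, max_iter)
    coefs = np.empty((len(lambdas), p))
    icpts = np.empty(len(lambdas))
    b = np.zeros(p)
    b0 = 0.0
    for k, lam in enumerate(lambdas):
        l1 = lam * (1.0 - alpha)
        l2 = lam * alpha
        lam_prev = lambdas[k - 1] if k > 0 else lam
        pr = _sigmoid(Xs @ b + b0)
        g_full = np.abs(Xs.T @ (y - pr)) / n
        thr = max((2.0 * lam - lam_prev) * (1.0 - alpha), 0.0)
        active = np.flatnonzero((g_full >= thr) | (b != 0.0))
        for _ in range(5):  # screening rounds: refit until KKT holds
            bA, b0 = _fista(Xs[:, active], y, l1, l2, b[active], b0,
                            tol, max_iter)
            b = np.zeros(p)
            b[active] = bA
            pr = _sigmoid(Xs @ b + b0)
            g_full = np.abs(Xs.T @ (y - pr)) / n
            viol = np.flatnonzero(g_full > l1 * (1.0 + 1e-3))
            viol = np.setdiff1d(viol, active)
            if len(viol) == 0:
                break
            active = np.union1d(active, viol)
        coefs[k] = b
        icpts[k] = b0
    return coefs, icpts


def _fit_binomial(Xs, y, alpha, lam, tol=1e-9, max_iter=5000):
    if lam == 0:
        clf = LogisticRegression(C=np.inf, tol=1e-10, max_iter=10000)
        clf.fit(Xs, y)
        return clf.coef_[0].copy(), float(clf.intercept_[0])
    coefs, icpts = _binomial_path(Xs, y, alpha, np.array([lam]),
                                  tol=tol, max_iter=max_iter)
    return coefs[0], float(icpts[0])


def _fit_gaussian(Xs, y, alpha, lam):
    n = len(y)
    if lam == 0:
        reg = LinearRegression()
    elif alpha == 1.0:
        reg = Ridge(alpha=2.0 * n * lam)
    else:
        reg = ElasticNet(
            alpha=lam * (1.0 + alpha), l1_ratio=_sk_mix(alpha),
            tol=1e-10, max_iter=100000,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(Xs, y)
    return np.asarray(reg.coef_, dtype=float).copy(), float(reg.intercept_)


def _binomial_deviance(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_enet(X, y, cfg: ENetConfig | None = None, seed: int = 0) -> ENetModel:
    """Penalized binomial-deviance (or gaussian) elastic-net fit.

    With ``lam='internal-cv'`` the lambda path is tuned by internal
    cross-validated deviance; the one-standard-error rule picks the most
    regularized lambda whose CV deviance is within one SE of the minimum.
    """
    cfg = cfg or ENetConfig()
    X = np.asarray(X, dtype=float)
    if cfg.family == "binomial":
        y = encode_labels(y).astype(float)
        if len(np.unique(y)) < 2:
            raise ValueError("y contains a single class")
    else:
        y = np.asarray(y, dtype=float)
    alpha = cfg.alpha
    scaler = _Standardizer().fit(X) if cfg.standardize else None
    Xs = scaler.transform(X) if scaler else X

    if cfg.lam != "internal-cv":
        lam = float(cfg.lam)
        if cfg.family == "binomial":
            coef, icpt = _fit_binomial(Xs, y, alpha, lam)
        else:
            coef, icpt = _fit_gaussian(Xs, y, alpha, lam)
        return ENetModel(coef, icpt, lam, cfg.alpha, cfg.family, scaler)

    lambdas = _lambda_path(Xs, y, alpha, cfg.n_lambda, cfg.lambda_min_ratio)
    n_folds = min(cfg.cv_folds, int(min(np.bincount(y.astype(int)))))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        if cfg.family == "binomial":
            coefs, icpts = _binomial_path(Xs[tr], y[tr], alpha, lambdas)
            eta = Xs[va] @ coefs.T + icpts
            for i in range(len(lambdas)):
                dev[f, i] = _binomial_deviance(_sigmoid(eta[:, i]), y[va])
        else:
            for i, lam in enumerate(lambdas):
                coef, icpt = _fit_gaussian(Xs[tr], y[tr], alpha, lam)
                dev[f, i] = float(np.mean((y[va] - (Xs[va] @ coef + icpt)) ** 2))
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    if cfg.one_se:
        ok = np.flatnonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])
        i_sel = int(ok.min())  # lambdas descend, so min index = largest lambda
    else:
        i_sel = i_min
    lam = float(lambdas[i_sel])
    if cfg.family == "binomial":
        coef, icpt = _fit_binomial(Xs, y, alpha, lam)
    else:
        coef, icpt = _fit_gaussian(Xs, y, alpha, lam)
    return ENetModel(
        coef, icpt, lam, cfg.alpha, cfg.family, scaler,
        cv_lambdas_=lambdas, cv_mean_=cv_mean, cv_se_=cv_se,
    )


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class SVMModel:
    clf: object  # calibrated classifier or a bare SVC
    scaler: _Standardizer

    @property
    def selected(self):
        return None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        clf = self.clf
        if isinstance(clf, CalibratedClassifierCV):
            clf = clf.calibrated_classifiers_[0].estimator
        return clf.decision_function(Xs)

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        if hasattr(self.clf, "predict_proba"):
            proba = self.clf.predict_proba(Xs)[:, list(self.clf.classes_).index(1)]
            dec = self.decision_function(X)
            # calibration must be monotone in the decision values; with
            # near-constant decisions the sigmoid slope can flip sign
            # numerically — fall back to the raw decision ordering then
            if len(proba) > 1 and np.ptp(dec) > 0 and np.ptp(proba) > 0:
                c = np.corrcoef(proba, dec)[0, 1]
                if np.isfinite(c) and c < 0:
                    return _sigmoid(dec)
            return proba
        # decision values, squashed monotonically: fine for ranking metrics
        return _sigmoid(self.clf.decision_function(Xs))


def fit_svm(X, y, cfg: SVMConfig | None = None, seed: int = 0,
            probability: bool = True) -> SVMModel:
    """RBF-kernel SVM; probabilities via Platt scaling on internal CV folds."""
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    X, y = _canonical_order(X, y)
    scaler = _Standardizer().fit(X)
    base = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf", tol=1e-6)
    if probability:
        cv = max(2, min(5, int(np.bincount(y).min())))
        clf = CalibratedClassifierCV(base, method="sigmoid", cv=cv, ensemble=False)
    else:
        clf = base
    clf.fit(scaler.transform(X), y)
    return SVMModel(clf=clf, scaler=scaler)


# ---------------------------------------------------------------------------
# Random forest (classifier; distinct from the ranking forest)
# ---------------------------------------------------------------------------

@dataclass
class RFModel:
    clf: RandomForestClassifier

    @property
    def selected(self):
        return None

    def scores(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(np.asarray(X, dtype=float))
        return proba[:, list(self.clf.classes_).index(1)]


def fit_rf(X, y, params: dict | None = None, seed: int = 0) -> RFModel:
    """Bootstrap ensemble of classification trees; probability = vote fraction."""
    params = dict(params or {})
    params.setdefault("n_estimators", 500)
    params.setdefault("max_features", "sqrt")
    clf = RandomForestClassifier(
        random_state=seed, oob_score=params.get("bootstrap", True), **params
    )
    Xc, yc = _canonical_order(np.asarray(X, dtype=float), encode_labels(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small OOB sets can miss some rows
        clf.fit(Xc, yc)
    return RFModel(clf=clf)


# ---------------------------------------------------------------------------
# Nearest shrunken centroids (PAM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NSCConfig:
    """Soft-thresholding of standardized class-centroid offsets.

    ``delta`` is the absolute threshold; ``delta_rel`` instead expresses it as
    a fraction of max|d_ik| of the training data (convenient for grids).
    ``threshold_scale`` multiplies the within-class standard deviation term
    per class (order: class 0 = low, class 1 = high).  ``s0`` stabilizes tiny
    per-gene variances; 'median' uses the median of the pooled SDs.
    """

    delta: float | None = None
    delta_rel: float | None = None
    threshold_scale: tuple[float, float] = (1.0, 1.0)
    s0: float | str = "median"
    priors: str = "empirical"  # or 'equal'

    def __post_init__(self) -> None:
        if (self.delta is None) == (self.delta_rel is None):
            raise ValueError("specify exactly one of delta / delta_rel")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.delta_rel is not None and self.delta_rel < 0:
            raise ValueError("delta_rel must be >= 0")
        if any(t <= 0 for t in self.threshold_scale):
            raise ValueError("threshold_scale entries must be positive")


@dataclass
class NSCModel:
    overall_: np.ndarray
    centroids_: np.ndarray  # (2, p) shrunken centroids, rows = class 0, 1
    d_shrunk_: np.ndarray  # (2, p)
    s_: np.ndarray
    s0_: float
    delta_: float
    priors_: np.ndarray
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.d_shrunk_ != 0.0, axis=0))

    @property
    def n_surviving(self) -> int:
        return int(len(self.selected))

    def discriminant(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        denom = (self.s_ + self.s0_) ** 2
        out = np.empty((X.shape[0], 2))
        for k in range(2):
            out[:, k] = ((X - self.centroids_[k]) ** 2 / denom).sum(axis=1)
            out[:, k] -= 2.0 * np.log(self.priors_[k])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.discriminant(X)
        # ties go to the larger-prior class (class order by descending prior)
        pref = np.argsort(-self.priors_, kind="mergesort")
        return np.where(
            np.isclose(d[:, pref[0]], d[:, pref[1]]) | (d[:, pref[0]] < d[:, pref[1]]),
            pref[0],
            pref[1],
        )

    def scores(self, X: np.ndarray) -> np.ndarray:
        d = self.discriminant(X)
        z = -0.5 * (d - d.min(axis=1, keepdims=True))
        w = np.exp(z)
        return w[:, 1] / w.sum(axis=1)


def fit_nsc(X, y, cfg: NSCConfig | None = None, seed: int = 0) -> NSCModel:
    """Shrunken-centroid fit.

    d_ik = (xbar_ik - xbar_i) / (m_k * scale_k * (s_i + s0)) with
    m_k = sqrt(1/n_k - 1/n); offsets are soft-thresholded by delta and the
    centroids rebuilt from the surviving offsets.
    """
    cfg = cfg or NSCConfig(delta_rel=0.0)
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    n, p = X.shape
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    overall = X.mean(axis=0)
    cent = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
    ss = sum(((X[y == k] - cent[k]) ** 2).sum(axis=0) for k in (0, 1))
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s)) if cfg.s0 == "median" else float(cfg.s0)
    if np.any(s + s0 == 0):
        raise ValueError(
            "zero pooled within-class SD with s0=0; use a positive s0 "
            "(e.g. the default s0='median')"
        )
    m = np.sqrt(1.0 / counts - 1.0 / n)
    scale = np.asarray(cfg.threshold_scale, dtype=float)
    denom = m[:, None] * scale[:, None] * (s + s0)[None, :]
    d = (cent - overall) / denom

    delta = cfg.delta if cfg.delta is not None else cfg.delta_rel * np.abs(d).max()
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunk_cent = overall + denom * d_shrunk

    priors = (
        counts / n if cfg.priors == "empirical" else np.array([0.5, 0.5])
    )
    return NSCModel(
        overall_=overall,
        centroids_=shrunk_cent,
        d_shrunk_=d_shrunk,
        s_=s,
        s0_=s0,
        delta_=float(delta),
        priors_=priors,
    )


# ---------------------------------------------------------------------------
# Uniform learner interface for the resampling engine
# ---------------------------------------------------------------------------

class ENetLearner:
    """Tunes alpha via the resampling grid; lambda by internal CV (one-SE)."""

    name = "ENET"
    provides_selection = True

    def __init__(self, alpha_grid=ALPHA_GRID, n_lambda: int = 30,
                 lambda_min_ratio: float = 0.01, cv_folds: int = 10):
        self.alpha_grid = tuple(alpha_grid)
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds

    def default_grid(self) -> list[dict]:
        return [{"alpha": a} for a in self.alpha_grid]

    def fit(self, X, y, params: dict, seed: int = 0, final: bool = True):
        cfg = ENetConfig(
            alpha=params["alpha"],
            lam=params.get("lam", "internal-cv"),
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            cv_folds=self.cv_folds,
        )
        return fit_enet(X, y, cfg, seed=seed)


class SVMLearner:
    name = "SVM"
    provides_selection = False

    def __init__(self, exponents=POW2_EXPONENTS):
        self.exponents = tuple(exponents)

    def default_grid(self) -> list[dict]:
        return [
            {"C": 2.0**i, "gamma": 2.0**j}
            for i in self.exponents
            for j in self.exponents
        ]

    def fit(self, X, y, params: dict, seed: int = 0, final: bool = True):
        cfg = SVMConfig(C=params["C"], gamma=params["gamma"])
        # Platt calibration only on final fits; tuning ranks by decision values
        return fit_svm(X, y, cfg, seed=seed, probability=final)


class RFLearner:
    name = "RF"
    provides_selection = False

    def __init__(self, n_estimators: int = 500, max_features_grid=("sqrt",)):
        self.n_estimators = n_estimators
        self.max_features_grid = tuple(max_features_grid)

    def default_grid(self) -> list[dict]:
        return [{"max_features": f} for f in self.max_features_grid]

    def fit(self, X, y, params: dict, seed: int = 0, final: bool = True):
        p = dict(params)
        p.setdefault("n_estimators", self.n_estimators)
        return fit_rf(X, y, p, seed=seed)


class NSCLearner:
    name = "PAM"
    provides_selection = True

    def __init__(self, delta_rel_grid=tuple(np.round(np.linspace(0, 1, 21), 3)),
                 threshold_scales=((1.0, 1.0),)):
        self.delta_rel_grid = tuple(delta_rel_grid)
        self.threshold_scales = tuple(threshold_scales)

    def default_grid(self) -> list[dict]:
        return [
            {"delta_rel": d, "threshold_scale": ts}
            for d in self.delta_rel_grid
            for ts in self.threshold_scales
        ]

    def fit(self, X, y, params: dict, seed: int = 0, final: bool = True):
        cfg = NSCConfig(
            delta_rel=params.get("delta_rel"),
            delta=params.get("delta"),
            threshold_scale=tuple(params.get("threshold_scale", (1.0, 1.0))),
        )
        return fit_nsc(X, y, cfg, seed=seed)


DEFAULT_LEARNERS = {
    "ENET": ENetLearner,
    "SVM": SVMLearner,
    "RF": RFLearner,
    "PAM": NSCLearner,
}
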