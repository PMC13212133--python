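"""Protein panel selection and evaluation.

The selection procedure: an L1-penalized logistic regression over the
candidate proteins is fitted along a 100-point lambda path (glmnet-style
coordinate descent on the IRLS quadratic approximation, with warm starts),
the penalty is chosen by 10-fold stratified cross-validated binomial
deviance at its minimum, proteins with nonzero coefficients are ranked by
decreasing absolute standardized coefficient, and an incremental-AUC curve
(unpenalized logistic refits on the top-k proteins, AUC on a held-out
split) is cut by the parsimony rule: the smallest k whose AUC is within a
tolerance (default 0.01) of the curve maximum. The resulting panel is then
evaluated with four classifiers (logistic, random forest, gradient-boosted
trees, support-vector with Platt-calibrated probabilities) on a stratified
70/30 split, scored by rank-statistic (Mann-Whitney) ROC/AUC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._glm import irls_logistic

__all__ = [
    "LassoFit",
    "PanelCurve",
    "ROCCurve",
    "PanelModel",
    "split_stratified",
    "lasso_logistic_cv",
    "rank_proteins",
    "incremental_auc",
    "select_parsimonious",
    "train_classifiers",
    "roc_auc",
]

N_LAMBDA = 100
LAMBDA_DECADES = 4.0
PARSIMONY_TOLERANCE = 0.01


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class LassoFit:
    lambda_grid: np.ndarray
    cv_error: np.ndarray          # mean CV deviance per lambda
    cv_error_sd: np.ndarray       # fold SD per lambda
    lambda_star: float
    coefficients_at_star: dict    # standardized scale, incl. "intercept"
    coefficients_original: dict   # original feature scale, incl. "intercept"
    nonzero_ids: list
    folds: np.ndarray
    seed: int
    feature_means: np.ndarray = field(repr=False, default=None)
    feature_sds: np.ndarray = field(repr=False, default=None)


@dataclass
class PanelCurve:
    k_values: np.ndarray
    auc_at_k: np.ndarray
    ranking: list


@dataclass
class PanelModel:
    panel_ids: list
    classifier_name: str
    fitted_params: object
    roc: ROCCurve
    auc: float
    split_seed: int
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None


# ---------------------------------------------------------------------------
# splitting and ROC


def split_stratified(outcome, train_fraction: float = 0.7, seed: int = 0):
    """Outcome-stratified train/test index split.

    Within each class the train count is the floor of fraction * class size,
    with remainders distributed (largest fractional part first) so the
    overall train count hits round(fraction * n).
    """
    y = np.asarray(outcome).astype(int)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < 2:
        raise ValueError("cannot stratify a class with fewer than 2 members")
    rng = np.random.default_rng(seed)
    n = y.size
    target_total = int(round(train_fraction * n))
    floors = np.floor(train_fraction * counts).astype(int)
    remainders = train_fraction * counts - floors
    extra = target_total - floors.sum()
    order = np.argsort(-remainders)
    take = floors.copy()
    for i in range(int(extra)):
        take[order[i % classes.size]] += 1
    train_idx = []
    for cls, k in zip(classes, take):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        train_idx.append(idx[:k])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC via the Mann-Whitney U statistic with midranks.

    The curve thresholds at each distinct score (ties grouped), so its
    trapezoidal area equals the rank-statistic AUC exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


# ---------------------------------------------------------------------------
# L1-penalized logistic path


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _l1_logistic(X, y, lam, beta0=0.0, beta=None, max_outer=100, tol=1e-9,
                 trace=None):
    """One L1-penalized logistic fit at fixed lambda by coordinate descent.

    X is assumed standardized; the intercept is unpenalized. Objective is
    mean binomial deviance / 2 plus lam * ||beta||_1. ``trace``, if a list,
    accumulates the penalized objective after each outer IRLS step (the
    inner sweeps minimize the quadratic surrogate, which need not decrease
    the exact objective sweep-by-sweep).
    """
    n, p = X.shape
    if beta is None:
        beta = np.zeros(p)
    beta = beta.copy()

    def objective(b0, b):
        eta = b0 + X @ b
        # log(1+exp) stable
        ll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return ll + lam * np.abs(b).sum()

    for _ in range(max_outer):
        eta = beta0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-6)
        z = eta + (y - mu) / w
        # inner coordinate descent on the weighted least squares problem
        for _sweep in range(100):
            max_change = 0.0
            r = z - beta0 - X @ beta
            wsum = w.sum()
            for j in range(p):
                xj = X[:, j]
                r += xj * beta[j]
                num = np.dot(w * xj, r) / n
                denom = np.dot(w, xj * xj) / n
                new = _soft(num, lam) / denom if denom > 0 else 0.0
                max_change = max(max_change, abs(new - beta[j]))
                beta[j] = new
                r -= xj * beta[j]
            new0 = beta0 + np.dot(w, r) / wsum
            max_change = max(max_change, abs(new0 - beta0))
            r += beta0 - new0
            beta0 = new0
            if max_change < tol:
                break
        if trace is not None:
            trace.append(objective(beta0, beta))
        eta_new = beta0 + X @ beta
        if np.max(np.abs(eta_new - eta)) < 1e-7:
            break
    return beta0, beta


def _deviance(X, y, beta0, beta):
    eta = beta0 + X @ beta
    return 2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta)


def _stratified_folds(y, n_folds, rng):
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def lasso_logistic_cv(features: pd.DataFrame, outcome, n_folds: int = 10,
                      seed: int = 0, n_lambda: int = N_LAMBDA) -> LassoFit:
    """L1 logistic path with lambda chosen at minimum mean CV deviance.

    Features are standardized internally (constant columns dropped with a
    warning); the grid is log-spaced over 4 decades down from lambda_max,
    the smallest penalty that zeroes every coefficient. Folds are
    stratified by outcome and stored for audit.
    """
    y = np.asarray(outcome).astype(float)
    Xdf = features.astype(float)
    sds = Xdf.std(axis=0, ddof=0)
    const = sds[sds == 0].index.tolist()
    if const:
        warnings.warn(f"dropping constant features: {const}")
        Xdf = Xdf.drop(columns=const)
        sds = sds.drop(index=const)
    names = list(Xdf.columns)
    means = Xdf.mean(axis=0)
    X = ((Xdf - means) / sds).to_numpy()
    n, p = X.shape
    if n < 5 * n_folds:
        raise ValueError("need at least 5 observations per fold")

    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / n
    grid = np.geomspace(lam_max, lam_max * 10 ** -LAMBDA_DECADES, n_lambda)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y.astype(int), n_folds, rng)
    dev = np.zeros((n_folds, n_lambda))
    for f in range(n_folds):
        tr, va = folds != f, folds == f
        beta0, beta = 0.0, np.zeros(p)
        for li, lam in enumerate(grid):
            beta0, beta = _l1_logistic(X[tr], y[tr], lam, beta0, beta)
            dev[f, li] = _deviance(X[va], y[va], beta0, beta)
    cv_mean = dev.mean(axis=0)
    cv_sd = dev.std(axis=0, ddof=1)
    star = int(np.argmin(cv_mean))
    lam_star = float(grid[star])

    beta0, beta = 0.0, np.zeros(p)
    for lam in grid[: star + 1]:
        beta0, beta = _l1_logistic(X, y, lam, beta0, beta)
    coefs_std = {"intercept": float(beta0),
                 **{nm: float(b) for nm, b in zip(names, beta)}}
    beta_orig = beta / sds.to_numpy()
    coefs_orig = {"intercept": float(beta0 - np.dot(beta_orig, means.to_numpy())),
                  **{nm: float(b) for nm, b in zip(names, beta_orig)}}
    nonzero = [nm for nm, b in zip(names, beta) if b != 0.0]
    if not nonzero:
        warnings.warn("all coefficients zero at lambda_star: intercept-only model")
    return LassoFit(lambda_grid=grid, cv_error=cv_mean, cv_error_sd=cv_sd,
                    lambda_star=lam_star, coefficients_at_star=coefs_std,
                    coefficients_original=coefs_orig, nonzero_ids=nonzero,
                    folds=folds, seed=seed,
                    feature_means=means.to_numpy(), feature_sds=sds.to_numpy())


def rank_proteins(fit: LassoFit) -> list:
    """Nonzero proteins by decreasing |standardized coefficient|, ties by id."""
    items = [(nm, abs(c)) for nm, c in fit.coefficients_at_star.items()
             if nm != "intercept" and c != 0.0]
    if not items:
        warnings.warn("empty nonzero set: returning empty ranking")
        return []
    return [nm for nm, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def incremental_auc(ranking: list, features: pd.DataFrame, outcome,
                    train_idx, test_idx) -> PanelCurve:
    """Validation AUC of unpenalized top-k logistic models, k = 1..len(ranking)."""
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and validation indices overlap")
    y = np.asarray(outcome).astype(float)
    aucs = []
    for k in range(1, len(ranking) + 1):
        cols = ranking[:k]
        Xtr = features.iloc[train_idx][cols].to_numpy(dtype=float)
        Xte = features.iloc[test_idx][cols].to_numpy(dtype=float)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        design = np.column_stack([np.ones(len(train_idx)), Xtr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = irls_logistic(design, y[train_idx], check_rank=False)
        scores = np.column_stack([np.ones(len(test_idx)), Xte]) @ fit.coefficients
        aucs.append(roc_auc(scores, y[test_idx]).auc)
    return PanelCurve(k_values=np.arange(1, len(ranking) + 1),
                      auc_at_k=np.array(aucs), ranking=list(ranking))


def select_parsimonious(curve: PanelCurve, tolerance: float = PARSIMONY_TOLERANCE):
    """Smallest k whose AUC is within ``tolerance`` of the curve maximum."""
    if curve.auc_at_k.size == 0:
        raise ValueError("empty panel curve")
    cutoff = curve.auc_at_k.max() - tolerance
    k_star = int(curve.k_values[np.flatnonzero(curve.auc_at_k >= cutoff)[0]])
    return k_star, curve.ranking[:k_star]


# ---------------------------------------------------------------------------
# classifier evaluation

CLASSIFIERS = ("logistic", "random-forest", "gradient-boosted-trees",
               "support-vector")


def _fit_predict(method: str, Xtr, ytr, Xte, seed: int):
    if method == "logistic":
        design = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = irls_logistic(design, ytr, check_rank=False)
        eta = np.column_stack([np.ones(Xte.shape[0]), Xte]) @ fit.coefficients
        return 1.0 / (1.0 + np.exp(-eta)), fit
    if method == "random-forest":
        from sklearn.ensemble import RandomForestClassifier
        clf = RandomForestClassifier(n_estimators=300, random_state=seed)
        clf.fit(Xtr, ytr)
        return clf.predict_proba(Xte)[:, 1], clf
    if method == "gradient-boosted-trees":
        from xgboost import XGBClassifier
        clf = XGBClassifier(n_estimators=200, max_depth=3, learning_rate=0.1,
                            random_state=seed, eval_metric="logloss",
                            verbosity=0)
        clf.fit(Xtr, ytr)
        return clf.predict_proba(Xte)[:, 1], clf
    if method == "support-vector":
        from sklearn.svm import SVC
        # probability=True fits a Platt-style sigmoid on internal CV folds
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
        clf.fit(Xtr, ytr)
        return clf.predict_proba(Xte)[:, 1], clf
    raise ValueError(f"unknown classifier method: {method!r}")


def train_classifiers(features: pd.DataFrame, outcome, split,
                      methods=CLASSIFIERS, seed: int = 0) -> dict[str, PanelModel]:
    """Fit each requested classifier on the train split, score the test split.

    Features are standardized with train-split parameters for every method.
    Returns a dict method -> PanelModel with held-out ROC and AUC.
    """
    train_idx, test_idx = split
    y = np.asarray(outcome).astype(float)
    X = features.to_numpy(dtype=float)
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xtr = (X[train_idx] - mu) / sd
    Xte = (X[test_idx] - mu) / sd
    out = {}
    for method in methods:
        scores, fitted = _fit_predict(method, Xtr, y[train_idx], Xte, seed)
        roc = roc_auc(scores, y[test_idx])
        out[method] = PanelModel(panel_ids=list(features.columns),
                                 classifier_name=method, fitted_params=fitted,
                                 roc=roc, auc=roc.auc, split_seed=seed,
                                 feature_means=mu, feature_sds=sd)
    return out
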