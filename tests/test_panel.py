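"""Stratified splitting, rank AUC, L1 path, parsimony rule, classifiers."""
import numpy as np
import pandas as pd
import pytest

from circamasld.panel import (
    PanelCurve,
    _l1_logistic,
    incremental_auc,
    lasso_logistic_cv,
    rank_proteins,
    roc_auc,
    select_parsimonious,
    split_stratified,
    train_classifiers,
)


class TestSplit:
    def test_exact_stratification_arithmetic(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        tr, te = split_stratified(y, 0.7, seed=0)
        assert y[tr].sum() == 21 and len(tr) - y[tr].sum() == 49
        assert len(tr) + len(te) == 100 and np.intersect1d(tr, te).size == 0

    def test_tiny_balanced_split(self):
        y = np.array([0, 0, 1, 1])
        tr, te = split_stratified(y, 0.5, seed=1)
        assert y[tr].sum() == 1 and len(tr) == 2

    def test_prevalence_preserved(self, rng):
        for seed in range(5):
            y = (rng.random(237) < 0.23).astype(int)
            tr, te = split_stratified(y, 0.7, seed=seed)
            tol = 1 / min(y.sum(), (1 - y).sum())
            assert abs(y[tr].mean() - y[te].mean()) <= tol + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_stratified(np.ones(10), 0.7, seed=0)


class TestROC:
    def test_pair_enumeration_example(self):
        # positives score 0.9, 0.7; negatives 0.8, 0.6 -> 3 of 4 pairs win
        curve = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert curve.auc == pytest.approx(3 / 4)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.ones(10), [1, 0] * 5).auc == 0.5

    def test_complement_identity(self, rng):
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=150)
        y = rng.integers(0, 2, 150)
        assert roc_auc(np.exp(s), y).auc == pytest.approx(roc_auc(s, y).auc)

    def test_trapezoid_equals_rank_statistic(self, rng):
        s = rng.integers(0, 10, 300).astype(float)  # heavy ties
        y = rng.integers(0, 2, 300)
        curve = roc_auc(s, y)
        trap = np.trapezoid(curve.tpr, curve.fpr)
        assert trap == pytest.approx(curve.auc, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=400)
        y = rng.integers(0, 2, 400)
        assert roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_curve_monotone_endpoints(self, rng):
        curve = roc_auc(rng.normal(size=100), rng.integers(0, 2, 100))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


def proximal_gradient_oracle(X, y, lam, n_iter=200_000, tol=1e-12):
    """Independent ISTA solver for the standardized L1 logistic problem."""
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    L = np.linalg.eigvalsh(Xa.T @ Xa / n).max() / 4 + 1e-9
    beta = np.zeros(p + 1)
    for _ in range(n_iter):
        eta = Xa @ beta
        grad = Xa.T @ (1 / (1 + np.exp(-eta)) - y) / n
        new = beta - grad / L
        new[1:] = np.sign(new[1:]) * np.maximum(np.abs(new[1:]) - lam / L, 0)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


class TestLasso:
    def _problem(self, rng, n=300, p=6, informative=2):
        X = rng.normal(size=(n, p))
        eta = 1.2 * X[:, 0] - 0.9 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return pd.DataFrame(X, columns=[f"P{i}" for i in range(p)]), y

    def test_huge_lambda_zeroes_everything(self, rng):
        X, y = self._problem(rng)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        b0, b = _l1_logistic(Z, y, lam=10.0)
        assert np.allclose(b, 0.0)

    def test_tiny_lambda_matches_unpenalized(self, rng):
        from circamasld._glm import irls_logistic

        X, y = self._problem(rng)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        b0, b = _l1_logistic(Z, y, lam=1e-8)
        ref = irls_logistic(np.column_stack([np.ones(len(y)), Z]), y)
        assert b0 == pytest.approx(ref.coefficients[0], abs=1e-4)
        assert b == pytest.approx(ref.coefficients[1:], abs=1e-4)

    def test_matches_proximal_gradient_oracle(self, rng):
        X, y = self._problem(rng)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        for lam in (0.02, 0.05, 0.1):
            b0, b = _l1_logistic(Z, y, lam=lam)
            ref = proximal_gradient_oracle(Z, y, lam)
            assert set(np.flatnonzero(b != 0)) == set(np.flatnonzero(
                np.abs(ref[1:]) > 1e-8))
            assert b == pytest.approx(ref[1:], abs=2e-5)
            assert b0 == pytest.approx(ref[0], abs=2e-5)

    def test_objective_trace_nonincreasing(self, rng):
        X, y = self._problem(rng)
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        trace = []
        _l1_logistic(Z, y, lam=0.05, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-10)

    def test_cv_selects_and_reports_consistently(self, rng):
        X, y = self._problem(rng, n=400)
        fit = lasso_logistic_cv(X, y, n_folds=5, seed=0, n_lambda=40)
        assert fit.lambda_star in fit.lambda_grid
        nz = {nm for nm, c in fit.coefficients_at_star.items()
              if nm != "intercept" and c != 0}
        assert set(fit.nonzero_ids) == nz
        assert {"P0", "P1"} <= nz
        # original-scale coefficients reproduce the standardized predictions
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        eta_std = fit.coefficients_at_star["intercept"] + Z @ np.array(
            [fit.coefficients_at_star[f"P{i}"] for i in range(6)])
        eta_orig = fit.coefficients_original["intercept"] + X.to_numpy() @ np.array(
            [fit.coefficients_original[f"P{i}"] for i in range(6)])
        assert eta_std == pytest.approx(eta_orig, abs=1e-8)

    def test_constant_feature_dropped(self, rng):
        X, y = self._problem(rng)
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = lasso_logistic_cv(X, y, n_folds=5, seed=0, n_lambda=20)
        assert "const" not in fit.coefficients_at_star


class TestRanking:
    def _fit(self, coefs):
        from circamasld.panel import LassoFit

        return LassoFit(lambda_grid=np.array([0.1]), cv_error=np.array([1.0]),
                        cv_error_sd=np.array([0.0]), lambda_star=0.1,
                        coefficients_at_star={"intercept": 0.0, **coefs},
                        coefficients_original={}, nonzero_ids=list(coefs),
                        folds=np.zeros(1), seed=0)

    def test_absolute_value_ordering(self):
        assert rank_proteins(self._fit({"A": -0.9, "B": 0.5, "C": 0.1})) == \
            ["A", "B", "C"]

    def test_tie_lexicographic(self):
        assert rank_proteins(self._fit({"B": 0.5, "A": -0.5})) == ["A", "B"]

    def test_zero_coefficients_excluded(self):
        assert rank_proteins(self._fit({"A": 0.4, "B": 0.0})) == ["A"]

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert rank_proteins(self._fit({"A": 0.0})) == []


class TestIncrementalAUC:
    def _data(self, rng, n=400, p=5):
        X = rng.normal(size=(n, p))
        eta = 2.0 * X[:, 0] + 1.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame(X, columns=[f"P{i}" for i in range(p)]), y

    def test_full_k_consistency_with_all_protein_model(self, rng):
        X, y = self._data(rng)
        tr, te = split_stratified(y, 0.7, seed=0)
        ranking = ["P0", "P1", "P2", "P3", "P4"]
        curve = incremental_auc(ranking, X, y, tr, te)
        assert curve.k_values[-1] == 5
        models = train_classifiers(X[ranking], y, (tr, te), methods=("logistic",))
        assert curve.auc_at_k[-1] == pytest.approx(models["logistic"].auc, abs=1e-9)

    def test_noise_features_hover_at_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("ABCD"))
        y = rng.integers(0, 2, 500)
        tr, te = split_stratified(y, 0.7, seed=1)
        curve = incremental_auc(list("ABCD"), X, y, tr, te)
        assert np.all(np.abs(curve.auc_at_k - 0.5) < 0.15)

    def test_separating_feature_first(self, rng):
        X = pd.DataFrame({"sep": np.r_[np.zeros(50), np.ones(50)],
                          "noise": rng.normal(size=100)})
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        tr, te = split_stratified(y, 0.7, seed=2)
        curve = incremental_auc(["sep", "noise"], X, y, tr, te)
        assert curve.auc_at_k[0] == 1.0

    def test_overlapping_split_rejected(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            incremental_auc(["P0"], X, y, np.arange(10), np.arange(5, 15))


class TestParsimony:
    def test_hand_example(self):
        curve = PanelCurve(k_values=np.arange(1, 7),
                           auc_at_k=np.array([0.70, 0.80, 0.93, 0.935, 0.936,
                                              0.9365]),
                           ranking=list("ABCDEF"))
        k, ids = select_parsimonious(curve, 0.01)
        assert k == 3 and ids == ["A", "B", "C"]

    def test_zero_tolerance_smallest_argmax(self):
        curve = PanelCurve(k_values=np.arange(1, 5),
                           auc_at_k=np.array([0.7, 0.9, 0.9, 0.85]),
                           ranking=list("ABCD"))
        assert select_parsimonious(curve, 0.0)[0] == 2

    def test_decreasing_curve_picks_one(self):
        curve = PanelCurve(k_values=np.arange(1, 4),
                           auc_at_k=np.array([0.9, 0.8, 0.7]),
                           ranking=list("ABC"))
        assert select_parsimonious(curve, 0.01)[0] == 1


class TestEndToEndRecovery:
    def test_panel_pipeline_recovers_planted_signal(self, small_cohort):
        """Selection finds the planted mediators; held-out AUC approaches the
        Bayes-optimal AUC computed from the generating model's true score."""
        feats = pd.DataFrame(small_cohort.proteome.values.T,
                             columns=small_cohort.proteome.protein_ids)
        y = small_cohort.participants.masld.to_numpy()
        fit = lasso_logistic_cv(feats, y, n_folds=10, seed=5)
        ranking = rank_proteins(fit)
        tr, te = split_stratified(y, 0.7, seed=5)
        curve = incremental_auc(ranking, feats, y, tr, te)
        k_star, ids = select_parsimonious(curve, 0.01)
        planted = {p for p, f in zip(small_cohort.truth["protein_ids"],
                                     small_cohort.truth["mediator_flags"]) if f}
        assert k_star <= len(planted) + 2
        # Bayes-optimal score: the generating model's true linear predictor
        b = np.array(small_cohort.truth["b_j"])
        exposure = np.array(small_cohort.truth["exposure"])
        eta_true = (small_cohort.truth["direct_c"] * exposure
                    + b @ small_cohort.proteome.values)
        bayes_auc = roc_auc(eta_true[te], y[te]).auc
        assert curve.auc_at_k[k_star - 1] >= bayes_auc - 0.05


class TestClassifiers:
    def test_separable_data_all_methods_near_perfect(self, rng):
        n = 200
        x = np.r_[rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n // 2)]
        X = pd.DataFrame({"a": x, "b": rng.normal(size=n)})
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        split = split_stratified(y, 0.7, seed=0)
        models = train_classifiers(X, y, split, seed=0)
        assert set(models) == {"logistic", "random-forest",
                               "gradient-boosted-trees", "support-vector"}
        for m in models.values():
            assert m.auc >= 0.99

    def test_shuffled_labels_near_chance(self, rng):
        aucs = []
        for rep in range(10):
            X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
            y = rng.integers(0, 2, 150)
            split = split_stratified(y, 0.7, seed=rep)
            models = train_classifiers(X, y, split, seed=rep)
            aucs.append(np.mean([m.auc for m in models.values()]))
        assert 0.4 < np.mean(aucs) < 0.6

    def test_unknown_method_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=list("ab"))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        with pytest.raises(ValueError, match="unknown classifier"):
            train_classifiers(X, y, split_stratified(y, 0.7, seed=0),
                              methods=("nearest-centroid",))

    def test_roc_area_matches_stored_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=list("ab"))
        y = (X.a + rng.normal(size=120) > 0).astype(int)
        models = train_classifiers(X, y, split_stratified(y, 0.7, seed=3),
                                   methods=("logistic",))
        m = models["logistic"]
        assert np.trapezoid(m.roc.tpr, m.roc.fpr) == pytest.approx(m.auc, abs=1e-9)
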