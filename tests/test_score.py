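"""Penalized logistic score model: solver, CV, projection, serialization."""

import numpy as np
import pytest

from morphoscore.score import (ScoreModel, auc_mann_whitney, fit_score_model,
                               loo_cv_auc, project_scores, _fit_once)


def _toy_binary(n=60, p=6, seed=0, strength=1.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    w = rng.standard_normal(p)
    eta = strength * (x @ w) / np.sqrt(p)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    icv = rng.normal(1.5e6, 1e5, n)
    return x, y, icv


def irls_ridge_logistic(x_std, icv_std, y, lam, tol=1e-12):
    """Independent oracle: Newton/IRLS on the same objective, ridge on the
    feature block only; intercept and ICV unpenalized."""
    n, p = x_std.shape
    a = np.column_stack([np.ones(n), icv_std, x_std])
    d = np.zeros(p + 2)
    d[2:] = lam
    th = np.zeros(p + 2)
    for _ in range(500):
        mu = 1 / (1 + np.exp(-(a @ th)))
        g = a.T @ (mu - y) / n + d * th
        h = (a * (mu * (1 - mu))[:, None]).T @ a / n + np.diag(d)
        th -= np.linalg.solve(h, g)
        if np.max(np.abs(g)) < tol:
            break
    return th


class TestAuc:
    def test_constant_scores_give_half(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        assert auc_mann_whitney(np.full(6, 0.4), y) == 0.5

    def test_perfect_separation_gives_one(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        assert auc_mann_whitney(s, y) == 1.0

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(7)
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        s = np.round(rng.random(6), 1)        # induce some ties
        wins = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                wins += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert auc_mann_whitney(s, y) == pytest.approx(wins / 9, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney(np.ones(4), np.ones(4))


class TestFit:
    def test_full_shrinkage_leaves_only_intercept_and_icv(self):
        x, y, icv = _toy_binary()
        model, _ = fit_score_model(x, y, icv, lambda_grid=[1e6])
        assert np.all(model.weights == 0.0)
        s = project_scores(model, x, icv)
        assert np.all((s > 0) & (s < 1))

    def test_ridge_solution_matches_irls_oracle(self):
        x, y, icv = _toy_binary(n=40, p=10, seed=3)
        lam = 0.1
        theta, (mu, sd, imu, isd), _, _ = _fit_once(
            x, y, icv, lam, alpha=0.0, tol=1e-15, max_iter=500_000)
        th_oracle = irls_ridge_logistic((x - mu) / sd, (icv - imu) / isd, y, lam)
        assert np.max(np.abs(theta - th_oracle)) < 1e-6

    def test_zero_penalty_matches_unpenalized_logistic(self):
        import statsmodels.api as sm
        x, y, icv = _toy_binary(n=300, p=3, seed=5, strength=0.8)
        theta, (mu, sd, imu, isd), _, _ = _fit_once(
            x, y, icv, 0.0, alpha=0.0, tol=1e-14, max_iter=500_000)
        a = np.column_stack([np.ones(300), (icv - imu) / isd, (x - mu) / sd])
        ref = sm.Logit(y, a).fit(disp=0, tol=1e-12)
        assert np.max(np.abs(theta - ref.params)) < 1e-5

    def test_single_class_labels_error(self):
        x, _, icv = _toy_binary()
        with pytest.raises(ValueError, match="single class"):
            fit_score_model(x, np.ones(len(x)), icv)

    def test_nonfinite_feature_names_column(self):
        x, y, icv = _toy_binary()
        x[3, 2] = np.nan
        with pytest.raises(ValueError, match="f2"):
            fit_score_model(x, y, icv)

    def test_objective_decreases_monotonically(self, small_training_set):
        feats, labels, covs = small_training_set
        _, cv = fit_score_model(feats, labels, covs.icv, n_lambda=6)
        path = cv.objective_path
        assert len(path) > 1
        assert all(b <= a + 1e-12 for a, b in zip(path, path[1:]))

    def test_row_permutation_invariance(self):
        x, y, icv = _toy_binary(n=50, p=8, seed=9)
        m1, _ = fit_score_model(x, y, icv, lambda_grid=[0.05], tol=1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(50)
        m2, _ = fit_score_model(x[perm], y[perm], icv[perm],
                                lambda_grid=[0.05], tol=1e-12)
        assert np.max(np.abs(m1.weights - m2.weights)) < 1e-6
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)

    def test_selected_lambda_breaks_ties_upward(self, small_training_set):
        feats, labels, covs = small_training_set
        _, cv = fit_score_model(feats, labels, covs.icv, n_lambda=8)
        best = cv.loo_auc.max()
        top_lams = cv.lambda_grid[cv.loo_auc == best]
        assert cv.selected_lambda == top_lams.max()


class TestLooCv:
    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            loo_cv_auc(np.zeros((2, 2)), np.array([0, 1]), np.ones(2), 0.1)

    def test_strong_separation_reaches_one(self, small_schema):
        from morphoscore.simulate import simulate_case_control
        feats, labels, covs = simulate_case_control(
            10, 8, 4.0, schema=small_schema, seed=2)
        auc = loo_cv_auc(feats, labels, covs.icv, lam=0.05, alpha_mix=0.5)
        assert auc >= 0.95


class TestProjection:
    def test_zero_model_scores_half(self):
        names = np.array([f"f{i}" for i in range(4)], dtype=object)
        model = ScoreModel(np.zeros(4), 0.0, 0.0, names, np.zeros(4),
                           np.ones(4), 0.0, 1.0, 0.1, 0.5)
        s = project_scores(model, np.random.default_rng(0).normal(size=(7, 4)),
                           np.zeros(7))
        assert np.allclose(s, 0.5)

    def test_scores_strictly_inside_unit_interval(self, small_training_set):
        feats, labels, covs = small_training_set
        model, _ = fit_score_model(feats, labels, covs.icv, n_lambda=4)
        s = project_scores(model, feats, covs.icv)
        assert np.all(s > 0) and np.all(s < 1)

    def test_score_monotone_in_single_feature(self):
        names = np.array(["f0"], dtype=object)
        model = ScoreModel(np.array([2.0]), 0.0, 0.0, names, np.zeros(1),
                           np.ones(1), 0.0, 1.0, 0.1, 0.5)
        grid = np.linspace(-3, 3, 25).reshape(-1, 1)
        s = project_scores(model, grid, np.zeros(25))
        assert np.all(np.diff(s) > 0)

    def test_projection_reproduces_insample_probabilities(self):
        x, y, icv = _toy_binary(n=50, p=5, seed=1)
        model, _ = fit_score_model(x, y, icv, lambda_grid=[0.02], tol=1e-12)
        s = project_scores(model, x, icv)
        xs = (x - model.feature_mean) / model.feature_sd
        eta = (model.intercept + model.icv_coef
               * (icv - model.icv_mean) / model.icv_sd + xs @ model.weights)
        assert np.allclose(s, 1 / (1 + np.exp(-eta)), atol=1e-12)

    def test_schema_mismatch_lists_columns(self, small_training_set):
        feats, labels, covs = small_training_set
        model, _ = fit_score_model(feats, labels, covs.icv, n_lambda=3)
        bad = feats.values[:, :-1]
        with pytest.raises(ValueError, match="missing"):
            project_scores(model, bad, covs.icv)

    def test_column_reordering_is_realigned(self):
        x, y, icv = _toy_binary(n=40, p=5, seed=2)
        from morphoscore.simulate import FeatureMatrix
        names = np.array([f"f{i}" for i in range(5)], dtype=object)
        fm = FeatureMatrix(np.arange(40).astype(object), names, x)
        model, _ = fit_score_model(fm, y, icv, lambda_grid=[0.05])
        perm = [3, 1, 4, 0, 2]
        fm2 = FeatureMatrix(fm.subject_ids, names[perm], x[:, perm])
        assert np.allclose(project_scores(model, fm, icv),
                           project_scores(model, fm2, icv))


def test_model_json_roundtrip(tmp_path, small_training_set):
    feats, labels, covs = small_training_set
    model, _ = fit_score_model(feats, labels, covs.icv, n_lambda=3)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ScoreModel.from_json(path)
    assert np.allclose(back.weights, model.weights)
    assert back.lam == model.lam
    s1 = project_scores(model, feats, covs.icv)
    s2 = project_scores(back, feats, covs.icv)
    assert np.allclose(s1, s2)
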