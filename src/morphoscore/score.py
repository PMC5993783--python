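"""Penalized logistic neuroanatomical score: training, CV and projection.

A regularized (elastic-net) logistic regression is trained to discriminate
patients from controls on the standardized morphometry, with the intercept and
an intracranial-volume (ICV) covariate left unpenalized so overall head size
cannot drive the classification.  The fitted linear rule, squashed through the
logistic function, defines a composite score in (0, 1) that is projected onto
new cohorts without any refitting.

The optimizer is a monotone FISTA (proximal gradient with Nesterov momentum
and a monotonicity safeguard) on the objective

    mean NLL + lam * [ alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2 ]

where only the morphometry weights w are penalized.  The L2 part is folded
into the smooth term; the L1 part is handled by soft thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["ScoreModel", "CvReport", "fit_score_model", "loo_cv_auc",
           "project_scores", "auc_mann_whitney"]


@dataclass
class ScoreModel:
    """Trained discriminant: penalized weights + training standardization."""

    weights: np.ndarray          # penalized coefficients, standardized scale
    intercept: float
    icv_coef: float              # unpenalized ICV coefficient
    feature_names: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray       # zero-variance features carry sd = 1, weight 0
    icv_mean: float
    icv_sd: float
    lam: float
    alpha_mix: float

    def to_json(self, path) -> None:
        obj = {
            "format": "morphoscore-model-v1",
            "intercept": self.intercept, "icv_coef": self.icv_coef,
            "icv_mean": self.icv_mean, "icv_sd": self.icv_sd,
            "lam": self.lam, "alpha_mix": self.alpha_mix,
            "feature_names": list(map(str, self.feature_names)),
            "weights": self.weights.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format") != "morphoscore-model-v1":
            raise ValueError("unrecognized model file format")
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]), icv_coef=float(obj["icv_coef"]),
            feature_names=np.asarray(obj["feature_names"], dtype=object),
            feature_mean=np.asarray(obj["feature_mean"], dtype=float),
            feature_sd=np.asarray(obj["feature_sd"], dtype=float),
            icv_mean=float(obj["icv_mean"]), icv_sd=float(obj["icv_sd"]),
            lam=float(obj["lam"]), alpha_mix=float(obj["alpha_mix"]),
        )


@dataclass
class CvReport:
    lambda_grid: np.ndarray
    loo_auc: np.ndarray          # one LOO-CV AUC per lambda
    selected_lambda: float
    insample_auc: float
    objective_path: list = field(default_factory=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # stable log(1 + exp(x))
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _standardize(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, mu, sd_safe


class _PenalizedLogistic:
    """Monotone FISTA solver on a fixed standardized design.

    Design columns: [intercept | unpenalized block | penalized block].
    """

    def __init__(self, a_unpen: np.ndarray, a_pen: np.ndarray, y: np.ndarray):
        self.u = a_unpen                 # (n, q) incl. intercept column
        self.x = a_pen                   # (n, p)
        self.y = y.astype(float)
        self.n = len(y)
        self._lip_quad = self._spectral_norm_sq() / (4.0 * self.n)

    def _spectral_norm_sq(self) -> float:
        d = self.u.shape[1] + self.x.shape[1]
        v = np.full(d, 1.0 / np.sqrt(d))
        for _ in range(60):
            av = self.u @ v[:self.u.shape[1]] + self.x @ v[self.u.shape[1]:]
            atv = np.concatenate([self.u.T @ av, self.x.T @ av])
            nrm = np.linalg.norm(atv)
            if nrm == 0:
                return 0.0
            v = atv / nrm
        return float(nrm)

    def _linpred(self, theta):
        q = self.u.shape[1]
        return self.u @ theta[:q] + self.x @ theta[q:]

    def objective(self, theta, lam, alpha) -> float:
        q = self.u.shape[1]
        eta = self._linpred(theta)
        nll = float(np.mean(_log1pexp(eta) - self.y * eta))
        w = theta[q:]
        return nll + lam * (alpha * float(np.abs(w).sum())
                            + 0.5 * (1 - alpha) * float(w @ w))

    def _smooth_grad(self, theta, lam, alpha):
        q = self.u.shape[1]
        resid = _sigmoid(self._linpred(theta)) - self.y
        g = np.concatenate([self.u.T @ resid, self.x.T @ resid]) / self.n
        g[q:] += lam * (1 - alpha) * theta[q:]
        return g

    def fit(self, lam, alpha, tol=1e-8, max_iter=10_000, theta0=None,
            track_objective=False):
        q = self.u.shape[1]
        d = q + self.x.shape[1]
        theta = np.zeros(d) if theta0 is None else theta0.copy()
        lip = self._lip_quad + lam * (1 - alpha) + 1e-12
        step = 1.0 / lip
        thresh = lam * alpha * step

        def prox_step(point):
            g = self._smooth_grad(point, lam, alpha)
            cand = point - step * g
            cand[q:] = np.sign(cand[q:]) * np.maximum(np.abs(cand[q:]) - thresh, 0.0)
            return cand

        zk = theta.copy()
        t_mom = 1.0
        obj = self.objective(theta, lam, alpha)
        path = [obj] if track_objective else None
        it = 0
        while it < max_iter:
            it += 1
            cand = prox_step(zk)
            obj_cand = self.objective(cand, lam, alpha)
            if obj_cand > obj:
                # momentum overshoot: restart; a plain step that cannot
                # improve means we are at the optimum
                if np.array_equal(zk, theta):
                    break
                zk = theta.copy()
                t_mom = 1.0
                continue
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
            zk = cand + ((t_mom - 1.0) / t_new) * (cand - theta)
            improved = obj - obj_cand
            theta, obj, t_mom = cand, obj_cand, t_new
            if track_objective:
                path.append(obj)
            if improved < tol * max(1.0, abs(obj)):
                # confirm with a plain proximal-gradient step from theta
                cand2 = prox_step(theta)
                obj2 = self.objective(cand2, lam, alpha)
                gain = obj - obj2
                if obj2 < obj:
                    theta, obj = cand2, obj2
                    if track_objective:
                        path.append(obj)
                if gain < tol * max(1.0, abs(obj)):
                    break
                zk = theta.copy()
                t_mom = 1.0
        return theta, obj, path


def _elastic_path(unpen: np.ndarray, xs: np.ndarray, y: np.ndarray,
                  lambdas: np.ndarray, alpha: float, tol: float,
                  max_iter: int) -> np.ndarray:
    """Warm-started solutions along a descending lambda grid.

    For alpha > 0 the penalized columns are screened with the sequential
    strong rule |x_j' r| >= alpha (2 lam_k - lam_{k-1}); every solution is
    verified against the full KKT conditions and violators re-enter, so the
    result is exact, not approximate.
    """
    n, p = xs.shape
    q = unpen.shape[1]
    thetas = np.zeros((len(lambdas), q + p))
    if alpha <= 0.0 or p == 0:
        solver = _PenalizedLogistic(unpen, xs, y)
        th = None
        for k, lam in enumerate(lambdas):
            th, _, _ = solver.fit(lam, alpha, tol, max_iter, th)
            thetas[k] = th
        return thetas

    theta = np.zeros(q + p)
    base = _PenalizedLogistic(unpen, xs[:, :0], y)
    th0, _, _ = base.fit(0.0, alpha, tol, max_iter)
    theta[:q] = th0
    lam_prev = float(lambdas[0])
    for k, lam in enumerate(lambdas):
        eta = unpen @ theta[:q] + xs @ theta[q:]
        grad = np.abs(xs.T @ (_sigmoid(eta) - y)) / n
        keep = (grad >= alpha * (2.0 * lam - lam_prev)) | (theta[q:] != 0.0)
        for _ in range(20):
            idx = np.flatnonzero(keep)
            sub = _PenalizedLogistic(unpen, xs[:, idx], y)
            th_init = np.concatenate([theta[:q], theta[q + idx]])
            th_sub, _, _ = sub.fit(lam, alpha, tol, max_iter, th_init)
            theta = np.zeros(q + p)
            theta[:q] = th_sub[:q]
            theta[q + idx] = th_sub[q:]
            eta = unpen @ th_sub[:q] + xs[:, idx] @ th_sub[q:]
            grad = np.abs(xs.T @ (_sigmoid(eta) - y)) / n
            viol = (grad > alpha * lam * (1.0 + 1e-4)) & ~keep
            if not viol.any():
                break
            keep |= viol
        thetas[k] = theta
        lam_prev = lam
    return thetas


def _check_features(values: np.ndarray, names) -> None:
    bad = ~np.all(np.isfinite(values), axis=0)
    if bad.any():
        culprit = np.asarray(names)[bad][:5]
        raise ValueError(f"non-finite feature values in column(s): {list(culprit)}")


def _as_matrix(features):
    """Accept a FeatureMatrix or a bare 2-D array."""
    if hasattr(features, "values") and hasattr(features, "feature_names"):
        return np.asarray(features.values, float), np.asarray(features.feature_names)
    arr = np.asarray(features, dtype=float)
    names = np.array([f"f{i}" for i in range(arr.shape[1])], dtype=object)
    return arr, names


def default_lambda_grid(x_std: np.ndarray, y: np.ndarray, alpha: float,
                        n_lambda: int = 30, ratio: float = 0.01) -> np.ndarray:
    """glmnet-style grid: log-spaced from the smallest full-shrinkage lambda."""
    n = len(y)
    a = max(alpha, 1e-3)
    lam_max = float(np.max(np.abs(x_std.T @ (y - y.mean()))) / (n * a))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_once(x, y, icv, lam, alpha, tol, max_iter, theta0=None,
              track_objective=False):
    xs, mu, sd = _standardize(x)
    icv_s, icv_mu, icv_sd = _standardize(icv.reshape(-1, 1))
    unpen = np.column_stack([np.ones(len(y)), icv_s[:, 0]])
    solver = _PenalizedLogistic(unpen, xs, y)
    theta, obj, path = solver.fit(lam, alpha, tol, max_iter, theta0,
                                  track_objective)
    return theta, (mu, sd, float(icv_mu[0]), float(icv_sd[0])), obj, path


def loo_cv_auc(features, labels, icv, lam: float, alpha_mix: float = 0.5,
               tol: float = 1e-8, max_iter: int = 10_000) -> float:
    """Leave-one-out CV AUC: each subject scored by a model fit without it."""
    x, _ = _as_matrix(features)
    y = np.asarray(labels, dtype=float)
    icv = np.asarray(icv, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out CV needs n >= 3")
    held_out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            theta, (mu, sd, imu, isd), _, _ = _fit_once(
                x[keep], y[keep], icv[keep], lam, alpha_mix, tol, max_iter)
        except ValueError as err:
            raise ValueError(f"fold holding out index {i}: {err}") from err
        eta = (theta[0] + theta[1] * (icv[i] - imu) / isd
               + (x[i] - mu) / sd @ theta[2:])
        held_out[i] = _sigmoid(np.array([eta]))[0]
    return auc_mann_whitney(held_out, y)


def fit_score_model(features, labels, icv, alpha_mix: float = 0.5,
                    lambda_grid=None, tol: float = 1e-8,
                    max_iter: int = 10_000, n_lambda: int = 30):
    """Train the score model; select lambda by LOO-CV AUC.

    Returns ``(ScoreModel, CvReport)``.  Ties in the CV AUC are broken toward
    the largest (most parsimonious) lambda.
    """
    x, names = _as_matrix(features)
    y = np.asarray(labels, dtype=float)
    icv = np.asarray(icv, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; need cases and controls")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    _check_features(x, names)

    xs_full, _, _ = _standardize(x)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(xs_full, y, alpha_mix, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    n = len(y)
    # fold-outer / lambda-inner so each fold warm-starts along the path
    held = np.empty((len(lambda_grid), n))
    for i in range(n):
        keep = np.arange(n) != i
        xs_k, mu_k, sd_k = _standardize(x[keep])
        icv_s, icv_mu, icv_sd = _standardize(icv[keep].reshape(-1, 1))
        unpen = np.column_stack([np.ones(int(keep.sum())), icv_s[:, 0]])
        thetas = _elastic_path(unpen, xs_k, y[keep], lambda_grid, alpha_mix,
                               tol, max_iter)
        x_i = (x[i] - mu_k) / sd_k
        icv_i = (icv[i] - icv_mu[0]) / icv_sd[0]
        held[:, i] = thetas[:, 0] + thetas[:, 1] * icv_i + thetas[:, 2:] @ x_i
    aucs = np.array([auc_mann_whitney(held[j], y) for j in range(len(lambda_grid))])
    best = int(np.argmax(aucs))        # grid is descending: first max = largest lam
    lam_sel = float(lambda_grid[best])

    # warm-start the final full-data fit from the screened path, then polish
    # with the full-design solver so the tracked objective is exact
    icv_f, _, _ = _standardize(icv.reshape(-1, 1))
    unpen_f = np.column_stack([np.ones(n), icv_f[:, 0]])
    warm = _elastic_path(unpen_f, xs_full, y, lambda_grid[:best + 1],
                         alpha_mix, tol, max_iter)[-1]
    theta, (mu, sd, imu, isd), _, path = _fit_once(
        x, y, icv, lam_sel, alpha_mix, tol, max_iter, theta0=warm,
        track_objective=True)
    model = ScoreModel(
        weights=theta[2:], intercept=float(theta[0]), icv_coef=float(theta[1]),
        feature_names=names, feature_mean=mu, feature_sd=sd,
        icv_mean=imu, icv_sd=isd, lam=lam_sel, alpha_mix=float(alpha_mix))
    insample = auc_mann_whitney(project_scores(model, features, icv), y)
    report = CvReport(lambda_grid=lambda_grid, loo_auc=aucs,
                      selected_lambda=lam_sel, insample_auc=insample,
                      objective_path=path)
    return model, report


def project_scores(model: ScoreModel, features, icv) -> np.ndarray:
    """Apply a trained model to new subjects; no refitting, scores in (0, 1)."""
    x, names = _as_matrix(features)
    icv = np.asarray(icv, dtype=float)
    train = list(map(str, model.feature_names))
    new = list(map(str, names))
    if train != new:
        missing = sorted(set(train) - set(new))[:5]
        extra = sorted(set(new) - set(train))[:5]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {missing}, unexpected {extra}")
        # same set, different order: realign to the training order
        order = {nm: k for k, nm in enumerate(new)}
        x = x[:, [order[nm] for nm in train]]
    eta = (model.intercept
           + model.icv_coef * (icv - model.icv_mean) / model.icv_sd
           + (x - model.feature_mean) / model.feature_sd @ model.weights)
    return _sigmoid(eta)
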