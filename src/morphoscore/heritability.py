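"""SNP-heritability: GRM construction and REML variance components.

The genetic relationship matrix uses the standard GCTA estimator

    A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with p_i the sample alternate-allele frequency.  SNP-heritability of a
phenotype y with fixed covariates X is estimated from the mixed model

    y = X b + g + e,   V = sigma2_g * A + sigma2_e * I

by restricted maximum likelihood.  The solver works in the eigenbasis of A
(one eigendecomposition, then O(n) likelihood evaluations) and uses
average-information updates with an expectation-maximization fallback whenever
an AI step leaves the parameter space or decreases the restricted likelihood.
Standard errors of h2 come from the delta method on the inverse AI matrix, and
the test of sigma2_g = 0 uses the boundary-corrected 50:50 chi-square mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import Genotypes

__all__ = ["Grm", "VarianceComponents", "compute_grm", "reml_fit", "lrt_pvalue"]

_VAR_FLOOR_FRAC = 1e-8


@dataclass
class Grm:
    subject_ids: np.ndarray
    matrix: np.ndarray
    n_snps: int

    def __post_init__(self):
        if self.matrix.shape != (len(self.subject_ids),) * 2:
            raise ValueError("GRM must be square with one row per subject")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float           # restricted log-likelihood at the optimum
    loglik_null: float      # restricted log-likelihood with sigma2_g = 0
    lrt_p: float
    converged: bool
    n_iter: int


def compute_grm(genotypes, maf_min: float = 0.01) -> Grm:
    """GCTA-estimator GRM; SNPs below ``maf_min`` excluded, NaNs mean-imputed."""
    if isinstance(genotypes, Genotypes):
        dosage = np.array(genotypes.dosage, dtype=float)
        ids = genotypes.subject_ids
    else:
        dosage = np.array(genotypes, dtype=float)
        ids = np.array([f"S{i:05d}" for i in range(dosage.shape[0])], dtype=object)
    n, m = dosage.shape
    col_mean = np.nanmean(dosage, axis=0)
    nan_r, nan_c = np.where(np.isnan(dosage))
    dosage[nan_r, nan_c] = col_mean[nan_c]
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError(f"all {m} SNPs fall below maf_min={maf_min}")
    z = (dosage[:, keep] - 2.0 * p[keep]) / np.sqrt(2.0 * p[keep] * (1.0 - p[keep]))
    mm = int(keep.sum())
    a = (z @ z.T) / mm
    return Grm(ids, a, mm)


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    x = np.column_stack([np.ones(n), arr])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    return x


class _EigenReml:
    """Restricted likelihood of (sigma2_g, sigma2_e) in the eigenbasis of A."""

    def __init__(self, y: np.ndarray, x: np.ndarray, a: np.ndarray):
        lam, u = np.linalg.eigh(a)
        self.lam = np.maximum(lam, 0.0)     # clip tiny negative eigenvalues
        self.y = u.T @ y
        self.x = u.T @ x
        self.n, self.k = x.shape

    def _core(self, sg: float, se: float):
        d = sg * self.lam + se
        if np.any(d <= 0):
            raise FloatingPointError("singular V")
        dinv = 1.0 / d
        w = self.x * dinv[:, None]
        xtvx = self.x.T @ w
        c = np.linalg.inv(xtvx)
        beta = c @ (w.T @ self.y)
        py = dinv * (self.y - self.x @ beta)
        return d, dinv, w, c, py, xtvx

    def loglik(self, sg: float, se: float) -> float:
        d, _, _, _, py, xtvx = self._core(sg, se)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        return -0.5 * ((self.n - self.k) * np.log(2 * np.pi)
                       + np.log(d).sum() + logdet_x + float(self.y @ py))

    def _apply_p(self, v, dinv, w, c):
        return dinv * v - w @ (c @ (w.T @ v))

    def score_and_ai(self, sg: float, se: float):
        d, dinv, w, c, py, _ = self._core(sg, se)
        lam = self.lam
        # tr(P V_i) = tr(V^-1 V_i) - tr(C X'V^-1 V_i V^-1 X)
        wg = self.x * (lam * dinv ** 2)[:, None]
        we = self.x * (dinv ** 2)[:, None]
        tr_pg = float((lam * dinv).sum() - np.trace(c @ (wg.T @ self.x)))
        tr_pe = float(dinv.sum() - np.trace(c @ (we.T @ self.x)))
        ypgpy = float((lam * py) @ py)
        ypepy = float(py @ py)
        score = np.array([-0.5 * (tr_pg - ypgpy), -0.5 * (tr_pe - ypepy)])
        ag = lam * py
        pag = self._apply_p(ag, dinv, w, c)
        pae = self._apply_p(py, dinv, w, c)
        ai = 0.5 * np.array([[float(ag @ pag), float(ag @ pae)],
                             [float(py @ pag), float(py @ pae)]])
        return score, ai

    def null_fit(self):
        """Closed-form REML with sigma2_g = 0: residual variance of OLS."""
        beta, _, _, _ = np.linalg.lstsq(self.x, self.y, rcond=None)
        rss = float(np.sum((self.y - self.x @ beta) ** 2))
        se = rss / (self.n - self.k)
        return se, self.loglik(0.0, se)


def reml_fit(y, covariates, grm: Grm, tol: float = 1e-6,
             max_iter: int = 100) -> VarianceComponents:
    """AI-REML estimate of (sigma2_g, sigma2_e) and h2 = sg/(sg+se).

    Components are constrained non-negative (clamped at a small floor); the
    restricted likelihood never decreases across accepted iterations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("REML needs at least 30 subjects")
    x = _design(covariates, n)
    if grm.matrix.shape[0] != n:
        raise ValueError("GRM size does not match phenotype length")
    eng = _EigenReml(y, x, grm.matrix)

    se0, ll_null = eng.null_fit()
    floor = max(_VAR_FLOOR_FRAC * se0, 1e-12)
    theta = np.array([0.5 * se0, 0.5 * se0])
    ll = eng.loglik(*theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai = eng.score_and_ai(*theta)

        def _em_step(th):
            s, _ = eng.score_and_ai(*th)
            return np.maximum(th + 2.0 * th ** 2 * s / n, floor)

        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = None
        accepted = None
        if delta is not None:
            # full AI step, then fractional steps along the same (ascent)
            # direction when the full step overshoots past the optimum
            for frac in (1.0, 0.5, 0.25, 0.125, 1 / 16, 1 / 32):
                cand = np.maximum(theta + frac * delta, floor)
                try:
                    ll_cand = eng.loglik(*cand)
                except FloatingPointError:
                    continue
                if ll_cand >= ll - 1e-10:
                    accepted = (cand, ll_cand)
                    break
        if accepted is None:
            cand = _em_step(theta)
            ll_cand = eng.loglik(*cand)
            if ll_cand >= ll - 1e-10:
                accepted = (cand, ll_cand)
            else:
                # step-halve the EM move toward the current point
                for _ in range(12):
                    cand = 0.5 * (cand + theta)
                    ll_cand = eng.loglik(*cand)
                    if ll_cand >= ll - 1e-10:
                        accepted = (cand, ll_cand)
                        break
        if accepted is None:
            converged = True
            break
        new_theta, new_ll = accepted
        done = abs(new_ll - ll) < tol
        theta, ll = new_theta, new_ll
        if done:
            converged = True
            break

    sg, se = float(theta[0]), float(theta[1])
    total = sg + se
    h2 = sg / total
    _, ai = eng.score_and_ai(sg, se)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    grad = np.array([se, -sg]) / total ** 2
    se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    p = lrt_pvalue(ll, ll_null)
    return VarianceComponents(sg, se, float(h2), se_h2, float(ll),
                              float(ll_null), p, converged, it)


def lrt_pvalue(loglik_full: float, loglik_null: float) -> float:
    """Boundary LRT p-value: 0.5 * P(chi2_1 >= 2 dl), 1 when dl <= 0."""
    dl = loglik_full - loglik_null
    if dl < -1e-6:
        raise ValueError("full-model likelihood below the null beyond tolerance")
    if dl <= 0:
        return 1.0
    return float(min(max(0.5 * stats.chi2.sf(2.0 * dl, df=1),
                         np.finfo(float).tiny), 1.0))
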