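"""Per-cohort SNP association of the neuroanatomical score.

Each SNP dosage is tested by ordinary least squares with the score as the
outcome and the dosage plus the standard covariate set (age, age^2, sex, seven
ancestry PCs) as predictors.  The per-allele effect is reported on the 0-1
score scale with its standard error and a two-sided t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Genotypes, CovariateTable

__all__ = ["AssocResult", "associate_snp", "scan_region", "stratify_subjects"]

#: PLINK-compatible summary-statistics columns produced by scan_region.
SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "A1", "BETA", "SE", "T", "P", "N", "COHORT", "FLAG"]


@dataclass
class AssocResult:
    """Single-SNP OLS result in one cohort."""

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    t_stat: float
    p: float
    n: int
    cohort: str = ""
    flagged: bool = False     # monomorphic in this cohort; exclude from meta


def _covariate_matrix(covariates) -> tuple[np.ndarray, list]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, CovariateTable):
        covariates = covariates.assoc_covariates()
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"c{i}" for i in range(arr.shape[1])]


def associate_snp(score, dosage, covariates=None, *, snp_id: str = "snp",
                  effect_allele: str = "A", cohort: str = "") -> AssocResult:
    """OLS of score on dosage + covariates + intercept.

    The dosage coefficient counts copies of ``effect_allele``.  A SNP that is
    monomorphic in the cohort is returned flagged (NaN estimates) rather than
    raising, so meta-analysis can pool the remaining cohorts.
    """
    y = np.asarray(score, dtype=float)
    x = np.asarray(dosage, dtype=float)
    if len(y) != len(x):
        raise ValueError("score and dosage lengths differ")
    cov, cov_names = _covariate_matrix(covariates)
    if cov.size and len(cov) != len(y):
        raise ValueError("covariate row count differs from score length")
    n = len(y)
    k = cov.shape[1] if cov.size else 0
    if n < k + 3:
        raise ValueError("too few subjects for the covariate set")

    if x.std() == 0.0:
        return AssocResult(snp_id, effect_allele, np.nan, np.nan, np.nan,
                           np.nan, n, cohort, flagged=True)

    design = np.column_stack([np.ones(n), x] + ([cov] if k else []))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear covariate columns by incremental rank
        bad = []
        r = np.linalg.matrix_rank(design[:, :2])
        for j in range(k):
            r2 = np.linalg.matrix_rank(design[:, :3 + j])
            if r2 == r:
                bad.append(cov_names[j])
            r = r2
        raise ValueError(f"rank-deficient covariates: {bad or 'dosage collinear'}")

    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - k - 2
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return AssocResult(snp_id, effect_allele, beta, se, t, p, n, cohort)


def scan_region(score, genotypes: Genotypes, covariates=None, *,
                cohort: str = "") -> pd.DataFrame:
    """One AssocResult per panel SNP, in panel (position) order.

    Uses the Frisch-Waugh-Lovell decomposition: the covariates are projected
    out of the score and of every dosage column once, then each SNP needs only
    a single simple regression.  Identical to the full per-SNP OLS.
    """
    y = np.asarray(score, dtype=float)
    d = np.asarray(genotypes.dosage, dtype=float)
    n, m = d.shape
    if len(y) != n:
        raise ValueError("score length must match genotype rows")
    cov, _ = _covariate_matrix(covariates)
    k = cov.shape[1] if cov.size else 0
    z = np.column_stack([np.ones(n)] + ([cov] if k else []))
    q, _ = np.linalg.qr(z)
    y_r = y - q @ (q.T @ y)
    d_r = d - q @ (q.T @ d)

    df = n - k - 2
    sxx = np.einsum("ij,ij->j", d_r, d_r)
    mono = d.std(axis=0) == 0.0
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    beta = (d_r.T @ y_r) / sxx_safe
    resid_ss = (y_r @ y_r) - beta ** 2 * sxx_safe
    se = np.sqrt(np.maximum(resid_ss, 0.0) / df / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)

    panel = genotypes.panel
    out = pd.DataFrame({
        "SNP": panel.snp_id, "CHR": panel.chrom, "POS": panel.pos,
        "A1": panel.alt_allele, "BETA": beta, "SE": se, "T": t, "P": p,
        "N": n, "COHORT": cohort, "FLAG": mono,
    })
    out.loc[mono, ["BETA", "SE", "T", "P"]] = np.nan
    return out


def stratify_subjects(covariates: CovariateTable, rule: str = "age>=16",
                      *, cohort: str | None = None) -> dict:
    """Partition subjects into disjoint, exhaustive labeled subsets.

    ``rule`` is either ``"all"`` (identity partition) or ``"age>=<cut>"``
    splitting at the cut with the boundary in the older stratum.  When
    ``cohort`` is given, only that cohort is split; the rest form a third
    "other" subset.  Empty strata are dropped with a warning.
    """
    n = len(covariates)
    idx = np.arange(n)
    if rule == "all":
        return {"all": idx}
    if not rule.startswith("age>="):
        raise ValueError(f"unknown stratification rule: {rule!r}")
    cut = float(rule[len("age>="):])
    in_scope = np.ones(n, dtype=bool)
    out: dict = {}
    if cohort is not None:
        in_scope = covariates.cohort == cohort
        if (~in_scope).any():
            out["other"] = idx[~in_scope]
    older = in_scope & (covariates.age >= cut)
    younger = in_scope & (covariates.age < cut)
    for name, mask in ((f"age>={cut:g}", older), (f"age<{cut:g}", younger)):
        if mask.any():
            out[name] = idx[mask]
        else:
            warnings.warn(f"stratum {name!r} is empty; skipped", stacklevel=2)
    return out
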