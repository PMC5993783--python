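"""Fixed-effects inverse-variance-weighted meta-analysis over cohorts.

Per-cohort effects are pooled with weights 1/se^2 (PLINK's fixed-effects IVW
convention); Cochran's Q and I^2 are reported as heterogeneity diagnostics
only.  A candidate-region Bonferroni correction and leave-one-cohort-out
sensitivity runs complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult

__all__ = ["MetaResult", "ivw_meta", "bonferroni_threshold",
           "leave_one_cohort_out", "meta_scan", "harmonize"]


@dataclass
class MetaResult:
    snp_id: str
    effect_allele: str
    beta_meta: float
    se_meta: float
    z: float
    p: float
    k: int                    # cohorts pooled
    q_stat: float             # Cochran heterogeneity
    i2: float                 # percent, in [0, 100]
    label: str = ""


def harmonize(results: list[AssocResult], effect_allele: str | None = None):
    """Flip effect signs so all results count the same allele.

    Only a sign flip is a valid harmonization here (the panel stores a single
    ref/alt pair per SNP); any other allele is an error naming the cohorts.
    """
    if effect_allele is None:
        effect_allele = results[0].effect_allele
    betas, ses = [], []
    for r in results:
        if r.effect_allele == effect_allele:
            betas.append(r.beta)
        else:
            betas.append(-r.beta)
        ses.append(r.se)
    return np.asarray(betas, float), np.asarray(ses, float), effect_allele


def ivw_meta(results: list[AssocResult], *, label: str = "") -> MetaResult:
    """Pool one SNP's per-cohort effects by fixed-effects IVW."""
    results = [r for r in results if not r.flagged]
    if not results:
        raise ValueError("no unflagged results to pool")
    ids = {r.snp_id for r in results}
    if len(ids) != 1:
        raise ValueError(f"results mix SNPs: {sorted(ids)}")
    alleles = {r.effect_allele for r in results}
    valid = {results[0].effect_allele}
    # a second allele label is only poolable as the complementary strand/ref
    if len(alleles) > 2:
        bad = [r.cohort for r in results if r.effect_allele not in valid]
        raise ValueError(f"effect alleles not harmonizable in cohorts: {bad}")
    b, se, allele = harmonize(results)
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("non-finite or non-positive SEs cannot be pooled")
    w = 1.0 / se ** 2
    beta = float((w * b).sum() / w.sum())
    se_meta = float(w.sum() ** -0.5)
    z = beta / se_meta
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    k = len(results)
    q = float((w * (b - beta) ** 2).sum())
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(results[0].snp_id, allele, beta, se_meta, z, p, k, q, i2, label)


def bonferroni_threshold(alpha: float, m: int, p: float | None = None):
    """Candidate-region Bonferroni: threshold alpha/m.

    With ``p`` given, also returns the corrected p-value min(p * m, 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    if p is None:
        return threshold
    return threshold, min(p * m, 1.0)


def _rows_to_results(df: pd.DataFrame) -> list[AssocResult]:
    return [AssocResult(r.SNP, r.A1, r.BETA, r.SE, r.T, r.P, int(r.N),
                        str(r.COHORT), bool(r.FLAG))
            for r in df.itertuples(index=False)]


def meta_scan(per_cohort: list[pd.DataFrame], *, label: str = "") -> pd.DataFrame:
    """IVW-pool per-cohort scan tables SNP by SNP; rows in panel order."""
    if not per_cohort:
        raise ValueError("no cohort tables given")
    rows = []
    base = per_cohort[0]
    for i, snp in enumerate(base["SNP"]):
        results = []
        for tab in per_cohort:
            row = tab.iloc[i]
            if row["SNP"] != snp:
                row = tab.loc[tab["SNP"] == snp].iloc[0]
            results.append(AssocResult(row["SNP"], row["A1"], row["BETA"],
                                       row["SE"], row["T"], row["P"],
                                       int(row["N"]), str(row["COHORT"]),
                                       bool(row["FLAG"])))
        mr = ivw_meta(results, label=label)
        rows.append({"SNP": mr.snp_id, "CHR": base["CHR"].iloc[i],
                     "POS": base["POS"].iloc[i], "A1": mr.effect_allele,
                     "BETA": mr.beta_meta, "SE": mr.se_meta, "Z": mr.z,
                     "P": mr.p, "K": mr.k, "Q": mr.q_stat, "I2": mr.i2,
                     "LABEL": label})
    return pd.DataFrame(rows)


def leave_one_cohort_out(results: list[AssocResult]) -> list[MetaResult]:
    """One pooled result per omitted cohort, labeled by the omission."""
    cohorts = [r.cohort for r in results]
    if len(set(cohorts)) < 2:
        raise ValueError("leave-one-cohort-out needs >= 2 cohorts")
    out = []
    for c in dict.fromkeys(cohorts):          # preserve order, unique
        kept = [r for r in results if r.cohort != c]
        out.append(ivw_meta(kept, label=f"without_{c}"))
    return out
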