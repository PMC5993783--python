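"""Synthetic multi-cohort imaging-genetics data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: an LD-structured candidate region of imputed SNP dosages (a 2 Mb,
110-SNP region analog), a high-dimensional morphometry vector (three surface
measures x two hemispheres x 5124 vertices + 16 subcortical volumes = 30,760
features) carrying a planted multivariate disease axis, a small-effect causal
variant, a polygenic background consistent with high SNP-heritability, and
age/sex/ancestry/cohort confounding across five cohorts of fixed sizes.

Genotypes come from a latent-Gaussian threshold model: each haplotype is a
Markov Gaussian chain across SNP positions thresholded at the per-SNP
allele-frequency quantile, so the dosage correlation matrix is positive
semi-definite by construction.  The default candidate-region LD is
haplotype-block structured: blocks of geometric length whose members are
near-duplicates (dosage r^2 ~ 0.97, as imputed panels show), independent
across blocks; a distance-decay mode and custom block layouts are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "SnpPanel", "Genotypes", "FeatureSchema", "FeatureMatrix", "CovariateTable",
    "SyntheticTruth", "CohortDataset", "default_panel", "simulate_genotypes",
    "simulate_cohorts", "simulate_case_control", "empirical_ld",
]

#: Sizes of the five association cohorts (elderly, adult population, adult
#: cognitive, adult clinical-control, pediatric), totalling 1863 subjects.
DEFAULT_COHORT_SIZES = (184, 653, 325, 250, 451)
DEFAULT_COHORT_LABELS = ("adni", "hunt", "ncng", "top", "ping")

#: (mean, sd, low, high) of the truncated-normal age distribution per cohort.
_COHORT_AGES = {
    "adni": (75.0, 6.0, 60.0, 90.0),
    "hunt": (58.0, 10.0, 40.0, 80.0),
    "ncng": (50.0, 15.0, 20.0, 80.0),
    "top": (35.0, 10.0, 18.0, 65.0),
    "ping": (12.0, 5.0, 3.0, 21.0),
}


@dataclass
class SnpPanel:
    """Candidate-region SNP map: ids, coordinates, alleles and target MAFs."""

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    maf: np.ndarray
    #: latent step correlations between consecutive SNPs (length m-1);
    #: generator metadata recorded so genotypes and MAFs share one LD model
    ld_steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("snp_ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing within chrom {c}")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5] for every SNP")

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "ref_allele": self.ref_allele, "alt_allele": self.alt_allele,
            "maf": self.maf,
        })


@dataclass
class Genotypes:
    """Dosage matrix (subjects x SNPs) with its panel; dosages in [0, 2]."""

    subject_ids: np.ndarray
    panel: SnpPanel
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.subject_ids):
            raise ValueError("dosage row count must equal number of subjects")
        if m != len(self.panel):
            raise ValueError("dosage column count must equal panel size")
        if self.dosage.min() < 0 or self.dosage.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    def subset(self, mask: np.ndarray) -> "Genotypes":
        return Genotypes(self.subject_ids[mask], self.panel, self.dosage[mask])


@dataclass(frozen=True)
class FeatureSchema:
    """Morphometry layout: measures x hemispheres x vertices + subcortical."""

    measures: tuple = ("area", "geometry", "sulc")
    hemispheres: tuple = ("lh", "rh")
    n_vertices: int = 5124
    n_subcortical: int = 16

    @property
    def n_features(self) -> int:
        return len(self.measures) * len(self.hemispheres) * self.n_vertices + self.n_subcortical

    def feature_names(self) -> np.ndarray:
        names = [
            f"{m}_{h}_v{v:05d}"
            for m in self.measures
            for h in self.hemispheres
            for v in range(self.n_vertices)
        ]
        names += [f"subcort_{k:02d}" for k in range(self.n_subcortical)]
        return np.asarray(names, dtype=object)


@dataclass
class FeatureMatrix:
    """Per-subject morphometric feature table (no missing values)."""

    subject_ids: np.ndarray
    feature_names: np.ndarray
    values: np.ndarray
    schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape must be (n_subjects, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.subject_ids[mask], self.feature_names,
                             self.values[mask], self.schema)


@dataclass
class CovariateTable:
    """Association covariates: age, age^2, sex, 7 ancestry PCs, ICV, cohort."""

    subject_ids: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    pcs: np.ndarray           # (n, 7), zero mean over the full sample
    icv: np.ndarray           # mm^3
    cohort: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.pcs = np.asarray(self.pcs, dtype=float)
        self.icv = np.asarray(self.icv, dtype=float)
        self.cohort = np.asarray(self.cohort, dtype=object)
        if np.any(self.age <= 0):
            raise ValueError("ages must be positive")
        if self.pcs.shape != (len(self.age), 7):
            raise ValueError("pcs must have shape (n, 7)")

    @property
    def age_sq(self) -> np.ndarray:
        return self.age ** 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "age": self.age,
                           "age_sq": self.age_sq, "sex": self.sex})
        for k in range(7):
            df[f"pc{k + 1}"] = self.pcs[:, k]
        df["icv"] = self.icv
        df["cohort"] = self.cohort
        return df

    def assoc_covariates(self) -> pd.DataFrame:
        """The standard association covariate set: age, age^2, sex, PC1-PC7."""
        df = pd.DataFrame({"age": self.age, "age_sq": self.age_sq, "sex": self.sex})
        for k in range(7):
            df[f"pc{k + 1}"] = self.pcs[:, k]
        return df

    def subset(self, mask: np.ndarray) -> "CovariateTable":
        return CovariateTable(self.subject_ids[mask], self.age[mask], self.sex[mask],
                              self.pcs[mask], self.icv[mask], self.cohort[mask])

    def __len__(self) -> int:
        return len(self.age)


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded with every generated dataset."""

    w_true: np.ndarray            # disease axis in feature space (incl. amplitude)
    causal_snp_id: str
    beta_causal: float            # per-allele effect on the latent score
    h2_true: float
    delta_case: float             # case-group shift in pooled-SD units
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")


@dataclass
class CohortDataset:
    """Bundle returned by :func:`simulate_cohorts`.

    Holds the candidate-region genotypes, the independent polygenic background
    panel (used for GRM/heritability), the morphometry, the covariates and the
    planted truth.  ``latent_score`` is the noiseless quantitative phenotype
    the features encode; downstream analyses must recover it from the features.
    """

    region: Genotypes
    region_ld: np.ndarray
    background: Genotypes
    features: FeatureMatrix
    covariates: CovariateTable
    truth: SyntheticTruth
    latent_score: np.ndarray

    @property
    def cohort_labels(self) -> np.ndarray:
        return np.unique(self.covariates.cohort)


def _check_maf_range(maf_range) -> tuple:
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not 0.0 < lo <= 0.5:
        raise ValueError(f"maf_range lower bound {lo} outside (0, 0.5]")
    if not 0.0 < hi <= 0.5:
        raise ValueError(f"maf_range upper bound {hi} outside (0, 0.5]")
    if lo > hi:
        raise ValueError(f"maf_range lower bound {lo} exceeds upper bound {hi}")
    return lo, hi


def _step_correlations(pos: np.ndarray, decay: float) -> np.ndarray:
    """Markov-chain step correlation between consecutive SNPs.

    ``decay`` is the latent correlation at the mean marker spacing, so close
    SNP pairs approach correlation 1 (near-perfect proxies, as imputed panels
    show) while distant pairs decorrelate.
    """
    m = len(pos)
    if m <= 1 or decay <= 0.0:
        return np.zeros(max(m - 1, 0))
    gaps = np.diff(pos).astype(float)
    mean_gap = (pos[-1] - pos[0]) / max(m - 1, 1)
    return decay ** (gaps / mean_gap)


def default_panel(panel_size: int = 110, *, chrom: str = "7",
                  start: int = 72_000_000, end: int = 74_000_000,
                  maf_range=(0.05, 0.5), ld_decay: float = 0.9999,
                  structure: str = "blocks", block_mean_size: float = 6.0,
                  seed: int = 0) -> SnpPanel:
    """Random synthetic SNP map over the candidate interval.

    Positions are uniform over the interval.  The LD model is recorded as
    per-step latent correlations on the panel:

    - ``structure="blocks"`` (default): haplotype blocks of geometric length
      (mean ``block_mean_size`` SNPs) with within-block step correlation
      ``ld_decay`` and independence across blocks — the bimodal r^2 pattern
      of imputed candidate-region panels, where tightly linked SNPs come in
      near-duplicate clusters;
    - ``structure="distance"``: correlation decays with physical distance,
      ``ld_decay`` at the mean marker spacing.

    MAFs follow a latent chain with the same step correlations, so tightly
    linked SNPs also share allele frequency (a prerequisite for high dosage
    r^2 between neighbours).
    """
    lo, hi = _check_maf_range(maf_range)
    rng = substream(seed, "panel")
    pos = np.sort(rng.choice(np.arange(start, end), size=panel_size, replace=False))
    if structure == "blocks":
        steps = np.full(max(panel_size - 1, 0), float(ld_decay))
        if block_mean_size > 1:
            j = 0
            while j < panel_size - 1:
                size = 1 + rng.geometric(1.0 / (block_mean_size - 1.0 + 1e-12))
                j += size
                if j <= panel_size - 1:
                    steps[j - 1] = 0.0          # block boundary
    elif structure == "distance":
        steps = _step_correlations(pos, ld_decay)
    else:
        raise ValueError(f"unknown LD structure: {structure!r}")
    lm = np.empty(panel_size)
    lm[0] = rng.standard_normal()
    eps = rng.standard_normal(panel_size)
    for j in range(1, panel_size):
        if structure == "blocks":
            # variants in near-perfect LD share their allele frequency
            lm[j] = lm[j - 1] if steps[j - 1] > 0 else eps[j]
        else:
            lm[j] = steps[j - 1] * lm[j - 1] \
                + np.sqrt(1 - steps[j - 1] ** 2) * eps[j]
    mafs = lo + (hi - lo) * norm.cdf(lm)
    mafs = np.clip(mafs, lo, hi)
    bases = np.array(list("ACGT"))
    ref = rng.choice(4, size=panel_size)
    alt = (ref + rng.integers(1, 4, size=panel_size)) % 4
    return SnpPanel(
        snp_id=np.array([f"snp{i:04d}" for i in range(panel_size)], dtype=object),
        chrom=np.full(panel_size, chrom, dtype=object),
        pos=pos, ref_allele=bases[ref], alt_allele=bases[alt], maf=mafs,
        ld_steps=steps,
    )


def empirical_ld(dosage: np.ndarray) -> np.ndarray:
    """Pairwise dosage correlation with unit diagonal; monomorphic SNPs get 0."""
    d = dosage - dosage.mean(axis=0)
    sd = d.std(axis=0)
    ok = sd > 0
    dn = np.zeros_like(d)
    dn[:, ok] = d[:, ok] / sd[ok]
    r = dn.T @ dn / dosage.shape[0]
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _ar1_haplotypes(n: int, thr: np.ndarray, steps: np.ndarray, rng,
                    block_sizes=None) -> np.ndarray:
    """One haplotype per subject: Markov latent Gaussian thresholded at `thr`.

    ``steps[j-1]`` is the latent correlation between SNPs j-1 and j.  With
    `block_sizes` the chain restarts at each block boundary, giving
    block-structured LD with independence across blocks.
    """
    m = len(thr)
    restarts = np.zeros(m, dtype=bool)
    restarts[0] = True
    if block_sizes is not None:
        edges = np.cumsum(block_sizes)
        if edges[-1] != m:
            raise ValueError("block sizes must sum to the panel size")
        restarts[edges[:-1]] = True
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        rho = steps[j - 1]
        if restarts[j] or rho == 0.0:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho ** 2) * eps[:, j]
    return (z < thr).astype(float)


def simulate_genotypes(n_subjects: int, panel: SnpPanel | None = None, *,
                       panel_size: int = 110, ld_decay: float = 0.9999,
                       maf_range=(0.05, 0.5), block_sizes=None, seed: int = 0,
                       subject_prefix: str = "S", stream: str = "genotypes"):
    """Simulate diploid dosages with AR(1)-decaying LD.

    Returns ``(Genotypes, ld)`` where ``ld`` is the empirical dosage
    correlation matrix of the generated sample.  Bit-identical for identical
    arguments and seed.
    """
    if panel_size < 1 and panel is None:
        raise ValueError("panel_size must be >= 1")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    _check_maf_range(maf_range)
    if panel is None:
        panel = default_panel(panel_size, maf_range=maf_range,
                              ld_decay=ld_decay, seed=seed)
    rng = substream(seed, stream)
    thr = norm.ppf(panel.maf)
    if ld_decay == 0.0 and block_sizes is None:
        # independent SNPs: direct Bernoulli thresholding, no chain needed
        dosage = ((rng.random((n_subjects, len(panel))) < panel.maf).astype(float)
                  + (rng.random((n_subjects, len(panel))) < panel.maf))
    else:
        steps = (panel.ld_steps if panel.ld_steps is not None
                 else _step_correlations(panel.pos, ld_decay))
        dosage = (_ar1_haplotypes(n_subjects, thr, steps, rng, block_sizes)
                  + _ar1_haplotypes(n_subjects, thr, steps, rng, block_sizes))
    ids = np.array([f"{subject_prefix}{i:05d}" for i in range(n_subjects)], dtype=object)
    geno = Genotypes(ids, panel, dosage)
    return geno, empirical_ld(dosage)


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    while True:
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))


#: Default morphometry covariance structure: a few shared latent factors
#: (global scaling, regional covariance) carry most of the per-feature
#: variance, with an iid residual on top — the pattern vertex-wise data shows.
#: Factor scales span ~2.5 orders of magnitude (a dominant global-size mode
#: down to fine regional modes), as empirical morphometry eigenspectra do.
DEFAULT_N_FACTORS = 15
DEFAULT_FACTOR_VARIANCE = 0.9
DEFAULT_FACTOR_SPREAD = 300.0


def _factor_loadings(schema: FeatureSchema, n_factors: int,
                     factor_variance: float, noise_sd: float,
                     factor_seed: int,
                     factor_spread: float = DEFAULT_FACTOR_SPREAD
                     ) -> tuple[np.ndarray, float]:
    """Loadings B (p x k) and the iid residual SD.

    Per-feature noise variance is noise_sd^2, split factor_variance : rest
    between the shared factors and the iid component.  Factor l carries a
    per-feature variance share decaying geometrically so the strongest and
    weakest factors differ by ``factor_spread``.  B depends only on
    ``factor_seed`` so training sets and cohorts share the same structure.
    """
    if not 0.0 <= factor_variance < 1.0:
        raise ValueError("factor_variance must lie in [0, 1)")
    rng = substream(factor_seed, "feature-factors")
    if n_factors == 0 or factor_variance == 0.0:
        return np.zeros((schema.n_features, 0)), noise_sd
    shares = factor_spread ** (-np.arange(n_factors) / max(n_factors - 1, 1))
    shares *= factor_variance * noise_sd ** 2 / shares.sum()
    b = rng.standard_normal((schema.n_features, n_factors)) * np.sqrt(shares)
    sd_iid = noise_sd * np.sqrt(1.0 - factor_variance)
    return b, sd_iid


def _planted_axis(schema: FeatureSchema, amplitude: float, rng,
                  loadings: np.ndarray | None = None) -> np.ndarray:
    """Disease axis of length ``amplitude``.

    With factor loadings given, the axis is a random mixture of the
    (normalized) factor directions: disease-related reorganization moves the
    brain along modes of natural anatomical covariation, which is also what
    makes the axis estimable from a small training sample.  Without loadings
    the axis is an arbitrary dense direction.
    """
    if loadings is None or loadings.shape[1] == 0:
        w = rng.standard_normal(schema.n_features)
    else:
        # equal-magnitude random-sign mixture: the axis engages every major
        # mode of covariation, none dominating
        norms = np.linalg.norm(loadings, axis=0)
        signs = rng.choice([-1.0, 1.0], size=loadings.shape[1])
        w = loadings @ (signs / norms)
    return amplitude * w / np.linalg.norm(w)


def _structured_noise(n: int, loadings: np.ndarray, sd_iid: float, rng,
                      chunk: int = 256) -> np.ndarray:
    p, k = loadings.shape
    z = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    out = rng.standard_normal((n, p))
    if sd_iid != 1.0:
        out *= sd_iid
    for i in range(0, n, chunk):
        out[i:i + chunk] += z[i:i + chunk] @ loadings.T
    return out


def _axis_noise_sd(w_unit: np.ndarray, loadings: np.ndarray, sd_iid: float) -> float:
    """Noise SD of the features along the unit axis (the pooled SD)."""
    proj = loadings.T @ w_unit if loadings.size else np.zeros(0)
    return float(np.sqrt(sd_iid ** 2 + float(proj @ proj)))


def _add_rank_one(values: np.ndarray, s: np.ndarray, w: np.ndarray,
                  chunk: int = 256) -> None:
    # in-place outer-product update, chunked to bound transient memory
    for i in range(0, values.shape[0], chunk):
        values[i:i + chunk] += s[i:i + chunk, None] * w[None, :]


def simulate_cohorts(cohort_sizes=DEFAULT_COHORT_SIZES, *,
                     cohort_labels=None, panel: SnpPanel | None = None,
                     schema: FeatureSchema | None = None,
                     truth: SyntheticTruth | None = None,
                     n_background: int = 1000,
                     ld_decay: float = 0.9999, maf_range=(0.05, 0.5),
                     h2_true: float = 0.8, causal_var_frac: float = 0.01,
                     causal_index: int | None = None,
                     axis_amplitude: float = 5.0,
                     feature_noise_sd: float = 1.0,
                     n_factors: int = DEFAULT_N_FACTORS,
                     factor_variance: float = DEFAULT_FACTOR_VARIANCE,
                     scanner_offset_sd: float = 0.3,
                     age_beta: float = -0.2, sex_beta: float = 0.1,
                     pc_beta: float = 0.05,
                     seed: int = 0) -> CohortDataset:
    """Generate the five-cohort association dataset with planted truth.

    The latent quantitative phenotype is

        s = beta_causal * x_causal + polygenic(background) + covariates + noise

    with the genetic share of the covariate-free variance equal to ``h2_true``
    and the single candidate-region causal SNP explaining ``causal_var_frac``
    of it.  Morphometry is ``baseline + s * w_true + noise`` plus an additive
    per-cohort scanner offset, so cohort is a genuine confounder that the
    per-cohort-scan + meta-analysis design must handle.
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError("h2_true must lie in [0, 1]")
    if truth is not None:
        h2_true = truth.h2_true
    cohort_sizes = tuple(int(c) for c in cohort_sizes)
    if len(cohort_sizes) == 0:
        raise ValueError("cohort_sizes must be nonempty")
    if cohort_labels is None:
        cohort_labels = (DEFAULT_COHORT_LABELS[:len(cohort_sizes)]
                         if len(cohort_sizes) <= len(DEFAULT_COHORT_LABELS)
                         else tuple(f"cohort{i + 1}" for i in range(len(cohort_sizes))))
    n = int(sum(cohort_sizes))
    schema = schema or FeatureSchema()
    if panel is None:
        panel = default_panel(ld_decay=ld_decay, seed=seed)
    m = len(panel)

    region, region_ld = simulate_genotypes(
        n, panel, ld_decay=ld_decay, maf_range=maf_range, seed=seed,
        stream="region-genotypes")
    bg_panel = default_panel(n_background, chrom="0", start=1,
                             end=100_000_000, maf_range=maf_range,
                             ld_decay=0.0, seed=seed + 1)
    background, _ = simulate_genotypes(
        n, bg_panel, ld_decay=0.0, maf_range=maf_range, seed=seed,
        stream="background-genotypes")
    background = Genotypes(region.subject_ids, bg_panel, background.dosage)

    rng = substream(seed, "cohorts")

    # --- latent score ------------------------------------------------------
    ci = m // 2 if causal_index is None else int(causal_index)
    xc = region.dosage[:, ci]
    xc_sd = xc.std()
    if xc_sd == 0:
        raise ValueError("causal SNP is monomorphic in the generated sample")
    frac = min(causal_var_frac, h2_true)
    g_causal = np.sqrt(frac) * (xc - xc.mean()) / xc_sd

    bg = background.dosage
    bg_std = (bg - bg.mean(0)) / np.maximum(bg.std(0), 1e-12)
    b = rng.standard_normal(n_background)
    g_poly = bg_std @ b
    tgt = np.sqrt(max(h2_true - frac, 0.0))
    sd = g_poly.std()
    g_poly = g_poly / sd * tgt if sd > 0 and tgt > 0 else np.zeros(n)

    e = rng.standard_normal(n) * np.sqrt(max(1.0 - h2_true, 0.0))
    s_genetic = g_causal + g_poly + e

    # --- covariates --------------------------------------------------------
    labels = np.concatenate([np.full(c, lab, dtype=object)
                             for c, lab in zip(cohort_sizes, cohort_labels)])
    age = np.empty(n)
    for lab in np.unique(labels):
        mask = labels == lab
        mu, sdv, lo, hi = _COHORT_AGES.get(lab, (40.0, 12.0, 18.0, 80.0))
        age[mask] = _truncnorm(rng, mu, sdv, lo, hi, int(mask.sum()))
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 7))
    pcs -= pcs.mean(axis=0)
    icv = rng.normal(1.5e6, 1.2e5, size=n) + 1.0e5 * sex

    age_std = (age - age.mean()) / age.std()
    cov_effect = age_beta * age_std + sex_beta * (sex - sex.mean()) + pcs[:, 0] * pc_beta
    s = s_genetic + cov_effect

    # --- morphometry -------------------------------------------------------
    loadings, sd_iid = _factor_loadings(schema, n_factors, factor_variance,
                                        feature_noise_sd, seed)
    base_rng = substream(seed, "axis")
    if truth is None:
        w_true = _planted_axis(schema, axis_amplitude, base_rng, loadings)
        truth = SyntheticTruth(
            w_true=w_true, causal_snp_id=str(panel.snp_id[ci]),
            beta_causal=float(np.sqrt(frac) / xc_sd), h2_true=float(h2_true),
            delta_case=0.0, seed=int(seed))
    w_true = np.asarray(truth.w_true, dtype=float)
    if w_true.shape != (schema.n_features,):
        raise ValueError("truth.w_true length must match the feature schema")

    values = _structured_noise(n, loadings, sd_iid, rng)
    _add_rank_one(values, s, w_true)
    offsets = rng.normal(0.0, scanner_offset_sd, size=(len(cohort_labels), schema.n_features))
    for k, lab in enumerate(cohort_labels):
        values[labels == lab] += offsets[k]

    features = FeatureMatrix(region.subject_ids, schema.feature_names(), values, schema)
    covs = CovariateTable(region.subject_ids, age, sex, pcs, icv, labels)
    return CohortDataset(region, region_ld, background, features, covs, truth, s)


def simulate_case_control(n_cases: int = 22, n_controls: int = 16,
                          delta_case: float = 3.0, *,
                          schema: FeatureSchema | None = None,
                          w_true: np.ndarray | None = None,
                          feature_noise_sd: float = 1.0,
                          n_factors: int = DEFAULT_N_FACTORS,
                          factor_variance: float = DEFAULT_FACTOR_VARIANCE,
                          factor_seed: int | None = None,
                          icv_reduction_per_sd: float = 1.0 / 30.0,
                          seed: int = 0):
    """Case/control training set shifted `delta_case` pooled-SDs along the axis.

    Returns ``(FeatureMatrix, labels, CovariateTable)`` with labels 1 = case.
    The case group's ICV is reduced in proportion to the anatomical shift
    (``icv_reduction_per_sd * delta_case``, i.e. 10% at the default shift of
    3) so the ICV-as-covariate logic in model training is genuinely exercised
    while ``delta_case = 0`` leaves the two groups fully exchangeable.
    ``factor_seed`` pins the shared noise-factor structure so a training set
    can match the cohorts it will be projected onto (defaults to ``seed``).
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per class")
    if delta_case < 0:
        raise ValueError("delta_case must be non-negative")
    schema = schema or FeatureSchema()
    rng = substream(seed, "case-control")
    loadings, sd_iid = _factor_loadings(
        schema, n_factors, factor_variance, feature_noise_sd,
        seed if factor_seed is None else factor_seed)
    if w_true is None:
        w_true = _planted_axis(schema, 1.0, substream(seed, "axis"), loadings)
    w_unit = np.asarray(w_true, dtype=float)
    w_unit = w_unit / np.linalg.norm(w_unit)

    n = n_cases + n_controls
    labels = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    values = _structured_noise(n, loadings, sd_iid, rng)
    # pooled SD along the axis: noise SD of the features in that direction
    shift = delta_case * _axis_noise_sd(w_unit, loadings, sd_iid)
    _add_rank_one(values, labels * shift, w_unit)

    age = _truncnorm(rng, 28.0, 6.0, 18.0, 50.0, n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = np.zeros((n, 7))
    icv = rng.normal(1.5e6, 1.2e5, size=n) + 1.0e5 * sex
    icv[labels == 1] *= (1.0 - icv_reduction_per_sd * delta_case)
    ids = np.array([f"T{i:04d}" for i in range(n)], dtype=object)
    cohort = np.full(n, "train", dtype=object)
    features = FeatureMatrix(ids, schema.feature_names(), values, schema)
    covs = CovariateTable(ids, age, sex, pcs, icv, cohort)
    return features, labels, covs
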