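"""GRM construction and REML variance components."""

import numpy as np
import pytest

from morphoscore.heritability import (Grm, _design, _EigenReml, compute_grm,
                                      lrt_pvalue, reml_fit)
from morphoscore.simulate import simulate_genotypes
from morphoscore._rng import substream


def _heritable_phenotype(grm, h2, seed, n):
    """Phenotype with genetic values drawn from N(0, h2 * A)."""
    rng = substream(seed, "pheno")
    lam, u = np.linalg.eigh(grm.matrix)
    g = u @ (rng.standard_normal(n) * np.sqrt(np.maximum(lam, 0)))
    if h2 > 0:
        g *= np.sqrt(h2) / g.std()
    else:
        g = np.zeros(n)
    return g + rng.standard_normal(n) * np.sqrt(1 - h2)


class TestGrm:
    def test_hand_worked_four_by_three_table(self):
        # frozen from the estimator formula evaluated by hand:
        # all sample frequencies are 0.5, so entries are multiples of 1/3
        x = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [1, 2, 1]], float)
        grm = compute_grm(x, maf_min=0.01)
        expect = np.array([
            [4 / 3, -2 / 3, -2 / 3, 0.0],
            [-2 / 3, 2 / 3, 0.0, 0.0],
            [-2 / 3, 0.0, 4 / 3, -2 / 3],
            [0.0, 0.0, -2 / 3, 2 / 3]])
        assert np.max(np.abs(grm.matrix - expect)) < 1e-12
        assert grm.n_snps == 3

    def test_duplicated_subject_matches_diagonal(self):
        g, _ = simulate_genotypes(50, panel_size=400, ld_decay=0.0, seed=2)
        d = np.vstack([g.dosage, g.dosage[:1]])
        grm = compute_grm(d, maf_min=0.01)
        assert grm.matrix[0, 50] == pytest.approx(grm.matrix[0, 0], abs=1e-10)

    def test_unrelated_panel_sampling_moments(self):
        n, m = 500, 2000
        g, _ = simulate_genotypes(n, panel_size=m, ld_decay=0.0, seed=7)
        grm = compute_grm(g.dosage, maf_min=0.01)
        off = grm.matrix[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert abs(off.std() * np.sqrt(grm.n_snps) - 1.0) < 0.2
        assert abs(grm.matrix.diagonal().mean() - 1.0) < 0.1

    def test_low_maf_snps_excluded_and_counted(self):
        rng = np.random.default_rng(0)
        common = (rng.random((200, 5)) < 0.3) + (rng.random((200, 5)) < 0.3)
        rare = np.zeros((200, 2))
        rare[0, :] = 1.0                       # maf 1/400
        grm = compute_grm(np.column_stack([common, rare]), maf_min=0.05)
        assert grm.n_snps == 5

    def test_all_snps_filtered_is_error(self):
        with pytest.raises(ValueError, match="maf_min"):
            compute_grm(np.zeros((10, 3)), maf_min=0.01)

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(1)
        d = (rng.random((100, 50)) < 0.4) + (rng.random((100, 50)) < 0.4)
        d = d.astype(float)
        d[3, 7] = np.nan
        grm = compute_grm(d, maf_min=0.01)
        assert np.isfinite(grm.matrix).all()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            Grm(np.array(["a", "b"], dtype=object),
                np.array([[1.0, 0.5], [0.2, 1.0]]), 10)


class TestReml:
    def test_matches_dense_grid_search_oracle(self):
        n = 60
        g, _ = simulate_genotypes(n, panel_size=150, ld_decay=0.0, seed=21)
        grm = compute_grm(g.dosage, maf_min=0.01)
        y = _heritable_phenotype(grm, 0.5, 21, n)
        cov = substream(21, "cov").standard_normal((n, 2))
        vc = reml_fit(y, cov, grm)
        eng = _EigenReml(y, _design(cov, n), grm.matrix)
        sg = np.linspace(max(vc.sigma2_g - 0.3, 1e-4), vc.sigma2_g + 0.3, 60)
        se = np.linspace(max(vc.sigma2_e - 0.3, 1e-4), vc.sigma2_e + 0.3, 60)
        grid_ll = max(eng.loglik(a, b) for a in sg for b in se)
        assert vc.loglik >= grid_ll - 1e-6
        assert vc.converged

    def test_restricted_loglik_improves_from_start(self):
        n = 80
        g, _ = simulate_genotypes(n, panel_size=200, ld_decay=0.0, seed=5)
        grm = compute_grm(g.dosage, maf_min=0.01)
        y = _heritable_phenotype(grm, 0.4, 5, n)
        vc = reml_fit(y, None, grm)
        eng = _EigenReml(y, _design(None, n), grm.matrix)
        se0, _ = eng.null_fit()
        assert vc.loglik >= eng.loglik(0.5 * se0, 0.5 * se0) - 1e-9

    def test_covariate_reparameterization_invariance(self):
        n = 100
        g, _ = simulate_genotypes(n, panel_size=300, ld_decay=0.0, seed=9)
        grm = compute_grm(g.dosage, maf_min=0.01)
        y = _heritable_phenotype(grm, 0.6, 9, n)
        cov = substream(9, "cov").standard_normal((n, 3))
        t = np.array([[2.0, 0.5, 0.0], [0.0, 1.0, -1.0], [1.0, 0.0, 3.0]])
        vc1 = reml_fit(y, cov, grm)
        vc2 = reml_fit(y, cov @ t, grm)
        assert vc1.h2 == pytest.approx(vc2.h2, abs=1e-6)
        assert vc1.sigma2_g == pytest.approx(vc2.sigma2_g, abs=1e-6)
        # the restricted likelihood shifts by the fixed constant log|det T|
        # under X -> XT; the LRT difference is invariant
        shift = np.log(abs(np.linalg.det(t)))
        assert vc2.loglik - vc1.loglik == pytest.approx(-shift, abs=1e-6)
        assert (vc1.loglik - vc1.loglik_null == pytest.approx(
            vc2.loglik - vc2.loglik_null, abs=1e-6))
        assert vc1.lrt_p == pytest.approx(vc2.lrt_p, rel=1e-6)

    def test_null_phenotype_rarely_significant(self):
        n, reps = 300, 200
        hits = 0
        h2s = []
        for rep in range(reps):
            g, _ = simulate_genotypes(n, panel_size=500, ld_decay=0.0,
                                      seed=3000 + rep)
            grm = compute_grm(g.dosage, maf_min=0.01)
            y = substream(3000 + rep, "null").standard_normal(n)
            vc = reml_fit(y, None, grm)
            h2s.append(vc.h2)
            hits += vc.lrt_p < 0.05
        assert np.mean(h2s) < 0.2
        assert hits <= reps * 0.05 + 3 * np.sqrt(reps * 0.05 * 0.95)
        assert (reps - hits) / reps >= 0.90    # non-significant in >=90%

    def test_grm_size_mismatch_rejected(self):
        g, _ = simulate_genotypes(40, panel_size=100, ld_decay=0.0, seed=0)
        grm = compute_grm(g.dosage, maf_min=0.01)
        with pytest.raises(ValueError, match="GRM size"):
            reml_fit(np.zeros(30), None, grm)

    def test_small_sample_rejected(self):
        g, _ = simulate_genotypes(10, panel_size=50, ld_decay=0.0, seed=0)
        grm = compute_grm(g.dosage, maf_min=0.01)
        with pytest.raises(ValueError, match="at least 30"):
            reml_fit(np.zeros(10), None, grm)


class TestLrt:
    def test_zero_improvement_gives_p_one(self):
        assert lrt_pvalue(-10.0, -10.0) == 1.0

    def test_inverse_of_mixture_tail(self):
        assert lrt_pvalue(0.0, -5.4139) == pytest.approx(5e-4, rel=2e-3)

    def test_monotone_decreasing_in_improvement(self):
        ps = [lrt_pvalue(d, 0.0) for d in (0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_full_below_null_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-11.0, -10.0)
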