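"""Synthetic-data generator: genotype LD structure, cohorts, case/control."""

import numpy as np
import pytest

from morphoscore.simulate import (
    DEFAULT_COHORT_SIZES, FeatureSchema, SyntheticTruth, default_panel,
    empirical_ld, simulate_case_control, simulate_cohorts, simulate_genotypes,
)


class TestGenotypes:
    def test_same_seed_gives_bit_identical_dosages(self):
        g1, ld1 = simulate_genotypes(200, panel_size=40, seed=9)
        g2, ld2 = simulate_genotypes(200, panel_size=40, seed=9)
        assert np.array_equal(g1.dosage, g2.dosage)
        assert np.array_equal(ld1, ld2)
        g3, _ = simulate_genotypes(200, panel_size=40, seed=10)
        assert not np.array_equal(g1.dosage, g3.dosage)

    def test_single_snp_ld_is_identity(self):
        _, ld = simulate_genotypes(100, panel_size=1, seed=0)
        assert ld.shape == (1, 1)
        assert ld[0, 0] == 1.0

    def test_independent_snps_have_near_zero_ld(self):
        _, ld = simulate_genotypes(5000, panel_size=40, ld_decay=0.0, seed=2)
        off = ld[~np.eye(40, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.05

    def test_allele_frequencies_recover_target_mafs(self):
        n = 5000
        g, _ = simulate_genotypes(n, panel_size=60, ld_decay=0.5, seed=4)
        freq = g.dosage.mean(axis=0) / 2.0
        obs_maf = np.minimum(freq, 1 - freq)
        se = np.sqrt(g.panel.maf * (1 - g.panel.maf) / (2 * n))
        assert np.all(np.abs(obs_maf - g.panel.maf) < 3.5 * se + 1e-9)

    def test_ld_decays_with_distance_on_average(self):
        _, ld = simulate_genotypes(3000, panel_size=60, ld_decay=0.85, seed=5)
        lag = lambda k: np.mean([abs(ld[i, i + k]) for i in range(60 - k)])
        assert lag(1) > lag(5) > lag(20)

    def test_dosages_within_bounds(self):
        g, _ = simulate_genotypes(500, panel_size=30, seed=1)
        assert g.dosage.min() >= 0 and g.dosage.max() <= 2

    @pytest.mark.parametrize("bad, msg", [
        ((0.0, 0.4), "lower bound"),
        ((0.1, 0.7), "upper bound"),
        ((0.4, 0.1), "exceeds"),
    ])
    def test_invalid_maf_range_names_offending_bound(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_genotypes(10, panel_size=5, maf_range=bad, seed=0)

    def test_block_structure_isolates_blocks(self):
        g, ld = simulate_genotypes(4000, panel_size=40, ld_decay=0.9,
                                   block_sizes=[20, 20], seed=3)
        across = ld[:20, 20:]
        within = np.array([ld[i, i + 1] for i in range(19)])
        assert np.mean(np.abs(across)) < 0.05 < np.mean(np.abs(within))

    def test_block_sizes_must_sum_to_panel(self):
        with pytest.raises(ValueError, match="block sizes"):
            simulate_genotypes(50, panel_size=10, ld_decay=0.5,
                               block_sizes=[4, 4], seed=0)

    def test_panel_positions_lie_in_candidate_interval(self):
        panel = default_panel(110)
        assert np.all(np.diff(panel.pos) > 0)
        assert panel.pos.min() >= 72_000_000 and panel.pos.max() < 74_000_000
        assert len(set(panel.snp_id)) == 110


class TestCohorts:
    def test_default_cohort_sizes_sum_to_1863(self, small_schema):
        ds = simulate_cohorts(schema=small_schema, n_background=50, seed=0)
        assert ds.region.n_subjects == 1863
        assert sum(DEFAULT_COHORT_SIZES) == 1863
        labels, counts = np.unique(ds.covariates.cohort, return_counts=True)
        assert sorted(counts) == sorted(DEFAULT_COHORT_SIZES)

    def test_covariate_invariants(self, small_schema):
        ds = simulate_cohorts((80, 120), schema=small_schema,
                              n_background=50, seed=1)
        cov = ds.covariates
        assert np.all(cov.age > 0)
        assert np.array_equal(cov.age_sq, cov.age ** 2)
        assert np.allclose(cov.pcs.mean(axis=0), 0.0, atol=1e-10)
        assert set(np.unique(cov.sex)) <= {0.0, 1.0}

    def test_h2_outside_unit_interval_rejected(self, small_schema):
        with pytest.raises(ValueError, match="h2_true"):
            simulate_cohorts((50,), schema=small_schema, h2_true=1.4, seed=0)

    def test_reproducible_from_seed(self, small_schema):
        a = simulate_cohorts((60, 40), schema=small_schema, n_background=30, seed=5)
        b = simulate_cohorts((60, 40), schema=small_schema, n_background=30, seed=5)
        assert np.array_equal(a.features.values, b.features.values)
        assert np.array_equal(a.region.dosage, b.region.dosage)
        assert np.array_equal(a.latent_score, b.latent_score)

    def test_zero_axis_features_carry_no_score_signal(self, small_schema):
        truth = SyntheticTruth(
            w_true=np.zeros(small_schema.n_features), causal_snp_id="snp0010",
            beta_causal=0.1, h2_true=0.5, delta_case=0.0, seed=3)
        ds = simulate_cohorts((400,), schema=small_schema, truth=truth,
                              n_background=50, seed=3)
        proj = ds.features.values @ np.ones(small_schema.n_features)
        r = np.corrcoef(proj, ds.latent_score)[0, 1]
        assert abs(r) < 0.12

    def test_causal_snp_explains_stated_score_variance(self, small_schema):
        ds = simulate_cohorts((2000,), schema=small_schema, n_background=200,
                              causal_var_frac=0.05, h2_true=0.6, seed=8)
        ci = list(ds.region.panel.snp_id).index(ds.truth.causal_snp_id)
        x = ds.region.dosage[:, ci]
        r2 = np.corrcoef(x, ds.latent_score)[0, 1] ** 2
        # score includes covariate effects, so the realized share is a bit
        # below the planted genetic share; Monte-Carlo slack on top
        assert 0.015 < r2 < 0.09

    def test_latent_score_heritability_decomposition(self, small_schema):
        ds = simulate_cohorts((2000,), schema=small_schema, n_background=400,
                              h2_true=0.5, age_beta=0.0, sex_beta=0.0,
                              pc_beta=0.0, seed=9)
        bg = ds.background.dosage
        z = (bg - bg.mean(0)) / np.maximum(bg.std(0), 1e-12)
        # regression of the score on the true generating panel recovers the
        # genetic share h2 (plus the small causal-SNP contribution)
        beta = np.linalg.lstsq(z, ds.latent_score - ds.latent_score.mean(),
                               rcond=None)[0]
        g = z @ beta
        share = g.var() / ds.latent_score.var()
        assert abs(share - ds.truth.h2_true) < 0.2

    def test_scanner_offsets_differ_between_cohorts(self, small_schema):
        ds = simulate_cohorts((300, 300), schema=small_schema,
                              n_background=30, scanner_offset_sd=1.0, seed=2)
        labs = np.unique(ds.covariates.cohort)
        m0 = ds.features.values[ds.covariates.cohort == labs[0]].mean(axis=0)
        m1 = ds.features.values[ds.covariates.cohort == labs[1]].mean(axis=0)
        assert np.std(m0 - m1) > 0.5


class TestCaseControl:
    def test_default_training_set_has_38_rows(self, small_schema):
        feats, labels, covs = simulate_case_control(schema=small_schema, seed=0)
        assert feats.values.shape[0] == 38
        assert int(labels.sum()) == 22 and int((1 - labels).sum()) == 16

    def test_case_icv_reduced_at_default_shift(self, small_schema):
        feats, labels, covs = simulate_case_control(schema=small_schema, seed=4)
        assert covs.icv[labels == 1].mean() < covs.icv[labels == 0].mean()

    def test_groups_exchangeable_at_zero_shift(self, small_schema):
        feats, labels, covs = simulate_case_control(
            30, 30, 0.0, schema=small_schema, seed=6)
        diff = (feats.values[labels == 1].mean(0)
                - feats.values[labels == 0].mean(0))
        pooled = feats.values.std(0)
        assert np.mean(np.abs(diff) / pooled) < 0.5
        # ICV shows no group effect either
        t = abs(covs.icv[labels == 1].mean() - covs.icv[labels == 0].mean())
        assert t < 3 * covs.icv.std() / np.sqrt(15)

    def test_negative_shift_rejected(self, small_schema):
        with pytest.raises(ValueError, match="delta_case"):
            simulate_case_control(5, 5, -1.0, schema=small_schema, seed=0)

    def test_minimum_group_size_enforced(self, small_schema):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_case_control(1, 5, 1.0, schema=small_schema, seed=0)


def test_empirical_ld_handles_monomorphic_columns():
    d = np.array([[0, 1.0], [0, 2.0], [0, 0.0]])
    ld = empirical_ld(d)
    assert ld[0, 0] == 1.0 and ld[1, 1] == 1.0
    assert ld[0, 1] == 0.0


def test_default_schema_is_30760_features():
    assert FeatureSchema().n_features == 30760
    assert len(FeatureSchema().feature_names()) == 30760
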