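"""Per-cohort SNP association and IVW meta-analysis over the 110-SNP region.

Each cohort is scanned separately (score ~ dosage + age + age^2 + sex +
PC1-7), the per-cohort effects are pooled by fixed-effects inverse-variance
weighting, and the candidate-region Bonferroni threshold is applied.
"""

import pandas as pd

from morphoscore import FeatureSchema, bonferroni_threshold, meta_scan, \
    scan_region, simulate_cohorts

schema = FeatureSchema(n_vertices=5, n_subcortical=4)
ds = simulate_cohorts(schema=schema, n_background=100, seed=11)
covs = ds.covariates

tables = []
for lab in pd.unique(covs.cohort):
    mask = covs.cohort == lab
    tables.append(scan_region(ds.latent_score[mask], ds.region.subset(mask),
                              covs.subset(mask).assoc_covariates(),
                              cohort=str(lab)))
    print(f"cohort {lab}: n={int(mask.sum())}, "
          f"min p = {tables[-1]['P'].min():.2e}")

meta = meta_scan(tables)
thr = bonferroni_threshold(0.05, len(meta))
top = meta.loc[meta["P"].idxmin()]
_, p_corr = bonferroni_threshold(0.05, len(meta), float(top["P"]))
print(f"\nmeta-analysis over {len(meta)} SNPs, threshold 0.05/110 = {thr:.1e}")
print(f"top SNP {top['SNP']} (allele {top['A1']}): beta = {top['BETA']:.4f} "
      f"per allele on the 0-1 score scale, p = {top['P']:.2e}, "
      f"Bonferroni-corrected p = {p_corr:.3f}")
print("planted causal SNP was:", ds.truth.causal_snp_id,
      "->", "localized" if top["SNP"] == ds.truth.causal_snp_id
      else "top SNP is a linked proxy")
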