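"""Run the whole study design end to end from one config and one seed.

Simulate cohorts -> train the score on a separate case/control set ->
project -> per-cohort scans -> IVW meta + Bonferroni -> fine-mapping ->
QQ enrichment -> GRM/REML heritability.  A second run with the same seed is
bit-identical.
"""

from morphoscore import RunConfig, run_pipeline

config = RunConfig(cohort_sizes=(60, 80, 50, 40, 120), n_vertices=20,
                   n_subcortical=4, n_background=100, n_lambda=6, seed=3)
report = run_pipeline(config)

print("config hash:", report.config_hash)
for stage, out in report.stages.items():
    brief = {k: v for k, v in out.items()
             if not isinstance(v, (list, dict))}
    print(f"  {stage}: {brief}")
if report.errors:
    print("stage errors:", report.errors)

top = report.stages["meta"]
print(f"\ntop SNP {top['top_snp']}: p = {top['top_p']:.2e} "
      f"(threshold {top['bonferroni_threshold']:.1e}, "
      f"significant = {top['significant']})")
h2 = report.stages["heritability"]
print(f"score SNP-heritability: {h2['h2']:.2f} (se {h2['se_h2']:.2f}, "
      f"LRT p = {h2['lrt_p']:.1e})")
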