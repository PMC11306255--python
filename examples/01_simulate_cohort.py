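"""Simulate a small birth-cohort-style longitudinal puberty dataset.

Generates 100 children per sex with nine clinic visits (height, weight,
BMC at the DXA clinics) and nine puberty questionnaires (Tanner stages,
voice breaking, axillary hair, menarche), then prints what was produced.
"""

from pubsitar import SimConfig, simulate_cohort

config = SimConfig(n_per_sex=100, seed=1)
cohort = simulate_cohort(config)

m = cohort.measurements
print(f"measurement rows: {len(m)}  (long format: id, sex, age_months, "
      "measure, value, occasion)")
print(m.groupby("measure").size().rename("n_obs").to_string())
print()
print("first height rows for one child:")
print(m[(m['measure'] == 'height') & (m['id'] == 'F00001')]
      [["age_months", "value"]].to_string(index=False))
print()
print("Ground truth is returned alongside: each child carries per-measure "
      "size/timing/intensity/post-growth effects, e.g. a timing (beta) of "
      "+1 means that child's growth runs one year late.")
truth = cohort.true_effects.per_measure
print(truth[truth["measure"] == "height"].head(3).round(3).to_string(index=False))
print()
print("covariate table columns:", list(cohort.covariates.columns))
print("The standardized puberty GRS is simulated to correlate "
      f"{config.grs_timing_correlation} with the latent timing factor.")
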