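"""Model selection and validation on a synthetic cohort.

Simulates a 14-pigment cohort whose peak absorbances are generated from
the frozen primary model plus 3 nm measurement noise, extracts the seven
covariates, runs exhaustive best-subsets selection ranked by BIC, and
validates the selected pair by leave-one-out cross-validation.
"""

import chromotune as ct

spec = ct.demo_cohort_spec(seed=11, n_frames=400, noise_sd=3.0)
trajectories, cohort = ct.simulate_cohort(spec)
table = ct.build_feature_table(
    trajectories, lambda_max=cohort.set_index("pigment_id")["lambda_max_nm"]
)
print(f"feature table: {len(table)} pigments x {len(ct.COVARIATE_COLUMNS)} covariates")
print(f"lambda_max range: {cohort.lambda_max_nm.min():.1f}"
      f"-{cohort.lambda_max_nm.max():.1f} nm")

ranked = ct.best_subsets(table, nbest=7)
print("\ntop 3 models by BIC:")
for m in ranked[:3]:
    print(f"  {'+'.join(m.covariates):60s} "
          f"R^2={m.fit_stats['r_squared']:.3f} BIC={m.fit_stats['bic']:.2f}")

pair = ["median_torsion15", "auc_rmsf_lysret"]
model = ct.ols_fit(table, pair)
print(f"\nrefit on the generating pair: intercept {model.intercept:.2f}, "
      f"slopes { {k: round(v, 3) for k, v in model.coefficients.items()} }")

loo = ct.loo_validate(table, pair)
print(f"leave-one-out pooled R^2 = {loo.pooled_r2:.3f} "
      f"(1-PRESS/TSS = {loo.press_r2:.3f})")

# With 3 nm noise the recovered slopes sit near the generating values
# (-8.720 deg^-1 and +34.925 per nm*atom) and held-out predictions track
# the generated absorbances closely.
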