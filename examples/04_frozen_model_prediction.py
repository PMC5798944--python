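"""Predicting peak absorbance with the frozen reference models.

Evaluates the two shipped linear models on hand-set feature values and
shows the packaged table of 14 teleost Rh2 pigments used as the
experimental reference.
"""

import chromotune as ct

# Primary model: lambda_max = 475.628 - 8.720*T15_median + 34.925*AUC(RMSF)
row = {"median_torsion15": 2.0, "auc_rmsf_lysret": 1.2}
pred = ct.predict_lambda_max(ct.FROZEN_PRIMARY, row)
print(f"primary model at T15=2.0 deg, AUC=1.2 nm*atom -> {pred:.1f} nm")

# Secondary model built without the cichlid pigments
row2 = {"median_torsion4": 170.0, "median_torsion14": 49.0}
pred2 = ct.predict_lambda_max(ct.FROZEN_SECONDARY, row2)
print(f"secondary model at T4=170 deg, T14=49 deg -> {pred2:.1f} nm")

ref = ct.load_reference_lambda_max()
print(f"\nreference pigments: {len(ref)}, lambda_max "
      f"{ref.lambda_max_nm.min()}-{ref.lambda_max_nm.max()} nm")
print(ref[["pigment_id", "species", "lambda_max_nm"]].to_string(index=False))

# Predictions above 495 nm correspond to green-sensitive pigments,
# below to blue-sensitive ones.
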