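"""Cross-validated prediction of per-fraction gEUD from dose/geometry features.

Leave-one-patient-out random forest and nested-CV multilayer perceptron,
with extra sample weight on clinically critical low-gEUD fractions
(weight 10 below 90%, 2 in 90-95%).  On a cohort where gEUD is a noisy
monotone function of the minimum CTV dose, both models recover the
relation on held-out patients, and D_min dominates the variable
importance - geometric deformation features add little.
"""

import numpy as np

import eudgate as eg
from eudgate.stats import FEATURE_SETS

table = eg.generate_feature_table(seed=0)
weights = eg.make_weights(table["gEUD"])
print(f"{len(table)} fractions from {table['patient_id'].nunique()} patients, "
      f"{(table['gEUD'] < 0.93).sum()} below 93% of prescription")

rf_a = eg.lopo_random_forest(table, FEATURE_SETS["A"], weights, seed=0)
print(f"RF  [D_min only]   held-out R = {rf_a.pearson_r:.3f} "
      f"(95% CI {rf_a.fisher_ci[0]:.3f}-{rf_a.fisher_ci[1]:.3f}), "
      f"VE_cv = {rf_a.ve_cv:.3f}")

rf_f = eg.lopo_random_forest(table, FEATURE_SETS["F"], weights, seed=0)
print(f"RF  [full set]     held-out R = {rf_f.pearson_r:.3f}")
print("    importance:",
      ", ".join(f"{k}={v:.2g}" for k, v in rf_f.importance.items()))

mlp_a = eg.nested_lopo_mlp(table, FEATURE_SETS["A"], weights, seed=0)
print(f"MLP [D_min only]   held-out R = {mlp_a.pearson_r:.3f}")

r_bc = float(np.corrcoef(rf_a.predictions["y_pred"],
                         rf_f.predictions["y_pred"])[0, 1])
z, p = eg.steiger_z_dependent(rf_a.pearson_r, rf_f.pearson_r, r_bc, len(table))
print(f"Steiger Z (D_min-only vs full RF): z = {z:.2f}, p = {p:.3f}")
print()
print("D_min alone predicts the per-fraction gEUD about as well as the full")
print("feature set - the added geometric features do not significantly")
print("improve the held-out correlation.")
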