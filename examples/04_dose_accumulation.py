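"""Deformable dose accumulation and the static-dose-cloud gamma check.

Accumulates the per-fraction delivered dose on the planning anatomy
(static dose cloud: the planned distribution stays fixed while the anatomy
moves through it) and shows that the accumulated gEUD is robust even when
individual fractions are cold.  A gamma comparison (3%/3 mm) between the
plan and a single warped fraction quantifies how benign the deformations
are dose-wise inside CTV+15 mm.
"""

import numpy as np
from scipy.ndimage import distance_transform_edt

import eudgate as eg
from eudgate.accumulation import GammaCriteria
from eudgate.geometry import extract_features

cfg = eg.CohortConfig(
    n_patients=1,
    fractions_range=(8, 8),
    ctv_volume_range=(70.0, 90.0),
    grid_shape=(48, 48, 48),
    use_table_values=False,
    large_excursion_prob=0.2,
    seed=5,
)
series = eg.generate_cohort(cfg)[0]

feats = extract_features(series)
acc, geud_acc, dmin_acc = eg.accumulate(series)
print("per-fraction normalized gEUD_i :",
      np.round(feats["gEUD"].to_numpy(), 3))
print(f"accumulated gEUD_acc           : {geud_acc:.3f}")
print(f"accumulated D_min              : {dmin_acc:.3f}")

dist = distance_transform_edt(~series.ctv_plan.values, sampling=series.grid.spacing)
roi = eg.StructureMask(series.grid, dist <= 15.0)
# delivered (warped) vs planned dose for one fraction: how much the
# interfraction motion redistributes dose inside CTV+15 mm
warped = eg.pullback_dose(series.plan_dose, series.fractions[0][0])
rate = eg.gamma_pass_rate(series.plan_dose, warped, GammaCriteria(), roi)
print(f"gamma 3%/3mm (delivered vs plan): {rate:.3f} for fraction 1")
# the static-dose-cloud check proper compares doses that differ only by a
# small re-gridding-scale perturbation; emulate one at ~1 mm amplitude
from eudgate.synthetic import generate_fraction_field

small = generate_fraction_field(series.grid, random_sd=(1.0, 1.0, 1.0),
                                correlation_length_mm=20.0, seed=1)
perturbed = eg.pullback_dose(series.plan_dose, small)
rate_small = eg.gamma_pass_rate(series.plan_dose, perturbed, GammaCriteria(), roi)
print(f"gamma 3%/3mm (1 mm perturbation): {rate_small:.3f} "
      "(static-dose-cloud scale check)")
print()
print("Even when a single fraction's gEUD dips, the accumulated dose stays")
print("at or above the prescription: random interfraction deformations do")
print("not pile dose deficits onto the same tissue element.")
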