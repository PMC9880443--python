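"""Equivalent uniform dose: power-law gEUD vs the cell-survival EUD_SF.

Builds a dose distribution with a small cold spot and compares the two
effectiveness measures.  With the tumor exponent a = -20 the gEUD is
dominated by the coldest voxels; the survival-based EUD_SF (alpha/beta =
4 Gy, SF2 calibrated so 60 Gy in 2 Gy fractions controls 50% of tumors
with 1e8 clonogens) behaves similarly but weights the cold spot through
the linear-quadratic cell-kill model instead of a power mean.
"""

import numpy as np

import eudgate as eg
from eudgate.eud import DVH, GEUDParams, SFModelParams

sf2 = eg.calibrate_sf2(tcp_target=0.5, total_dose=60.0, dose_per_fraction=2.0, n0=1e8)
print(f"calibrated SF2                 : {sf2:.9f}")

# a CTV receiving 60 Gy except for a 2%-volume cold spot at 45 Gy
dvh = DVH(bin_edges=[0.0, 45.0, 60.0], cum_volume=[1.0, 1.0, 0.98])
geud = eg.geud(dvh, GEUDParams(a=-20.0))
per_fraction = DVH(dvh.bin_edges / 30.0, dvh.cum_volume)
eud_sf = eg.eud_sf(per_fraction, SFModelParams(sf2=sf2, n_fractions=30))

print(f"gEUD (a = -20)                 : {geud:.2f} Gy")
print(f"EUD_SF (30 x 2 Gy course)      : {eud_sf:.2f} Gy")
print(f"mean dose                      : {eg.geud(dvh, GEUDParams(a=1.0)):.2f} Gy")
print()
print("A 2% cold spot at 75% of the prescription pulls both equivalent")
print("uniform doses far below the 59.7 Gy mean - the gEUD to "
      f"{geud/60:.0%} and the EUD_SF to {eud_sf/60:.0%} of 60 Gy - which is")
print("why per-fraction cold spots matter even when the mean dose looks fine.")
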