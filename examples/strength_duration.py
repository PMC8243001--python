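"""Strength-duration analysis of optogenetic excitation (reduced grid).

For each pulse duration the minimal spiking irradiance is found by
bisection; the Hill-Lapicque model is fit to the threshold temporal
average current (TAC), and a power series maps TAC back to irradiance,
yielding rheobase and chronaxie in both domains.  An 8-point grid keeps
this example around a minute; the full analysis uses 15 points.
"""

import numpy as np

from opsinkit import fixture, rs_neuron
from opsinkit.sdc import build_sdc

result = build_sdc(fixture("rsrs_final"), rs_neuron(),
                   pd_grid_s=np.geomspace(1e-2, 1.0, 8))

print("PD (ms)   threshold (W/m^2)   threshold TAC (uA/cm^2)")
for pd, irr, tac in zip(result.pd_s, result.threshold_irradiance_W_m2,
                        result.threshold_tac_uA_cm2):
    print(f"{pd * 1e3:7.1f} {irr:15.2f} {tac:18.3f}")

print(f"\nTAC rheobase   {result.tac_rheobase_uA_cm2:6.3f} uA/cm^2   "
      f"chronaxie {result.tac_chronaxie_s * 1e3:6.2f} ms   "
      f"adj R^2 {result.tac_fit_adj_r2:.4f}")
print(f"power mapping  irradiance = {result.map_a:.2f} * TAC^{result.map_b:.2f} "
      f"+ {result.map_c:.2f}   (adj R^2 {result.map_adj_r2:.4f})")
print(f"irradiance-domain rheobase {result.irradiance_rheobase_W_m2:.2f} W/m^2, "
      f"chronaxie {result.irradiance_chronaxie_s * 1e3:.2f} ms")
print("\nRheobase: minimal strength for a spike at long pulses; chronaxie:")
print("duration at which threshold doubles -- the classical excitability pair.")
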