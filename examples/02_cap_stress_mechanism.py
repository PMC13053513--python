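"""The soft-plaque mechanism in the cap-stress kernel.

Sweeps the plaque modulus under fixed geometry and pressure: a stiff plaque
shields the thin cap (low stress), a soft plaque leaves it to carry the
load, approaching the thin-walled critical stress p*a/h (utilization 1).
"""

import numpy as np

from cvikit import CapProperties, cap_hoop_stress, critical_stress

cap = CapProperties()   # Ec = 200 kPa, nu = 0.25, h = 20 um
a, b = 1.5, 2.5         # lumen / outer wall radius (mm)
p = 12.0                # lumen pressure (kPa) ~ 90 mmHg

star = critical_stress(p, a, cap.h_mm)
print(f"critical stress p*a/h = {star:.0f} kPa\n")
print(f"{'Ep (kPa)':>10s} {'cap stress (kPa)':>18s} {'utilization':>12s}")
for Ep in [1e-3, 5, 25, 100, 500, 2000, 10000]:
    sigma = cap_hoop_stress(a, b, cap, Ep=Ep, p=p)
    print(f"{Ep:>10g} {sigma:>18.1f} {max(sigma, 0) / star:>12.3f}")

print("\nUtilization -> 1 as the plaque modulus vanishes (Laplace thin-wall limit);")
print("a calcified-stiff plaque drives the cap toward zero (even compressive) stress.")
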