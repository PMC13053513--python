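"""Analyze one idealized coronary lesion end to end.

Builds a 55%-stenosis lesion with a soft (low-attenuation) plaque core,
solves the reduced-order hemodynamics, computes the fibrous-cap stress
profile and prints the 11 lesion features, ending with the cap
vulnerability index (CVI).
"""

from cvikit import CapProperties, FlowConditions, analyze_lesion, build_lesion

geom, plaque = build_lesion(
    a_ref=1.6,          # proximal reference lumen radius (mm)
    severity=0.55,      # diameter stenosis at the throat
    length=16.0,        # lesion length (mm)
    hu_min=25.0,        # softest plaque attenuation (HU); <=30 flags LAP
    remodeling_index=1.15,  # >=1.1 flags positive remodeling
)

ana = analyze_lesion(geom, plaque, cap=CapProperties(), cond=FlowConditions())

print("Lesion features (geometry / plaque flags / hemodynamics / index):")
for name, value in ana.features().items():
    print(f"  {name:<10s} {value:.4g}" if isinstance(value, float) else f"  {name:<10s} {value}")

print(f"\nPeak of the index sits at z = {ana.cvi.argmax_z:.1f} mm "
      f"(lesion spans {geom.lesion_span[0]:.0f}-{geom.lesion_span[1]:.0f} mm).")
print("ds/length describe the narrowing; lap/sc/pr/nrs are adverse-plaque flags;")
print("ffr/dffr/wss/aps are the hemodynamic loads (wss, aps in dyn/cm2);")
print("cvi is max over the cap of (cap stress / critical stress) x (WSS / pressure).")
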