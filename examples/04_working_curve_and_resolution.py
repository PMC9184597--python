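"""Jacobs working curve and radial print resolution.

Fits the two printed cure-depth extremes of the absorber-free ink (5 s ->
576.0 um, 30 s -> 1162.3 um), predicts intermediate depths, inverts the curve
for a target layer thickness, and evaluates the radial resolution pattern.
"""

from gelrsm import photopoly

curve = photopoly.fit_working_curve([(5.0, 576.0), (30.0, 1162.3)])
print(f"light penetration depth Dp = {curve.dp:.1f} um")
print(f"critical exposure time tc = {curve.ec:.2f} s "
      "(irradiance unknown, so exposure is in seconds)")
print(f"cure depth at 15 s: {photopoly.predict_cure_depth(curve, 15.0):.0f} um")
print(f"exposure for a 300 um layer: "
      f"{photopoly.exposure_for_depth(curve, 300.0):.2f} s")

pattern = photopoly.RadialPattern(n=10, h=0.15, d_measured=1.1)
p = photopoly.radial_resolution(pattern)
print(f"\nradial pattern (10 lines, 0.15 mm wide, 1.1 mm circle): "
      f"resolution p = {p * 1000:.0f} um")
print("p is the smallest resolvable gap between adjacent lines; "
      "p <= 0 would mean the lines merged.")
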