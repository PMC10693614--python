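"""Measure body lengths from detection polygons.

Builds a bent, limbed capsule outline with a known 250 cm head-to-tail
length, then measures it: the outline is smoothed to suppress the limbs,
split at its two furthest points, and the midline of the two boundary
chains (plus a tip correction for smoothing shrinkage) gives the curved
body length.  Panel calibration against known squares closes the loop.
"""

import dronesurvey as ds
from dronesurvey.morphometry import calibrate, f1_score, midline_length, straight_length

poly, truth = ds.generate_body_polygon(
    centerline_length=250.0, width=60.0, bend_angle=0.8, n_limbs=4
)
res = midline_length(poly, bandwidth=0.5, resample_n=200)
print(f"ground truth curved length: {truth:.0f} cm")
print(f"measured curved length:     {res.curved_length:.1f} cm "
      f"(error {100 * (res.curved_length - truth) / truth:+.1f}%)")
print(f"straight head-tail length:  {res.straight_length:.1f} cm "
      "(shorter: the body is bent)")
print(f"area {res.area / 1e4:.2f} m2, perimeter {res.perimeter / 100:.2f} m, "
      f"tip correction {res.smoothing_correction:.1f} cm")

panels = ds.generate_panels(seed=0)  # 10 squares, 1.2-7.5 m sides
measured = [straight_length(p) / 100 for p in panels]
reference = [p.properties["side_m"] * 2**0.5 for p in panels]
rep = calibrate(measured, reference)
print(f"\npanel calibration: y = {rep['slope']:.3f} x + {rep['intercept']:.4f}, "
      f"R2 = {rep['r_squared']:.3f} (slope 1 = unbiased measurement)")

m = f1_score(tp=30, fp=2, fn=3)
print(f"\ndetector check example: precision {m.precision:.3f}, "
      f"recall {m.recall:.3f}, F1 {m.f1:.3f}")
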