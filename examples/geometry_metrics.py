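"""Compare two structure masks with the five geometric agreement metrics.

Builds a 10 mm-radius sphere as ground truth, a simulated observer contour
of it, and prints the per-pair report: MSD/HD in mm (surface agreement,
0 = perfect), DSC in [0, 1] (volume overlap, 1 = perfect), VD in cc
(signed volume excess of the test contour) and CMD in mm (centroid shift).
"""

from contourqa import PhantomSpec, evaluate_pair, make_phantom, perturb_mask
from contourqa.synthetic import Ellipsoid, ObserverModel

spec = PhantomSpec(organs={"sphere": Ellipsoid((96.0, 96.0, 64.0), (10.0, 10.0, 10.0))})
gt = make_phantom(spec)["sphere"]
observer = ObserverModel("manual", radial_sd_mm=2.0, seed=42)
contour = perturb_mask(gt, observer, observer_id="obs01", patient_id="P01")

report = evaluate_pair(contour, gt)
print(f"MSD  {report.msd_mm:6.2f} mm   (mean surface distance)")
print(f"DSC  {report.dsc:6.3f}      (overlap; 1 = identical)")
print(f"HD   {report.hd_mm:6.2f} mm   (worst surface distance)")
print(f"VD   {report.vd_cc:+6.2f} cc   ({report.vd_rel_pct:+.1f}% of reference volume)")
print(f"CMD  {report.cmd_mm:6.2f} mm   (centre-of-mass shift)")
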