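"""Extract DVH summaries from a dose grid and compare contour arms.

Builds a Gaussian dose falloff around a target, computes Dmin/Dmax/Dmean/
Dmedian inside a spinal-cord analogue for the ground truth and for a
slightly expanded AI contour, then reports the clinical-goal difference
(Dmax for a serial organ).  A positive delta means the AI contour sees
more dose than the reference — here because its expansion reaches closer
to the target.
"""

from contourqa import dvh_from_dose, make_dose, make_phantom, organ_metric_policy, perturb_mask
from contourqa.synthetic import ObserverModel, PhantomSpec, ZCylinder

spec = PhantomSpec(organs={"spinal_cord": ZCylinder((96.0, 130.0), (5.0, 5.0), (10.0, 86.0))})
gt = make_phantom(spec)["spinal_cord"]
ai = perturb_mask(
    gt, ObserverModel("ai_only", radial_sd_mm=0.0, systematic_margin_mm=2.0, seed=7), "ai", "P01"
)
dose = make_dose(spec.grid, target_center_mm=(96.0, 105.0, 50.0), prescription_gy=68.0)

metric = organ_metric_policy("spinal_cord")  # serial organ -> d_max
gt_dvh = dvh_from_dose(dose, gt)
ai_dvh = dvh_from_dose(dose, ai)
print(f"clinical goal metric: {metric}")
print(f"GT  Dmax {gt_dvh.d_max:6.2f} Gy   Dmean {gt_dvh.d_mean:6.2f} Gy")
print(f"AI  Dmax {ai_dvh.d_max:6.2f} Gy   Dmean {ai_dvh.d_mean:6.2f} Gy")
print(f"delta {metric}: {ai_dvh.value(metric) - gt_dvh.value(metric):+.2f} Gy "
      "(positive = AI contour sees more dose)")
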