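"""Generate a phantom case and quantify its kidneys into %ID and GFR.

Builds one synthetic torso at the small CPU grid, applies the ground-truth
kidney masks to the quantitative (attenuation/scatter/resolution-corrected)
SPECT, and converts the captured activity to glomerular filtration rate with
GFR = 9.1462 x %ID + 23.0653 per kidney.
"""

import ctfree_gfr as cg

spec = cg.PhantomSpec.desk(seed=7)
case = cg.generate_case(spec)

pct = cg.percent_injected_dose(case.quantitative_spect, case.labels,
                               case.injected_activity_MBq)
result = cg.gfr_from_pct_id(
    pct,
    volumes_ml={c: case.labels.class_volume_ml(c) for c in (1, 2)},
    injected_MBq=case.injected_activity_MBq,
)

print(f"category: {case.category}, injected {case.injected_activity_MBq:.0f} MBq")
print(f"ground-truth %ID  right {case.true_pct_id[1]:.2f}  left {case.true_pct_id[2]:.2f}")
print(f"measured %ID      right {result.pct_id_right:.2f}  left {result.pct_id_left:.2f}")
print(f"kidney volumes    right {result.volume_right_ml:.0f} mL  left {result.volume_left_ml:.0f} mL")
print(f"GFR (mL/min)      right {result.gfr_right:.1f}  left {result.gfr_left:.1f}  "
      f"total {result.gfr_total:.1f}")
print("\nThe measured %ID sits slightly below ground truth: the system PSF has "
      "blurred some renal activity outside the true mask (partial-volume loss).")
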