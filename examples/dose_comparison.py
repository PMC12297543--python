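"""Effective-dose comparison: conventional SPECT/CT versus CT-free SPECT.

The SPECT component (1.813 mSv for a 370 MBq Tc-99m DTPA injection) is fixed;
the CT component scales with the dose-length product (DLP) at 15 uSv/mGy-cm
over the abdomen/pelvis.  Removing the CT removes that entire component.
"""

from ctfree_gfr.dosimetry import dose_report

rows = dose_report(dlps=[100.0, 200.0, 300.0, 450.0])

print(f"{'DLP (mGy-cm)':>12} {'CT (mSv)':>9} {'SPECT/CT (mSv)':>15} {'saved by CT-free':>17}")
for r in rows:
    print(f"{r['dlp_mGycm']:>12.0f} {r['ct_mSv']:>9.3f} {r['total_mSv']:>15.3f} "
          f"{r['reduction_pct']:>16.1f}%")
print("\nAcross typical abdominal CT protocols the CT-free study avoids "
      f"{rows[0]['reduction_pct']:.1f}-{rows[-1]['reduction_pct']:.1f}% of the "
      "total effective dose.")
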