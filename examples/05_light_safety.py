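"""Light-safety exposure budget for trans-scleral illumination.

Computes the maximum photochemically safe exposure time for light entering
through the sclera (attenuated by scleral transmission, spread over the
illuminated patch), the bound for accidental trans-pupillary exposure, the
thermal margin on the sclera, and the external/eye field-of-view angle
conversion.  All powers are pre-weighted by the hazard spectral functions.
"""

import fundusqa as fq

budget = fq.SafetyBudget()  # 0.5 mW weighted, 30% transmission, 13 mm2

t_scleral = fq.photochemical_tmax(budget)
print(f"trans-scleral photochemical t_max: {t_scleral.hours:.1f} h "
      f"({t_scleral.seconds:.0f} s) against the 10 J/cm2 retinal limit")

t_pupil = fq.pupil_tmax(budget)
print(f"trans-pupillary t_max at the 9 mm2 boundary area: "
      f"{t_pupil.minutes:.0f} min (larger areas only extend this bound)")

ok, margin = fq.thermal_check(230.0, budget)
print(f"thermal check at 230 mW/cm2: {'PASS' if ok else 'FAIL'}, "
      f"margin {margin:.2f}x below the 700 mW/cm2 limit")

conv = fq.calibrate_angle_convention([(45.0, 67.5)])
print(f"FOV conversion ratio (eye/external): {conv.eye_to_external_ratio}")
print(f"60 deg external-angle = "
      f"{fq.external_to_eye_angle(60.0, conv):.0f} deg eye-angle")
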