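"""Agar-plate inhibition zone prediction and its statistical comparison.

A 3×3 cm coated substrate releases vancomycin into an agar layer
(D = 0.72 mm²/h, no clearance) for 24 h; wherever the concentration meets the
MIC of S. aureus (2 µg/mL) bacterial growth is inhibited. The measured
inhibition area for this coating was 12.97 ± 1.30 cm² over 3 plates, and a
one-sample t-test asks whether a simulated area is consistent with that.
"""

from vancoelute import default_config, one_sample_t_test, run_agar

res = run_agar(default_config("agar", "test"))
print(f"predicted inhibition area at 24 h : {res.inhibition_area_cm2:.2f} cm^2 "
      f"(substrate footprint alone: 9.00 cm^2)")

# Comparing a simulated area of 15.43 cm² against the measured plates:
t = one_sample_t_test(12.97, 1.30, 3, 15.43)
print(f"t = {t.t:.3f}, df = {t.df}, two-sided p = {t.p:.3f}")
print("p > 0.05: the simulated and measured inhibition areas are consistent.")
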