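"""The calibrated-BOLD forward model and its inversion at reference constants.

Walks the physiological chain once by hand: arterial oxygen content under
normoxia and hyperoxia, the venous deoxyhaemoglobin ratio, the M-value a
given hyperoxia response implies, and the venous CBV change recovered from
a hypercapnic BOLD response.
"""

from laminarbold import (
    CalibParams,
    arterial_o2_content,
    forward_bold_hypercapnia,
    hyperoxia_dhb_ratio,
    invert_cbv,
    m_value,
    severinghaus_saturation,
)

params = CalibParams()  # alpha=0.2, beta=1, OEF0=0.30, [Hb]=15 g/dL

print("-- oxygen transport --")
for po2 in (100.0, 450.0):
    print(f"PaO2 {po2:6.0f} mmHg: SaO2 = {severinghaus_saturation(po2):.4f}, "
          f"CaO2 = {arterial_o2_content(po2, params):.2f} mL/dL")

ratio = hyperoxia_dhb_ratio(100.0, 450.0, params)
print(f"\nvenous [dHb] ratio at +350 mmHg PetO2: {ratio:.3f} "
      "(the O2 challenge washes out ~25% of venous dHb)")

dbold_ho = 0.035  # a 3.5% hyperoxia BOLD response
m = m_value(dbold_ho, ratio, params)
print(f"\na {100*dbold_ho:.1f}% hyperoxia response implies M = {100*m:.1f}% "
      "(theoretical ceiling of the BOLD signal change)")

dbold_hc = forward_bold_hypercapnia(1.125, params.cmro2_ratio("+10"), m, params)
print(f"\nforward model: a 12.5% CBV increase at +10 mmHg PetCO2 "
      f"gives {100*dbold_hc:.2f}% BOLD change")
cbv = invert_cbv(dbold_hc, m, params.cmro2_ratio("+10"), params)
print(f"inverting that response recovers dCBV = {100*(cbv-1):.2f}%")
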