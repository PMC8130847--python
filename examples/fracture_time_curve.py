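"""Time-to-fracture as a function of deployment strain.

Inverts the degradation law for the time at which the decaying fracture
strain meets the strain an element carries.  The printed curve is the
device-level design rule: U-bend crowns near strain 0.3 fail within a month,
while lightly strained strut bodies survive more than half a year.
"""

from scaffold_degrade import DegradationCoefficients, fracture_time

coeffs = DegradationCoefficients()  # published fit for Absorb-type PLLA

print("strain   fracture time")
for eps in (0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5):
    t = fracture_time(eps, coeffs)
    print(f"{eps:6.2f}   {t:7.1f} d  ({t / 30:4.1f} months)")
print()
print("Higher deployment strain -> earlier local fracture; the curve is the")
print("map from a post-deployment strain field to the degradation timeline.")
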