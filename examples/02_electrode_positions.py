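"""10-10 electrode positions and the five standard montages.

Positions come from the proportional-arc construction on the spherical
head; the printed angular distances are the definitional 10-20 fractions
(20% of the 180-degree ear-to-ear arc = 36 degrees, etc.).
"""

import numpy as np

import fieldlab as fl
from fieldlab.tenten import angular_distance_deg

for label in ("Cz", "C3", "C5", "T7", "Oz", "Fp2", "F3", "F4", "FC3", "FC5", "P3"):
    v = fl.standard_position(label)
    print(f"{label:4s} -> ({v[0]:+.3f}, {v[1]:+.3f}, {v[2]:+.3f})")

print(f"\nCz-C3 arc: {angular_distance_deg('Cz', 'C3'):.1f} deg (20% of ear-to-ear)")
print(f"Cz-T7 arc: {angular_distance_deg('Cz', 'T7'):.1f} deg (40%)")
print(f"C3-C5 arc: {angular_distance_deg('C3', 'C5'):.1f} deg (10-10 step)")

print("\nMontages:")
for name in fl.MONTAGE_NAMES:
    m = fl.get_montage(name)
    parts = [f"{e.polarity[0].upper()}:{e.position}({e.shape[0]})" for e in m.electrodes]
    print(f"  {name:7s} {m.total_current_mA} mA  " + " ".join(parts))
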