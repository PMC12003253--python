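"""Sphere diameter <-> volume arithmetic for the NEMA body phantom.

The six fillable spheres are specified by inner diameter; partial-volume
reasoning is usually done in volume units, so both directions matter.
"""

import petphantomqa as qa

for d in (10, 13, 17, 22, 28, 37):
    print(f"{d:2d} mm sphere -> {qa.sphere_volume_ml(d):6.2f} ml")

for v in (0.2, 1.0, 4.6):
    print(f"{v:4.1f} ml sphere -> {qa.diameter_mm_from_volume(v):6.2f} mm diameter")

print(
    "\nThe 37 mm sphere holds ~26.5 ml; lesions at or below the 17 mm sphere "
    "(~2.57 ml) are the regime where partial-volume losses dominate."
)
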