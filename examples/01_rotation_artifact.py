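"""How head rotation corrupts the ALPS index, and how reorientation fixes it.

Builds the periventricular phantom, applies a 15 deg chin-up rotation,
simulates a noiseless 65-volume DTI acquisition, fits the tensor, and
computes the index both ways.
"""
import numpy as np

import alps_reorient as ar

template = ar.build_template()  # unrotated reference phantom, 64x64x32 @ 2.5 mm

for angle in (0.0, 15.0):
    subject = ar.run_single_subject(
        ar.RotationSpec((angle, 0.0, 0.0)), template=template, snr=np.inf
    )
    print(
        f"chin-up {angle:4.0f} deg | original ALPS {subject.original.index:.4f} | "
        f"reoriented ALPS {subject.reoriented.index:.4f} | "
        f"registration residual {subject.registration_error_deg:.2f} deg"
    )

print(
    "\nThe original index drops from 1.375 to ~1.178 because the rotation mixes"
    "\nthe tensor's y and z axes (cos^2(15)*0.40 + sin^2(15)*1.40 = 0.467e-3 in"
    "\nthe projection ROIs); the reoriented index recovers the true 1.375."
)
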