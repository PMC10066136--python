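"""Rotation-sensitivity curves: original vs reoriented index, x vs z axis.

Chin-up (x) rotation perturbs the original index far more than neck (z)
rotation on this geometry, and reorientation flattens both curves.
"""
import numpy as np

import alps_reorient as ar

template = ar.build_template()
angles = [0.0, 5.0, 10.0, 15.0, 20.0]

for axis in ("x", "z"):
    table = ar.run_rotation_sweep(axis, angles, template=template, snr=np.inf)
    print(f"\n{axis}-axis sweep (noiseless):")
    print(table[["angle_deg", "original", "reoriented"]].round(4).to_string(index=False))
    dev = (table.original - template.baseline_index).abs().max()
    print(f"max deviation of the original index from 1.375: {dev:.3f}")

print(
    "\nEach row is a full pipeline run: rotate -> simulate -> fit -> ALPS,"
    "\nthen register -> reorient -> ro-ALPS. The reoriented column stays at"
    "\nthe true value on both sweeps."
)
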