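"""Recover ridge geometry from an analytic Gaussian ridge.

Builds a 64x64 image holding a straight Gaussian ridge of known amplitude,
width and orientation (the idealized signature of an antiparallel strand
pairing on a contact map), runs the scale-space ridge detector, and compares
the recovered direction phi, offset d, height h and width w against the
ground truth.
"""

import numpy as np

from betaridge import RunConfig, compute_ridge_fields
from betaridge.ridge import analytic_ridge, on_axis_cells

AMPLITUDE, STD, ANGLE = 1.0, 1.5, 135.0  # the antiparallel direction

img = analytic_ridge(64, ANGLE, amplitude=AMPLITUDE, std=STD)
fields = compute_ridge_fields(img, RunConfig())
mask = on_axis_cells(64, ANGLE) & fields.valid

phi_deg = np.rad2deg(np.median(fields.phi[mask]))
print(f"cells on the ridge axis flagged valid : {int(mask.sum())}")
print(f"recovered direction phi               : {phi_deg:6.2f} deg (truth {ANGLE})")
print(f"recovered offset d                    : {np.median(fields.d[mask]):6.3f} cells (truth 0)")
print(f"recovered height h                    : {np.median(fields.h[mask]):6.3f} (truth {AMPLITUDE})")
print(f"recovered width w                     : {np.median(fields.w[mask]):6.3f} cells (truth {STD})")
print()
print("phi identifies the pairing orientation (135 deg = antiparallel,")
print("45 deg = parallel); h and w recover the ridge profile that the")
print("random-forest stages consume as 2D features.")
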