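"""Geometry of the snapshot-tomography optical train.

Builds the demonstrated system configuration (60x/1.4NA objective, 2.86x
relay, 500 um / 13.8 mm micro-lens array, 4x second relay, 13 um camera
pixels) and prints the derived imaging figures plus the table of per-lenslet
viewing angles.  Lenslets whose center leaves the objective pupil, or whose
viewing-angle expression has no real solution, are excluded from the table.
"""

from spotfts import (
    LensletGrid,
    SystemConfig,
    field_of_view,
    lenslet_diffraction_limit,
    overall_magnification,
    pixel_resolution_at_sample,
)
from spotfts.optics import viewing_angles

config = SystemConfig()
print(f"overall magnification       : {overall_magnification(config):.2f}")
print(f"field of view               : {field_of_view(config):.2f} um")
print(f"pixel resolution at sample  : {pixel_resolution_at_sample(config):.3f} um")
print(f"diffraction limit (width)   : {lenslet_diffraction_limit(config, 'width'):.3f} um")
print(f"diffraction limit (diagonal): {lenslet_diffraction_limit(config, 'diagonal'):.3f} um")

grid = LensletGrid.build(config)
angles = viewing_angles(grid, config)
print(f"\nusable lenslets: {len(angles)} of {len(grid.indices)} "
      f"({sum(grid.in_pupil)} inside the pupil)")
print("m      n      alpha[deg]  beta[deg]")
for (m, n), ang in zip(grid.valid_indices(), angles):
    print(f"{m:+.1f}   {n:+.1f}   {ang.alpha_deg:+8.2f}  {ang.beta_deg:+8.2f}")

# The magnification/FOV/pixel figures say how much sample each lenslet
# sub-image covers; the angle table is the set of tomographic viewing
# directions a single camera frame records simultaneously.
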