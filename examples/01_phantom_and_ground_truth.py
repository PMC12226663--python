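"""Generate a synthetic enterography phantom and compare its ground truth
with the analytic tube geometry.

A straight bowel segment (lumen radius 5 mm, wall 3 mm, length 100 mm) is
rasterized at SSFSE-like spacing; the annular-cylinder volume
pi*((r+t)^2 - r^2)*L should match the truth mask's voxel-counted volume
within voxelization error.
"""

import numpy as np

import enterometry as em
from enterometry.morphometry import mask_volume_mL

n, s = 60, 0.8
c = n * s / 2
spec = em.PhantomSpec(
    grid_shape=(n, n, 27),
    spacing=(s, s, 5.0),
    curve_control_points=np.array([[c, c, 15.0], [c, c, 65.0], [c, c, 115.0]]),
    lumen_radius_mm=5.0,
    wall_thickness_mm=3.0,
    noise_sigma=0.0,
)
volume, truth = em.make_phantom(spec)

analytic = np.pi * (8.0**2 - 5.0**2) * 100.0 / 1000.0
measured = mask_volume_mL(truth.wall_mask)
print(f"analytic annulus volume : {analytic:.2f} mL")
print(f"truth-mask voxel volume : {measured:.2f} mL "
      f"({100 * (measured / analytic - 1):+.1f}% voxelization error)")
print(f"true length             : {truth.true_length_cm:.1f} cm")
print(f"true mean thickness     : {truth.true_mean_thickness_mm:.1f} mm")
# The voxelized wall volume tracks the closed-form annulus volume to a few
# percent; length and thickness are exact by construction.
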