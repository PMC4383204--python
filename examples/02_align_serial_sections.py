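"""Recover per-section misplacements of a simulated serial-section stack.

Sections a textured phantom into 20 slides with random translation jitter
(sd 3 px) and rotation (sd 1°), re-aligns the stack by chained pairwise
phase correlation, and compares the estimated transforms with the exact
ground truth the simulator returns.  Errors well below half a pixel /
half a degree mean the reconstruction will not smear the vessel wall.
"""

import math

import numpy as np

import vesselmorph as vm

n = 20
spec = vm.VesselSpec(
    length_um=4.0 * (n + 3),
    outer_radius_um=40.0,
    lumen_radius_profile=20.0,
    noise_sd=0.02,
    texture_amplitude=0.15,
)
volume, labels = vm.generate_vessel_volume(spec, spacing=(4.0, 0.369, 0.369), seed=1)
zs = [k for k in range(labels.shape[0]) if np.any(labels.data[k] == vm.LUMEN)]
volume = vm.Volume(data=volume.data[zs[0] + 1 : zs[0] + 1 + n], spacing=volume.spacing)
labels = vm.LabelVolume(data=labels.data[zs[0] + 1 : zs[0] + 1 + n], spacing=labels.spacing)

plan = vm.SectioningSpec(
    pixel_size_xy=0.369, section_thickness=4.0,
    jitter_sd_px=3.0, rotation_sd_deg=1.0, seed=7,
)
stack, _, truth = vm.section_volume(volume, labels, plan)

estimated = vm.align_stack(stack, max_rotation_deg=5.0)
ref = len(stack) // 2
errs = []
for k in range(len(stack)):
    rel = truth[ref].inverse().compose(truth[k])
    e = estimated[k]
    errs.append((math.hypot(e.dx - rel.dx, e.dy - rel.dy), abs(e.theta_deg - rel.theta_deg)))
errs = np.array(errs)

print(f"aligned {len(stack)} sections of {stack.section_shape} at 0.369 um/px")
print(f"translation error: median {np.median(errs[:, 0]):.3f} px, max {errs[:, 0].max():.3f} px")
print(f"rotation error:    median {np.median(errs[:, 1]):.3f} deg, max {errs[:, 1].max():.3f} deg")
print("each section's recovered rigid transform is compared against the "
      "misplacement the sectioning simulator actually applied.")
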