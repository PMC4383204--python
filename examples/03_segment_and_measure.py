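"""Seeded 3-class segmentation of a noisy vessel volume.

Scatters 10 seeds per class (background / lumen / neointima) in a noisy
phantom, labels every remaining voxel by minimal-cost geodesics over
intensity differences and gradients, and scores the result against the
phantom's exact ground truth (Dice per class) before computing the NVI.
"""

import numpy as np

import vesselmorph as vm
from vesselmorph.segmentation import seeds_from_labels

spec = vm.VesselSpec(
    length_um=60.0, outer_radius_um=30.0, lumen_radius_profile=15.0, noise_sd=0.05
)
volume, truth = vm.generate_vessel_volume(spec, spacing=(2.0, 1.0, 1.0), seed=3)
seeds = seeds_from_labels(truth, n_per_class=10, seed=4)

labels = vm.segment(volume, seeds, beta=1.0, presmooth_sigma_um=1.0)

for code, name in [(0, "background"), (1, "lumen"), (2, "neointima")]:
    a, b = labels.data == code, truth.data == code
    dice = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
    print(f"Dice {name:<11}= {dice:.4f}")

segment = vm.nvi(labels)
print(f"NVI from segmentation = {segment.nvi_rounded:.3f} % "
      f"(ground truth {vm.analytic_nvi(spec):.1f} %)")
print("Dice near 1 means the geodesic labeling reproduces the true class "
      "boundaries despite the voxel noise.")
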