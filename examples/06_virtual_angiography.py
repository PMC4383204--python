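"""Render a virtual angiogram from a two-channel fluorescence phantom.

Channel 0 carries diffuse tissue autofluorescence; channel 1 is bright in
the collagenous vessel wall.  A weighted subtraction suppresses the tissue,
thresholding removes the residue, and a maximum intensity projection along
the stack axis yields the angiogram-like footprint of the vessel.
"""

import numpy as np

import vesselmorph as vm
from vesselmorph.angiography import ChannelRecipe

spec = vm.VesselSpec(length_um=60.0, outer_radius_um=25.0, lumen_radius_profile=12.0)
_, labels = vm.generate_vessel_volume(spec, spacing=(2.0, 1.0, 1.0))
rng = np.random.default_rng(0)
ch_tissue = np.clip(
    np.where(labels.data == vm.BACKGROUND, 0.5, 0.3) + rng.normal(0, 0.05, labels.shape), 0, 1
)
ch_wall = np.clip(
    np.where(labels.data == vm.NEOINTIMA, 0.9, 0.2) + rng.normal(0, 0.05, labels.shape), 0, 1
)
volume = vm.Volume(
    data=np.stack([ch_tissue, ch_wall], axis=-1).astype(np.float32),
    spacing=labels.spacing,
    channel_names=["autofluorescence", "collagen"],
)

enhanced = vm.enhance(volume, ChannelRecipe(weights=(-0.8, 1.0), suppression_threshold=0.1))
angiogram = vm.mip(enhanced, axis="z")

footprint = np.count_nonzero(angiogram > 0.2)
wall_mask = (labels.data == vm.NEOINTIMA).any(axis=0)
print(f"enhanced volume range: {enhanced.data.min():.2f} .. {enhanced.data.max():.2f}")
print(f"angiogram footprint: {footprint} px; true wall footprint: {wall_mask.sum()} px")
print("after subtraction and thresholding the projection shows the vessel "
      "wall annulus with the background tissue suppressed.")
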