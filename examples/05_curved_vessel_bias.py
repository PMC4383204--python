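"""Show the curved-vessel NI bias and its correction.

A curved vessel with a constant true NI of 75% is sectioned in the stack
plane; where the vessel bends away from the cutting direction the sections
become near-tangential and the measured NI is badly inflated.  The
perpendicular re-sliced series stays at the true value, and the artificial
proximal-vs-distal gradient disappears.
"""

import numpy as np

import vesselmorph as vm

spec = vm.VesselSpec(
    centerline_kind="circular_arc",
    arc_radius_um=250.0,
    arc_angle_deg=75.0,
    outer_radius_um=30.0,
    lumen_radius_profile=15.0,
)
volume, labels = vm.generate_vessel_volume(spec, spacing=(1.0, 1.0, 1.0))
plan = vm.SectioningSpec(pixel_size_xy=1.0, section_thickness=4.0, seed=0)
_, label_stack, _ = vm.section_volume(volume, labels, plan)
stack_volume = vm.LabelVolume(
    data=label_stack.as_array().astype(np.uint8), spacing=(4.0, 1.0, 1.0)
)

centerline = vm.extract_centerline(stack_volume)
zs = [k for k in range(stack_volume.shape[0]) if np.any(stack_volume.data[k] == vm.LUMEN)]
conventional = np.array(
    [vm.ni_from_label_section(stack_volume.data[k])[2] for k in zs]
)
arcs = centerline.arclength
margin = 16.0
keep = (arcs > margin) & (arcs < centerline.total_arclength - margin)
series = vm.perpendicular_series(
    None, stack_volume, centerline, arclengths=arcs[keep], size=90, pixel_size=1.0
)
corrected = np.array([vm.ni_from_label_section(lab)[2] for _, lab, _ in series])

print(f"analytic NI everywhere: {vm.analytic_ni(spec, 0.5):.1f} %")
print(f"conventional stack-plane NI: {conventional[keep].min():.1f} .. "
      f"{conventional[keep].max():.1f} % (max bias "
      f"{np.abs(conventional[keep] - 75).max():.1f} points)")
print(f"corrected perpendicular NI : {corrected.min():.1f} .. {corrected.max():.1f} % "
      f"(max bias {np.abs(corrected - 75).max():.1f} points)")
mid = 0.5 * (arcs[keep][0] + arcs[keep][-1])
cv, pv = conventional[keep], corrected
print(f"proximal-vs-distal mean difference: conventional "
      f"{cv[arcs[keep] < mid].mean() - cv[arcs[keep] >= mid].mean():+.2f}, "
      f"corrected {pv[arcs[keep] < mid].mean() - pv[arcs[keep] >= mid].mean():+.2f}")
print("only the near-tangential conventional sections are biased; the "
      "perpendicular series tracks the true constant NI.")
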