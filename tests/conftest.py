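"""Shared fixtures: session-scoped phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vesselmorph as vm

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        deadline=None,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def straight_spec() -> vm.VesselSpec:
    """Straight annular vessel, R = 50 µm, r = 25 µm (analytic NI = 75)."""
    return vm.VesselSpec(
        centerline_kind="straight",
        length_um=300.0,
        outer_radius_um=50.0,
        lumen_radius_profile=25.0,
    )


@pytest.fixture(scope="session")
def straight_volume(straight_spec):
    """The straight phantom voxelized at 1 µm isotropic spacing."""
    return vm.generate_vessel_volume(straight_spec, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def arc_spec() -> vm.VesselSpec:
    """Circular-arc vessel with constant lumen profile (analytic NI = 75):
    curvature radius 250 µm, 75° sweep, so stack-plane obliquity runs from
    0° at the proximal end past 60° near the distal end."""
    return vm.VesselSpec(
        centerline_kind="circular_arc",
        arc_radius_um=250.0,
        arc_angle_deg=75.0,
        outer_radius_um=30.0,
        lumen_radius_profile=15.0,
    )


@pytest.fixture(scope="session")
def arc_volume(arc_spec):
    return vm.generate_vessel_volume(arc_spec, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def arc_label_volume(arc_spec, arc_volume):
    """Arc phantom sectioned in the stack plane and restacked as labels."""
    vol, lab = arc_volume
    plan = vm.SectioningSpec(pixel_size_xy=1.0, section_thickness=4.0, seed=0)
    _, labs, _ = vm.section_volume(vol, lab, plan)
    return vm.LabelVolume(data=labs.as_array().astype(np.uint8), spacing=(4.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def noisy_seg_phantom():
    """The standard noisy segmentation phantom (noise sd 0.05) with its
    ground truth: straight vessel, 2 x 1 x 1 µm grid."""
    spec = vm.VesselSpec(
        centerline_kind="straight",
        length_um=60.0,
        outer_radius_um=30.0,
        lumen_radius_profile=15.0,
        noise_sd=0.05,
    )
    vol, lab = vm.generate_vessel_volume(spec, spacing=(2.0, 1.0, 1.0), seed=3)
    return spec, vol, lab


@pytest.fixture(scope="session")
def noiseless_seg_phantom():
    spec = vm.VesselSpec(
        centerline_kind="straight",
        length_um=60.0,
        outer_radius_um=30.0,
        lumen_radius_profile=15.0,
    )
    vol, lab = vm.generate_vessel_volume(spec, spacing=(2.0, 1.0, 1.0))
    return spec, vol, lab


@pytest.fixture(scope="session")
def registration_stack():
    """30 perturbed sections at the native 0.369 µm/px scan resolution:
    jitter sd 5 px, rotation sd 2°, scanner noise sd 0.02, plus the
    tissue-texture field that makes rotation recovery well-posed.
    Returns (image stack, label stack, ground-truth transforms)."""
    n_sections = 30
    spec = vm.VesselSpec(
        centerline_kind="straight",
        length_um=4.0 * (n_sections + 3),
        outer_radius_um=40.0,
        lumen_radius_profile=20.0,
        noise_sd=0.02,
        texture_amplitude=0.15,
    )
    vol, lab = vm.generate_vessel_volume(spec, spacing=(4.0, 0.369, 0.369), seed=1)
    zs = [k for k in range(lab.shape[0]) if np.any(lab.data[k] == vm.LUMEN)]
    z0 = zs[0] + 1
    vol = vm.Volume(data=vol.data[z0 : z0 + n_sections], spacing=vol.spacing)
    lab = vm.LabelVolume(data=lab.data[z0 : z0 + n_sections], spacing=lab.spacing)
    plan = vm.SectioningSpec(
        pixel_size_xy=0.369,
        section_thickness=4.0,
        jitter_sd_px=5.0,
        rotation_sd_deg=2.0,
        seed=7,
    )
    return vm.section_volume(vol, lab, plan)


def stack_plane_ni_series(label_stack, completeness: float = 0.98):
    """Per-section NI of the stack-plane label sections whose annulus is
    complete (sections clipping the segment ends are not valid NI
    measurements)."""
    neo = np.array([np.count_nonzero(s == vm.NEOINTIMA) for s in label_stack.sections])
    full = neo >= completeness * neo.max()
    return np.array(
        [vm.ni_from_label_section(label_stack.sections[k])[2] for k in np.where(full)[0]]
    )


@pytest.fixture(scope="session")
def pipeline_config():
    """Small end-to-end demo: straight phantom, mild jitter, tilt 0."""
    return {
        "seed": 11,
        "phantom": {
            "vessel": {
                "centerline_kind": "straight",
                "length_um": 100.0,
                "outer_radius_um": 30.0,
                "lumen_radius_um": 15.0,
                "noise_sd": 0.02,
                "texture_amplitude": 0.08,
            },
            "spacing_um": [4.0, 1.0, 1.0],
            "sectioning": {
                "pixel_size_xy": 1.0,
                "section_thickness": 4.0,
                "jitter_sd_px": 2.0,
                "rotation_sd_deg": 0.5,
            },
        },
        "registration": {"max_rotation_deg": 4.0},
        "segmentation": {"presmooth_sigma_um": 1.5},
        "reslice": {"size_px": 90, "pixel_size_um": 1.0},
    }
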