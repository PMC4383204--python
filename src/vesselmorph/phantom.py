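"""Synthetic vessel phantoms with analytic ground truth.

A phantom is an annular vessel (lumen inside a neointimal wall) embedded in a
uniform tissue background, either straight or bent along a circular arc, and
optionally with a lumen radius that varies along the vessel.  Because the
geometry is analytic, every derived quantity — per-level neointimal index
(NI), segment neointimal volume index (NVI), class volumes — has a closed
form, which makes phantoms the ground truth against which registration,
segmentation, re-slicing and morphometry are validated.

The sectioning simulator cuts a phantom volume into serial 2-D sections the
way a microtome would: at a chosen obliquity (tilt) to the vessel axis, with
independent per-section random placement error (translation jitter and
rotation), returning the exact inverse transforms as registration ground
truth.

Geometry conventions: arrays are ``(z, y, x)``; straight vessels run along
``z``; arc vessels bend in the z–y plane starting tangent to ``+z``; the
lumen radius profile is parameterized by arclength fraction so it means the
same thing for straight and curved centerlines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import LUMEN, NEOINTIMA, LabelVolume, SectionStack, Volume
from .registration import RigidTransform2D, apply_transform_image

__all__ = [
    "VesselSpec",
    "SectioningSpec",
    "generate_vessel_volume",
    "section_volume",
    "analytic_ni",
    "analytic_nvi",
    "analytic_class_volumes",
]

RadiusProfile = Callable[[np.ndarray], np.ndarray]


def _as_profile(value) -> RadiusProfile:
    if callable(value):
        return lambda s: np.asarray(value(s), dtype=float)
    r = float(value)
    return lambda s: np.full_like(np.asarray(s, dtype=float), r)


@dataclass
class VesselSpec:
    """Geometry and appearance of a synthetic annular vessel.

    Parameters
    ----------
    centerline_kind:
        ``"straight"`` (axis along z) or ``"circular_arc"`` (bend in the z–y
        plane, starting tangent to +z).
    length_um:
        Vessel length for straight centerlines (ignored for arcs).
    arc_radius_um, arc_angle_deg:
        Arc curvature radius and swept angle for ``circular_arc``.
        The arc radius must exceed the outer radius so the wall cannot
        self-intersect.
    outer_radius_um:
        External boundary of the neointima (internal elastic lamina
        surrogate).
    lumen_radius_profile:
        Either a constant radius in µm or a function of arclength fraction
        ``s in [0, 1]`` returning the lumen radius; must stay strictly
        between 0 and the outer radius.
    background_intensity, lumen_intensity, neointima_intensity:
        Class intensities in [0, 1].  Defaults emulate autofluorescence
        appearance: collagenous wall bright, open lumen dark, myocardial
        background intermediate.
    noise_sd:
        Standard deviation of additive i.i.d. Gaussian voxel noise (scanner
        noise; clipped to [0, 1] after addition).
    texture_amplitude, texture_scale_um, texture_scale_z_um:
        Amplitude (intensity sd) and correlation lengths (in-plane and
        axial) of a smooth 3-D random field added to the tissue classes
        (background and neointima).  The axial scale exceeds the in-plane
        scale because tissue structures (myocyte bundles, collagen tracts)
        typically span several 4 um sections while showing fine in-plane
        detail.  This emulates the anatomical texture — myocytes,
        collagen bundles — that neighbouring serial sections share because
        such structures are larger than one section thickness; it is what
        makes section-to-section rotational alignment well-posed, since the
        annular vessel itself is rotationally symmetric.  0 disables it.
    """

    centerline_kind: str = "straight"
    length_um: float = 100.0
    arc_radius_um: float = 200.0
    arc_angle_deg: float = 90.0
    outer_radius_um: float = 50.0
    lumen_radius_profile: object = 25.0
    background_intensity: float = 0.4
    lumen_intensity: float = 0.05
    neointima_intensity: float = 0.8
    noise_sd: float = 0.0
    texture_amplitude: float = 0.0
    texture_scale_um: float = 1.5
    texture_scale_z_um: float = 40.0

    def __post_init__(self) -> None:
        if self.centerline_kind not in ("straight", "circular_arc"):
            raise ValueError(f"unknown centerline_kind {self.centerline_kind!r}")
        if self.outer_radius_um <= 0:
            raise ValueError("outer_radius_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.centerline_kind == "circular_arc":
            if self.arc_radius_um <= self.outer_radius_um:
                raise ValueError(
                    "arc radius must exceed the outer radius (no self-intersection)"
                )
            if not 0 < self.arc_angle_deg <= 180:
                raise ValueError("arc_angle_deg must be in (0, 180]")
        elif self.length_um <= 0:
            raise ValueError("length_um must be positive")
        profile = _as_profile(self.lumen_radius_profile)
        s = np.linspace(0.0, 1.0, 101)
        r = profile(s)
        if np.any(r <= 0) or np.any(r >= self.outer_radius_um):
            raise ValueError(
                "lumen radius profile must satisfy 0 < r(s) < outer_radius for all s"
            )

    @property
    def profile(self) -> RadiusProfile:
        return _as_profile(self.lumen_radius_profile)

    @property
    def total_arclength_um(self) -> float:
        if self.centerline_kind == "straight":
            return float(self.length_um)
        return float(self.arc_radius_um * math.radians(self.arc_angle_deg))

    def centerline_points(self, s_frac: np.ndarray) -> np.ndarray:
        """Ground-truth centerline (z, y, x) µm positions, relative to the
        vessel start, at arclength fractions ``s_frac``."""
        s_frac = np.asarray(s_frac, dtype=float)
        if self.centerline_kind == "straight":
            z = s_frac * self.length_um
            return np.stack([z, np.zeros_like(z), np.zeros_like(z)], axis=-1)
        phi = s_frac * math.radians(self.arc_angle_deg)
        rc = self.arc_radius_um
        return np.stack(
            [rc * np.sin(phi), rc * (1.0 - np.cos(phi)), np.zeros_like(phi)], axis=-1
        )

    def centerline_tangents(self, s_frac: np.ndarray) -> np.ndarray:
        s_frac = np.asarray(s_frac, dtype=float)
        if self.centerline_kind == "straight":
            t = np.zeros(s_frac.shape + (3,))
            t[..., 0] = 1.0
            return t
        phi = s_frac * math.radians(self.arc_angle_deg)
        return np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)


@dataclass
class SectioningSpec:
    """How a phantom volume is cut into serial sections.

    ``tilt_deg`` is the angle between the cutting-plane normal and the volume
    z axis (the vessel axis for a straight phantom), realized by tilting the
    sampling planes in the z–x plane.  ``jitter_sd_px`` and
    ``rotation_sd_deg`` are per-section normal placement errors.  One RNG
    stream, seeded from ``seed``, is drawn in section order
    (dy, dx, theta per section) — the reproducibility contract.
    """

    pixel_size_xy: float = 0.369
    section_thickness: float = 4.0
    tilt_deg: float = 0.0
    jitter_sd_px: float = 0.0
    rotation_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if not 0 <= self.tilt_deg < 90:
            raise ValueError("tilt_deg must satisfy 0 <= tilt < 90")


def _vessel_fields(
    spec: VesselSpec, z: np.ndarray, y: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance from centerline, arclength fraction, and in-range mask for
    physical coordinates (broadcastable grids, vessel-local frame)."""
    if spec.centerline_kind == "straight":
        inside = (z >= 0.0) & (z <= spec.length_um)
        s_frac = np.clip(z / spec.length_um, 0.0, 1.0)
        dist = np.sqrt(y**2 + x**2)
        return dist, s_frac, inside
    rc = spec.arc_radius_um
    angle = math.radians(spec.arc_angle_deg)
    # arc center sits at (z, y) = (0, rc); phi measured from the start point
    dz = z - 0.0
    dy = y - rc
    phi = np.arctan2(dz, -dy)  # 0 at start, increasing along the arc
    inside = (phi >= 0.0) & (phi <= angle)
    d_plane = np.sqrt(dz**2 + dy**2)
    dist = np.sqrt((d_plane - rc) ** 2 + x**2)
    s_frac = np.clip(phi / angle, 0.0, 1.0)
    return dist, s_frac, inside


def generate_vessel_volume(
    spec: VesselSpec,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    extent: tuple[int, int, int] | None = None,
    margin_um: float = 5.0,
    seed: int | None = None,
) -> tuple[Volume, LabelVolume]:
    """Voxelize a vessel phantom into an intensity volume and a label volume.

    Voxel class membership is decided at the voxel center in physical µm
    coordinates (no partial-volume anti-aliasing), so label volumes are exact
    set-theoretic objects.  If ``extent`` (voxel counts per axis) is omitted
    it is chosen to hold the vessel plus ``margin_um`` on every side; if
    given, the vessel must fit with at least one voxel of margin, otherwise
    an error names the first out-of-bounds arclength.

    Returns the intensity :class:`Volume` (float32, class intensities plus
    optional Gaussian noise, clipped to [0, 1]) and the ground-truth
    :class:`LabelVolume`.
    """
    spacing = tuple(float(s) for s in spacing)
    R = spec.outer_radius_um

    # vessel bounding box in the vessel-local frame: the cross-section disk
    # at arclength s, perpendicular to the tangent t, extends R*sqrt(1-t_a^2)
    # along axis a — exact per-axis bounds (end caps are subsets of disks)
    s_dense = np.linspace(0.0, 1.0, 513)
    pts = spec.centerline_points(s_dense)
    tans = spec.centerline_tangents(s_dense)
    disk_extent = R * np.sqrt(np.clip(1.0 - tans**2, 0.0, 1.0))
    lo = (pts - disk_extent).min(axis=0)
    hi = (pts + disk_extent).max(axis=0)

    if extent is None:
        extent = tuple(
            int(math.ceil((hi[a] - lo[a] + 2 * margin_um) / spacing[a])) + 1
            for a in range(3)
        )
    extent = tuple(int(e) for e in extent)

    # position the vessel so its bounding box is centered in the volume
    phys_extent = np.array([(extent[a] - 1) * spacing[a] for a in range(3)])
    offset = (phys_extent - (hi - lo)) / 2.0 - lo  # vessel-local -> volume µm

    # check containment with >= 1 voxel margin, reporting the first bad arclength
    total_len = spec.total_arclength_um
    for sf, p, ext in zip(s_dense, pts, disk_extent):
        pv = p + offset
        for a in range(3):
            if (
                pv[a] - ext[a] < spacing[a] * 0.999
                or pv[a] + ext[a] > phys_extent[a] - spacing[a] * 0.999
            ):
                raise ValueError(
                    f"vessel exceeds volume extent at arclength {sf * total_len:.1f} um "
                    f"(axis {'zyx'[a]}); enlarge the extent or reduce the vessel"
                )

    zz = np.arange(extent[0]) * spacing[0] - offset[0]
    yy = np.arange(extent[1]) * spacing[1] - offset[1]
    xx = np.arange(extent[2]) * spacing[2] - offset[2]
    z = zz[:, None, None]
    y = yy[None, :, None]
    x = xx[None, None, :]

    dist, s_frac, in_range = _vessel_fields(spec, z, y, x)
    r_lumen = spec.profile(s_frac)

    labels = np.zeros(extent, dtype=np.uint8)
    shape = np.broadcast_shapes(dist.shape, r_lumen.shape, in_range.shape)
    dist = np.broadcast_to(dist, shape)
    r_lumen = np.broadcast_to(r_lumen, shape)
    in_range = np.broadcast_to(in_range, shape)
    labels[in_range & (dist < r_lumen)] = LUMEN
    labels[in_range & (dist >= r_lumen) & (dist < R)] = NEOINTIMA

    intensity = np.full(extent, spec.background_intensity, dtype=np.float32)
    intensity[labels == LUMEN] = spec.lumen_intensity
    intensity[labels == NEOINTIMA] = spec.neointima_intensity
    rng = np.random.default_rng(seed)
    if spec.texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        scales = (spec.texture_scale_z_um, spec.texture_scale_um, spec.texture_scale_um)
        sigma = [scales[a] / (2.0 * spacing[a]) for a in range(3)]
        field = gaussian_filter(rng.standard_normal(extent), sigma)
        sd = field.std()
        if sd > 0:
            field = field / sd * spec.texture_amplitude
        intensity = intensity + np.where(labels != LUMEN, field, 0.0).astype(np.float32)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=extent).astype(np.float32)
    if spec.texture_amplitude > 0 or spec.noise_sd > 0:
        intensity = np.clip(intensity, 0.0, 1.0).astype(np.float32)

    volume = Volume(data=intensity, spacing=spacing)
    label_volume = LabelVolume(data=labels, spacing=spacing)
    return volume, label_volume


def section_volume(
    volume: Volume,
    labels: LabelVolume | None,
    plan: SectioningSpec,
) -> tuple[SectionStack, SectionStack | None, list[RigidTransform2D]]:
    """Simulate serial sectioning of a volume at a given obliquity.

    The cutting-plane normal is the z axis tilted by ``plan.tilt_deg`` in the
    z–x plane; one section is produced per ``section_thickness`` step along
    that normal, sampled on a ``pixel_size_xy`` grid (trilinear for
    intensities, nearest-neighbour for labels).  Each section is then
    perturbed by a random rigid transform drawn from the plan's jitter and
    rotation distributions; the exact inverse (alignment) transforms are
    returned as ground truth, so ``apply_transforms(stack, ground_truth)``
    restores the unperturbed sections.

    With ``tilt_deg = 0`` and grid spacings matching the volume, the
    unperturbed sections equal the axis-aligned slices of the input exactly.
    """
    tilt = math.radians(plan.tilt_deg)
    n = np.array([math.cos(tilt), 0.0, math.sin(tilt)])  # (z, y, x)
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.array([-math.sin(tilt), 0.0, math.cos(tilt)])

    shape = np.asarray(volume.shape, dtype=float)
    spacing = np.asarray(volume.spacing)
    corners = np.array(
        [[(shape[a] - 1) * spacing[a] if bit else 0.0 for a, bit in enumerate(bits)]
         for bits in np.ndindex(2, 2, 2)]
    )
    center = (shape - 1) * spacing / 2.0

    rel = corners - center
    span_n = np.ptp(rel @ n)
    span_1 = np.ptp(rel @ e1)
    span_2 = np.ptp(rel @ e2)
    n_sections = int(math.floor(span_n / plan.section_thickness + 1e-9)) + 1
    ps = plan.pixel_size_xy
    height = int(round(span_1 / ps + 1e-9)) + 1
    width = int(round(span_2 / ps + 1e-9)) + 1

    ii = (np.arange(height) - (height - 1) / 2.0) * ps
    jj = (np.arange(width) - (width - 1) / 2.0) * ps
    in_plane = ii[:, None, None] * e1[None, None, :] + jj[None, :, None] * e2[None, None, :]

    rng = np.random.default_rng(plan.seed)
    from scipy.ndimage import map_coordinates

    sec_center = ((height - 1) / 2.0, (width - 1) / 2.0)
    img_sections: list[np.ndarray] = []
    lab_sections: list[np.ndarray] = []
    truth: list[RigidTransform2D] = []

    multichannel = volume.data.ndim == 4
    for k in range(n_sections):
        off = (k - (n_sections - 1) / 2.0) * plan.section_thickness
        pos = center + off * n + in_plane  # (H, W, 3) µm
        idx = (pos - np.asarray(volume.origin)) / spacing  # fractional indices
        coords = np.moveaxis(idx, -1, 0)
        if multichannel:
            sec = np.stack(
                [
                    map_coordinates(volume.data[..., ch], coords, order=1,
                                    mode="constant", cval=0.0)
                    for ch in range(volume.data.shape[3])
                ],
                axis=-1,
            ).astype(np.float32)
        else:
            sec = map_coordinates(
                volume.data, coords, order=1, mode="constant", cval=0.0
            ).astype(np.float32)
        if labels is not None:
            lab = map_coordinates(
                labels.data, coords, order=0, mode="constant", cval=0
            ).astype(np.uint8)

        # per-section placement error: draws in fixed order (dy, dx, theta)
        dy = rng.normal(0.0, plan.jitter_sd_px) if plan.jitter_sd_px > 0 else 0.0
        dx = rng.normal(0.0, plan.jitter_sd_px) if plan.jitter_sd_px > 0 else 0.0
        th = rng.normal(0.0, plan.rotation_sd_deg) if plan.rotation_sd_deg > 0 else 0.0
        perturb = RigidTransform2D(dx=dx, dy=dy, theta_deg=th, center=sec_center)
        if not perturb.is_identity():
            sec = apply_transform_image(sec, perturb, order=1)
            if labels is not None:
                lab = apply_transform_image(lab, perturb, order=0)
        img_sections.append(sec)
        if labels is not None:
            lab_sections.append(lab)
        truth.append(perturb.inverse())

    img_stack = SectionStack(
        sections=img_sections,
        pixel_size_xy=ps,
        section_thickness=plan.section_thickness,
    )
    lab_stack = (
        SectionStack(
            sections=lab_sections,
            pixel_size_xy=ps,
            section_thickness=plan.section_thickness,
        )
        if labels is not None
        else None
    )
    return img_stack, lab_stack, truth


def analytic_ni(spec: VesselSpec, s: float) -> float:
    """Ground-truth neointimal index (percent) at arclength fraction ``s``.

    NI = 100 * (R^2 - r(s)^2) / R^2 for an annulus with outer radius R and
    lumen radius r(s) — the area ratio in closed form.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("arclength fraction must be in [0, 1]")
    R = spec.outer_radius_um
    r = float(spec.profile(np.asarray(s)))
    return 100.0 * (R**2 - r**2) / R**2


def analytic_class_volumes(spec: VesselSpec, n_quad: int = 2001) -> dict[str, float]:
    """Closed-form lumen and neointima volumes in µm³.

    For both straight and arc centerlines the volume is the arclength
    integral of the cross-sectional area (for the arc this is exact by
    Pappus' theorem: the annulus centroid lies on the centerline).
    """
    L = spec.total_arclength_um
    s = np.linspace(0.0, 1.0, n_quad)
    r = spec.profile(s)
    R = spec.outer_radius_um
    v_lumen = float(np.trapezoid(math.pi * r**2, s) * L)
    v_neo = float(np.trapezoid(math.pi * (R**2 - r**2), s) * L)
    return {"lumen_um3": v_lumen, "neointima_um3": v_neo}


def analytic_nvi(spec: VesselSpec) -> float:
    """Ground-truth neointimal volume index (percent) of the whole segment."""
    v = analytic_class_volumes(spec)
    return 100.0 * v["neointima_um3"] / (v["neointima_um3"] + v["lumen_um3"])
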