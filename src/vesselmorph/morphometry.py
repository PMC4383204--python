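"""Neointimal morphometry: NI per cross-section, NVI per segment, and the
oblique-sectioning bias analytics.

The neointimal index (NI) of a single vessel cross-section is

    NI = 100 * A_neointima / (A_neointima + A_lumen)

an area ratio, so it is invariant to uniform rescaling of both areas — in
particular, obliquely cutting a *straight* vessel scales both areas by
1/cos(tilt) and leaves NI unchanged.  For curved vessels that argument
fails: near-tangential cuts inflate NI, which is what perpendicular
re-slicing corrects.

The neointimal volume index (NVI) extends NI to a reconstructed segment:

    NVI = 100 * V_neointima / (V_neointima + V_lumen)

computed by voxel counting on the segmented label volume.  Areas are
likewise obtained by pixel counting on nearest-neighbour-resampled label
sections (no subpixel boundary fitting), keeping NI and NVI mutually
consistent.  NVI is conventionally reported at 3 decimals; tables retain
full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .containers import LUMEN, NEOINTIMA, LabelVolume
from .reslice import Centerline, CrossSection
from .segmentation import class_volumes

__all__ = [
    "SegmentMorphometry",
    "MorphometryResult",
    "ni",
    "ni_from_label_section",
    "nvi_from_volumes",
    "nvi",
    "morphometry_from_series",
    "oblique_thickness",
    "max_radial_thickness",
    "compare_series",
]


@dataclass
class SegmentMorphometry:
    """Segment-level volumes and the neointimal volume index."""

    neointima_voxels: int
    neointima_um3: float
    neointima_plus_lumen_voxels: int
    neointima_plus_lumen_um3: float
    nvi_percent: float

    @property
    def nvi_rounded(self) -> float:
        return round(self.nvi_percent, 3)


@dataclass
class MorphometryResult:
    """Per-cross-section NI series plus the segment NVI.

    ``provenance`` records whether the series came from raw stack-plane
    sections (``conventional_stack_plane``) or from perpendicular virtual
    re-slicing (``corrected_perpendicular``).
    """

    per_section: pd.DataFrame  # arclength_um, area_neointima_um2, area_lumen_um2, ni_percent
    segment: SegmentMorphometry | None
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in ("conventional_stack_plane", "corrected_perpendicular"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        s = self.per_section["ni_percent"]
        if len(s) and not ((s >= 0).all() and (s <= 100).all()):
            raise ValueError("NI values must lie in [0, 100]")


def ni(neointimal_area: float, luminal_area: float) -> float:
    """Neointimal index (percent) from neointimal and luminal areas.

    Units cancel: µm² and raw pixel counts give the same NI.
    """
    if neointimal_area < 0 or luminal_area < 0:
        raise ValueError("areas must be non-negative")
    total = neointimal_area + luminal_area
    if total == 0:
        raise ValueError("no vessel in section (both areas are zero)")
    return 100.0 * neointimal_area / total


def ni_from_label_section(
    section: np.ndarray | CrossSection, pixel_area: float = 1.0
) -> tuple[float, float, float]:
    """Areas (µm²) and NI of a 2-D label image by pixel counting.

    Returns ``(area_neointima, area_lumen, ni_percent)``.
    """
    if isinstance(section, CrossSection):
        pixel_area = section.pixel_area_um2
        section = section.image
    section = np.asarray(section)
    a_n = float(np.count_nonzero(section == NEOINTIMA)) * pixel_area
    a_l = float(np.count_nonzero(section == LUMEN)) * pixel_area
    return a_n, a_l, ni(a_n, a_l)


def nvi_from_volumes(v_neointima: float, v_lumen: float) -> float:
    """Neointimal volume index (percent) from class volumes (any consistent
    units — voxel counts or µm³)."""
    if v_neointima < 0 or v_lumen < 0:
        raise ValueError("volumes must be non-negative")
    total = v_neointima + v_lumen
    if total == 0:
        raise ValueError("no vessel in segment (neointima + lumen volume is zero)")
    return 100.0 * v_neointima / total


def nvi(
    labels: LabelVolume,
    centerline: Centerline | None = None,
    arclength_range: tuple[float, float] | None = None,
) -> SegmentMorphometry:
    """Segment NVI by voxel counting, optionally restricted along the vessel.

    With ``arclength_range = (s0, s1)`` (µm) and a centerline, only voxels
    whose nearest centerline point has arclength in the range are counted —
    how a sub-segment (e.g. the distal portion) is isolated.
    """
    if arclength_range is not None:
        if centerline is None:
            raise ValueError("arclength_range requires a centerline")
        data = labels.data
        vessel = np.argwhere((data == LUMEN) | (data == NEOINTIMA))
        phys = np.asarray(labels.origin) + vessel * np.asarray(labels.spacing)
        tree = cKDTree(centerline.points)
        _, nearest = tree.query(phys)
        s = centerline.arclength[nearest]
        keep = (s >= arclength_range[0]) & (s <= arclength_range[1])
        vx = labels.voxel_volume_um3
        kept = vessel[keep]
        codes = data[kept[:, 0], kept[:, 1], kept[:, 2]]
        n_neo = int(np.count_nonzero(codes == NEOINTIMA))
        n_lum = int(np.count_nonzero(codes == LUMEN))
    else:
        vols = class_volumes(labels)
        vx = labels.voxel_volume_um3
        n_neo = vols["neointima"]["voxels"]
        n_lum = vols["lumen"]["voxels"]
    value = nvi_from_volumes(n_neo, n_lum)
    return SegmentMorphometry(
        neointima_voxels=n_neo,
        neointima_um3=n_neo * vx,
        neointima_plus_lumen_voxels=n_neo + n_lum,
        neointima_plus_lumen_um3=(n_neo + n_lum) * vx,
        nvi_percent=value,
    )


def morphometry_from_series(
    label_sections: list[CrossSection],
    arclengths: np.ndarray,
    segment: SegmentMorphometry | None = None,
    provenance: str = "corrected_perpendicular",
    min_vessel_pixels: int = 1,
) -> MorphometryResult:
    """Assemble a per-section NI table from resampled label cross-sections.

    Sections with fewer than ``min_vessel_pixels`` vessel pixels are dropped
    (planes beyond the segment ends sample only background).
    """
    rows = []
    for cs, s in zip(label_sections, arclengths):
        img = cs.image
        n_vessel = np.count_nonzero((img == LUMEN) | (img == NEOINTIMA))
        if n_vessel < min_vessel_pixels:
            continue
        a_n, a_l, value = ni_from_label_section(cs)
        rows.append(
            {
                "arclength_um": float(s),
                "area_neointima_um2": a_n,
                "area_lumen_um2": a_l,
                "ni_percent": value,
            }
        )
    frame = pd.DataFrame(rows, columns=["arclength_um", "area_neointima_um2",
                                        "area_lumen_um2", "ni_percent"])
    return MorphometryResult(per_section=frame, segment=segment, provenance=provenance)


def oblique_thickness(true_thickness: float, tilt_deg: float) -> float:
    """Apparent linear thickness of a layer cut at ``tilt_deg`` obliquity:
    ``t / cos(tilt)``.  A 60° cut doubles the apparent thickness."""
    if not 0 <= tilt_deg < 90:
        raise ValueError("tilt must satisfy 0 <= tilt < 90 degrees")
    return true_thickness / math.cos(math.radians(tilt_deg))


def max_radial_thickness(
    label_section: np.ndarray,
    pixel_size: float = 1.0,
    n_angles: int = 360,
    radial_step: float = 0.25,
) -> float:
    """Maximal radial neointimal width (µm) of a 2-D label section.

    Rays are cast from the lumen centroid; along each ray the neointimal
    width is the length of the ray covered by neointima pixels, and the
    maximum over rays is returned — the classical single-dimension
    thickness measurement whose oblique-cut inflation motivates NI.
    """
    section = np.asarray(label_section)
    lumen = np.argwhere(section == LUMEN)
    if len(lumen) == 0:
        raise ValueError("section contains no lumen")
    cy, cx = lumen.mean(axis=0)
    max_r = float(np.hypot(*section.shape))
    radii = np.arange(0.0, max_r, radial_step)
    best = 0.0
    for theta in np.linspace(0.0, 2 * math.pi, n_angles, endpoint=False):
        ys = cy + radii * math.sin(theta)
        xs = cx + radii * math.cos(theta)
        valid = (ys >= 0) & (ys < section.shape[0]) & (xs >= 0) & (xs < section.shape[1])
        samples = section[ys[valid].astype(int), xs[valid].astype(int)]
        width = np.count_nonzero(samples == NEOINTIMA) * radial_step * pixel_size
        best = max(best, width)
    return best


def compare_series(
    conventional: MorphometryResult,
    corrected: MorphometryResult,
    split_um: float | None = None,
    match_tolerance_um: float = 1e-6,
) -> pd.DataFrame:
    """Conventional-vs-corrected NI comparison with a paired t-test.

    Both results must hold equally many sections matched by arclength.  The
    series is summarized over its full length and over the proximal/distal
    halves split at ``split_um`` (default: the arclength midpoint).  Returns
    one row per part with means, SDs, the mean paired difference, the paired
    t statistic, df = n - 1 and the two-sided p value.
    """
    a = conventional.per_section.sort_values("arclength_um").reset_index(drop=True)
    b = corrected.per_section.sort_values("arclength_um").reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError(f"section count mismatch: {len(a)} vs {len(b)}")
    if not np.allclose(a["arclength_um"], b["arclength_um"], atol=max(match_tolerance_um, 1e-9)):
        raise ValueError("series are not matched by arclength")

    s = a["arclength_um"].to_numpy()
    if split_um is None:
        split_um = 0.5 * (s[0] + s[-1])
    parts = {
        "full_length": np.ones_like(s, dtype=bool),
        "proximal": s < split_um,
        "distal": s >= split_um,
    }
    rows = []
    for name, mask in parts.items():
        x = a["ni_percent"].to_numpy()[mask]
        y = b["ni_percent"].to_numpy()[mask]
        n = len(x)
        if n == 0:
            continue
        if n >= 2 and not np.allclose(x, y):
            t_res = stats.ttest_rel(x, y)
            t_stat, p = float(t_res.statistic), float(t_res.pvalue)
        elif n >= 2:
            t_stat, p = 0.0, 1.0  # identical series: zero difference
        else:
            t_stat, p = float("nan"), float("nan")
        rows.append(
            {
                "part": name,
                "n": n,
                "conventional_mean": float(np.mean(x)),
                "conventional_sd": float(np.std(x, ddof=1)) if n > 1 else 0.0,
                "corrected_mean": float(np.mean(y)),
                "corrected_sd": float(np.std(y, ddof=1)) if n > 1 else 0.0,
                "mean_paired_diff": float(np.mean(x - y)),
                "t": t_stat,
                "df": n - 1,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
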