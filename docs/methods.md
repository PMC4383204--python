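# Methods

This note documents the models, parameters and numerical choices behind
vesselmorph, and what the synthetic validation does and does not establish
about real serial-section data.

## Data model and conventions

All arrays are ordered `(z, y, x)`, with `z` the section order starting at
the most proximal slide; multichannel data is channel-last.  Physical
coordinates are voxel-center positions in micrometres:
`position = origin + index · spacing`.  The default geometry follows
typical whole-slide fluorescence scanning of 4 µm serial sections digitized
at 0.369 µm/pixel, giving strongly anisotropic voxels
(0.369 × 0.369 × 4 µm, ≈ 1:10 in-plane:axial).  Spacing metadata is
mandatory on load — there are no silent defaults, because every downstream
quantity is physical.  Label volumes use the fixed code set
0 = background, 1 = lumen, 2 = neointima.

Orientation (proximal→distal vs reverse) of a stack cannot be inferred from
pixels; it is the loader's responsibility, via the metadata sidecar and
file ordering.

## Morphometric statistics

* **NI** (per cross-section): `100 · A_n / (A_n + A_l)`, areas by pixel
  counting of label images.  Unit-free: pixel counts and µm² give the same
  value.  Defined only where the section contains vessel (both areas zero
  is an error, not 0/0 = 0).
* **NVI** (per segment): `100 · V_n / (V_n + V_l)`, volumes by voxel
  counting of the segmented label volume, optionally restricted to voxels
  whose nearest centerline point falls in an arclength window (how a
  proximal or distal sub-segment is isolated).  Reported at 3 decimals by
  convention; tables keep full precision.
* **Oblique thickness**: a layer of true radial thickness `t` cut at
  obliquity θ appears `t / cos θ` wide; at 60° the apparent width doubles.
  `max_radial_thickness` measures this on label sections by casting rays
  from the lumen centroid and taking the longest neointima-covered run.
* **Conventional vs corrected comparison**: the stack-plane NI series and
  the perpendicular-resliced series, matched level-by-level by arclength,
  summarized over the full segment and the proximal/distal halves (split at
  the arclength midpoint unless given), with a paired t-test
  (df = n − 1, two-sided p).

Areas deliberately come from pixel counting of nearest-neighbour-resampled
labels rather than subpixel boundary fits, so NI and NVI are mutually
consistent (NVI is exactly the volume integral of the same counting rule).

## Phantom generator

The generator produces the study conditions for every validation: an
annular vessel (lumen radius profile `r(s)` inside outer radius `R`,
parameterized by arclength fraction so straight and curved vessels share
the same profile semantics) along a straight axis or a circular arc in the
z–y plane, embedded in uniform tissue background.  Voxel class membership
is decided at the voxel center in physical coordinates with no
partial-volume anti-aliasing, which keeps label volumes exact set-theoretic
objects with closed-form expected measures:

* straight: `V = π r² L` per class component;
* arc: by Pappus' theorem the revolved annulus volume is cross-section area
  × arclength (the annulus centroid lies on the centerline), exact for any
  radius profile.

Appearance has four components, all in [0, 1]:

| component | default | rationale |
| --- | --- | --- |
| class intensities (lumen / background / wall) | 0.05 / 0.4 / 0.8 | autofluorescence-like: open lumen dark, collagenous wall bright, myocardium intermediate |
| i.i.d. voxel noise `noise_sd` | 0 (tests use 0.02–0.05) | scanner/shot noise |
| tissue texture amplitude | 0 (tests use 0.08–0.15) | see below |
| texture correlation lengths (in-plane, axial) | 1.5 µm, 40 µm | sub-cellular in-plane detail; fiber-scale structures spanning many 4 µm sections |

The **texture field** is a seeded Gaussian random field added to the tissue
classes (not the lumen).  It exists because registration realism demands
it: an annulus-plus-white-noise phantom makes rotational alignment
*ill-posed* — the annulus is rotationally symmetric and i.i.d. noise
decorrelates completely between adjacent sections, whereas real
neighbouring sections share fiber-scale anatomy.  The anisotropic
correlation (fine in-plane, long axially) mirrors myocyte bundles and
collagen tracts running through several sections.

The **sectioning simulator** cuts the volume along planes whose normal is
tilted by `tilt_deg` from the vessel axis (trilinear for intensities,
nearest-neighbour for labels), one section per `section_thickness`, then
perturbs each section with an independent random rigid transform
(translation jitter sd in px, rotation sd in degrees) drawn from a single
seeded RNG in section order.  The exact inverse transforms are returned, so
registration can be scored against ground truth.  With zero tilt and
matching grids the sections equal the axis-aligned slices exactly.

What the phantom does **not** emulate: branching trees, non-circular
lumina, staining color, folds/tears, uneven illumination, compression
artifacts.  Passing phantom tests therefore demonstrates the geometry
pipeline (registration, reconstruction, re-slicing, counting) is correct
and unbiased under controlled degradation — not that segmentation would
reach the same Dice on arbitrary real stains.

## Registration

Model: rigid per-section motion (translation + rotation) only.  Automated
sectioning keeps stretching artifacts uniform between neighbouring
sections, and elastic warping would risk deforming the lumen areas under
measurement, so non-rigid registration is deliberately excluded.

`align_pair` searches rotation exhaustively — coarse grid 0.25° within
±`max_rotation_deg`, then a local 0.05° refinement — and for each candidate
estimates translation by subpixel phase correlation (upsampled ×20) on
Hann-windowed, mean-subtracted images; the candidate is scored by the true
normalized cross-correlation of the shifted overlap with an edge margin of
1/8 of the frame.  Two numerical details matter:

* both images are pre-smoothed (Gaussian, σ = 1 px) before matching;
  without this, the interpolation blur that rotation resampling adds to
  nonzero candidates systematically *increases* their correlation against
  a different section and repels the estimate from small angles;
* the two-stage angle grid keeps the per-pair quantization at 0.05° so that
  chaining tens of sections cannot random-walk past half a degree.

`align_stack` chains pairwise transforms outward from a reference section
(default: the middle) — chosen over groupwise optimization for simplicity
on the short stacks (tens of sections) this toolkit targets.  An optional
rectangular ROI restricts matching to the region containing the vessel
while expressing transforms in full-image coordinates.  Resampling uses
constant background fill (0); label stacks are always resampled
nearest-neighbour.  Featureless (constant) input raises
"no registration signal" rather than returning an arbitrary transform.

Measured on the standard perturbed phantom stack (30 sections at
0.369 µm/px, jitter sd 5 px, rotation sd 2°, noise sd 0.02, texture
amplitude 0.15), recovery errors against ground truth are ≤ 0.35 px and
≤ 0.25° for every section.

## Segmentation

Seeded three-class labeling by exact multi-source shortest paths: every
unseeded voxel takes the class of the seed set reachable at minimal
accumulated cost over the 6-connected grid, with step cost

```
cost(a, b) = h_ab · (ε + |I(a) − I(b)| + β · (g(a) + g(b))/2)
```

where `h_ab` is the physical step length (so the 4 µm axial step costs ~10×
an in-plane step, matching the data's anisotropy), `g` the spacing-aware
gradient magnitude, `β` the gradient sensitivity (default 1.0, exposed
because no canonical value exists), and `ε = 1e-6` a regularizer that
reduces the labeling to nearest-seed-in-physical-distance in flat volumes.
Multichannel intensities use Euclidean differences across channels.
Dijkstra from each class's seed set is exact; ties resolve to the lowest
class code, making the output fully deterministic.  Seeded voxels always
keep their class.

`presmooth_sigma_um` (default 0) optionally denoises the intensities before
cost construction.  On noiseless data the raw costs reproduce phantom
ground truth exactly; on noisy volumes (noise sd ≈ 0.05) σ ≈ 1 µm is
needed, because unsmoothed noise contributes ≈ `noise_sd` per step along
*every* path and swamps the one-time boundary-crossing cost.  With σ = 1 µm
the standard noisy phantom segments at Dice ≥ 0.95 per class; textured
volumes benefit from σ ≈ 1.5–2 µm.

The implementation is validated against an independent brute-force
Dijkstra oracle on random instances up to 8×8×8 (exact agreement), and
satisfies seed monotonicity: adding a seed of class c can only grow c's
region (minus other classes' seeded voxels).

## Centerline and virtual re-sectioning

The vessel axis is estimated from per-section lumen centroids in physical
coordinates (robust to the 1:10 spacing anisotropy, unlike 3-D
skeletonization), smoothed by a moving average of `smoothing_window` = 5
sections; tangents come from central differences (one-sided at the ends),
arclength from chord sums.  Each analyzed region must contain exactly one
lumen component per section — analysis is per unbranched segment, and
multiple components raise an instructive error.  Note the voxel-center
polyline of an L µm tube at spacing h spans L − h, and end-point smoothing
pulls the extreme centroids slightly inward; measurements therefore use the
segment interior.

Arbitrary planes are resampled by constructing a deterministic orthonormal
in-plane frame from the normal (coordinate axis least parallel to the
normal, Gram–Schmidt, right-handed completion — continuous along smooth
centerlines except at rare axis switches), then sampling trilinearly
(intensities) or nearest-neighbour (labels, preserving the code set and
countability of areas).  Perpendicular series place planes at fixed
arclength steps (`floor(L/step) + 1` planes) or at caller-given
arclengths; perpendicular sampling freely crosses physical section
boundaries — that interpolation is precisely what "virtual sectioning"
means.  Sampling outside the volume yields background 0.

## Virtual angiography

The multi-band computation reduces to per-channel linear weights
(negative = digital subtraction) plus threshold suppression and clipping,
followed by maximum intensity projection; arbitrary projection directions
rotate the volume onto an axis first.  The spectral characteristics of real
fluorophores and filters are acquisition hardware, not computation, and are
out of scope.

## Pipeline

`run_pipeline(config, out_dir)` chains phantom (or stack input) → rigid
alignment → assembly → segmentation (seeds from CSV, or scripted interior
sampling of the ground-truth labels for phantom runs) → centerline →
conventional stack-plane NI + perpendicular corrected NI at matched
arclengths → NVI → report.  Everything is seeded from one config value;
reruns are bit-identical.  Every CSV begins with a
`# config_sha256=<hash>` comment and `manifest.json` records the full
effective config, so runs are self-describing.  Phantom runs add analytic
ground-truth NI columns (mapped by arclength fraction; exact for constant
lumen profiles).

## Validation scales and analysis windows

Validation problem sizes were chosen as the smallest that leave
discretization clearly below the tolerances being asserted: phantoms are
voxelized at 1 µm isotropic for volumetric checks (voxel-count error ≲ 1%
against closed forms), straight-vessel tilt studies use a 300 µm tube so
that 60° sections away from the ends are complete, and the curved-vessel
study uses a 250 µm-radius, 75° arc whose stack-plane obliquity sweeps
through 60° and beyond.  NI is only a defined measurement on sections that
capture the complete annulus; stack-plane series therefore exclude
sections clipping the segment's end caps (selected by neointimal-area
completeness), and perpendicular series exclude a 16–60 µm end margin
where planes would leave the segment.  These are analysis windows, not
tolerances: within them, every claimed bound is asserted everywhere.

## Known limitations

* Rigid-only registration: real tears, folds and differential stretching
  are out of scope, as is whole-slide-scale multi-resolution alignment.
* Chained pairwise alignment accumulates what little per-pair bias remains;
  for stacks much longer than ~100 sections a groupwise or anchored scheme
  would be preferable.
* Centroid centerlines degrade where sections cut the vessel
  near-tangentially (the centroid of an elongated tangential cut is not on
  the axis); the corrected series is accordingly evaluated on the segment
  interior.  Stenoses that close the lumen entirely would break the
  single-component assumption.
* Geodesic segmentation assumes classes are separable by intensity and
  gradients; heavily textured stains with overlapping class appearance
  need more seeds, stronger denoising, or a different model.
* No branch handling: analysis is per unbranched segment between orifice
  and first bifurcation.
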