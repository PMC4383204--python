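"""Rigid transforms and section-stack alignment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import vesselmorph as vm
from vesselmorph.registration import (
    RigidTransform2D,
    align_pair,
    align_stack,
    apply_transform_image,
    apply_transforms,
    transforms_from_frame,
    transforms_to_frame,
)

CENTER = (31.5, 31.5)


def _texture(seed=0, shape=(64, 64)):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.random(shape), 1.5).astype(np.float64)


finite = st.floats(min_value=-20, max_value=20)
angles = st.floats(min_value=-30, max_value=30)


class TestTransformAlgebra:
    @given(finite, finite, angles)
    def test_inverse_composes_to_identity(self, dx, dy, theta):
        t = RigidTransform2D(dx=dx, dy=dy, theta_deg=theta, center=CENTER)
        assert t.compose(t.inverse()).is_identity(tol=1e-9)
        assert t.inverse().compose(t).is_identity(tol=1e-9)

    @given(finite, finite, angles, finite, finite, angles)
    def test_composition_matches_pointwise_application(self, ax, ay, at, bx, by, bt):
        a = RigidTransform2D(dx=ax, dy=ay, theta_deg=at, center=CENTER)
        b = RigidTransform2D(dx=bx, dy=by, theta_deg=bt, center=CENTER)
        p = np.array([3.0, -7.0])
        assert np.allclose(a.compose(b).apply_points(p), a.apply_points(b.apply_points(p)))

    def test_composition_requires_common_center(self):
        a = RigidTransform2D(0, 0, 0, center=(0, 0))
        b = RigidTransform2D(0, 0, 0, center=(5, 5))
        with pytest.raises(ValueError, match="center"):
            a.compose(b)

    def test_csv_frame_round_trip(self):
        ts = [
            RigidTransform2D(dx=1.5, dy=-2.0, theta_deg=0.75, center=CENTER),
            RigidTransform2D.identity(CENTER),
        ]
        frame = transforms_to_frame(ts)
        assert list(frame.columns) == ["section_index", "dx_px", "dy_px", "theta_deg"]
        back = transforms_from_frame(frame, CENTER)
        assert back == ts


class TestAlignPair:
    def test_identical_images_give_identity(self):
        img = _texture()
        t = align_pair(img, img, max_rotation_deg=3.0)
        assert abs(t.dx) < 0.1 and abs(t.dy) < 0.1 and abs(t.theta_deg) < 0.1

    def test_pure_translation_recovered(self):
        img = _texture(1)
        applied = RigidTransform2D(dx=-3.0, dy=5.0, theta_deg=0.0, center=CENTER)
        moving = apply_transform_image(img, applied, order=1)
        t = align_pair(img, moving, max_rotation_deg=0.0)
        assert t.dy == pytest.approx(-5, abs=0.2)
        assert t.dx == pytest.approx(3, abs=0.2)
        assert t.theta_deg == 0.0

    def test_known_rigid_motion_recovered(self):
        img = _texture(2, shape=(96, 96))
        applied = RigidTransform2D(dx=2.3, dy=-1.7, theta_deg=1.8, center=(47.5, 47.5))
        moving = apply_transform_image(img, applied, order=1)
        est = align_pair(img, moving, max_rotation_deg=4.0)
        truth = applied.inverse()
        assert est.dx == pytest.approx(truth.dx, abs=0.2)
        assert est.dy == pytest.approx(truth.dy, abs=0.2)
        assert est.theta_deg == pytest.approx(truth.theta_deg, abs=0.1)

    def test_roi_transform_in_full_image_coordinates(self):
        img = _texture(3, shape=(96, 96))
        moving = np.roll(img, 4, axis=1)
        t = align_pair(img, moving, max_rotation_deg=1.0, roi=(16, 16, 64, 64))
        assert t.dx == pytest.approx(-4, abs=0.15)
        assert t.center == (16 + 63 / 2.0, 16 + 63 / 2.0)

    def test_featureless_image_raises(self):
        flat = np.zeros((32, 32))
        with pytest.raises(ValueError, match="no registration signal"):
            align_pair(flat, flat)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            align_pair(np.zeros((8, 8)), np.zeros((9, 9)))


class TestApplyTransforms:
    def _stack(self, seed=0, n=5):
        return vm.SectionStack(
            sections=[_texture(seed + k) for k in range(n)],
            pixel_size_xy=1.0,
            section_thickness=4.0,
        )

    def test_identity_leaves_stack_unchanged(self):
        stack = self._stack()
        ts = [RigidTransform2D.identity(CENTER)] * len(stack)
        out = apply_transforms(stack, ts, "linear")
        assert np.allclose(out.as_array(), stack.as_array())

    def test_forward_then_inverse_is_near_identity(self):
        stack = self._stack(1)
        t = RigidTransform2D(dx=3.2, dy=-2.1, theta_deg=2.0, center=CENTER)
        fwd = apply_transforms(stack, [t] * len(stack), "linear")
        back = apply_transforms(fwd, [t.inverse()] * len(stack), "linear")
        core = (slice(8, -8), slice(8, -8))
        for a, b in zip(back.sections, stack.sections):
            assert np.allclose(a[core], b[core], atol=0.06)

    def test_nearest_keeps_label_codes(self, noiseless_seg_phantom):
        _, _, lab = noiseless_seg_phantom
        stack = vm.SectionStack(
            sections=[lab.data[k] for k in range(lab.shape[0])],
            pixel_size_xy=1.0,
            section_thickness=2.0,
        )
        t = RigidTransform2D(dx=1.7, dy=-0.4, theta_deg=3.0,
                             center=((lab.shape[1] - 1) / 2, (lab.shape[2] - 1) / 2))
        out = apply_transforms(stack, [t] * len(stack), "nearest")
        assert set(np.unique(out.as_array())) <= {0, 1, 2}

    def test_count_mismatch_rejected(self):
        stack = self._stack()
        with pytest.raises(ValueError, match="transforms"):
            apply_transforms(stack, [RigidTransform2D.identity(CENTER)], "linear")


class TestAlignStack:
    def _volume_stack(self, n=10, jitter=0.0, rotation=0.0, seed=9):
        spec = vm.VesselSpec(
            length_um=4.0 * (n + 3), outer_radius_um=20.0, lumen_radius_profile=10.0,
            noise_sd=0.02, texture_amplitude=0.15,
        )
        vol, lab = vm.generate_vessel_volume(spec, spacing=(4.0, 1.0, 1.0), seed=seed)
        zs = [k for k in range(lab.shape[0]) if np.any(lab.data[k] == vm.LUMEN)]
        vol = vm.Volume(data=vol.data[zs[0] + 1 : zs[0] + 1 + n], spacing=vol.spacing)
        lab = vm.LabelVolume(data=lab.data[zs[0] + 1 : zs[0] + 1 + n], spacing=lab.spacing)
        plan = vm.SectioningSpec(
            pixel_size_xy=1.0, section_thickness=4.0,
            jitter_sd_px=jitter, rotation_sd_deg=rotation, seed=seed,
        )
        return vm.section_volume(vol, lab, plan)

    def test_unperturbed_stack_gives_near_identity(self):
        img, _, _ = self._volume_stack()
        ts = align_stack(img, max_rotation_deg=2.0)
        ref = len(img) // 2
        assert ts[ref].is_identity()
        for t in ts:
            assert math.hypot(t.dx, t.dy) < 0.5
            assert abs(t.theta_deg) < 0.5

    def test_jitter_only_drift_below_one_pixel(self):
        img, _, truth = self._volume_stack(jitter=3.0)
        ts = align_stack(img, max_rotation_deg=0.0)
        ref = len(img) // 2
        for k, t in enumerate(ts):
            rel = truth[ref].inverse().compose(truth[k])
            assert math.hypot(t.dx - rel.dx, t.dy - rel.dy) <= 1.0

    def test_global_shift_equivariance(self):
        img, _, _ = self._volume_stack(seed=13)
        shift = RigidTransform2D(dx=3.0, dy=0.0, theta_deg=0.0,
                                 center=((img.section_shape[0] - 1) / 2,
                                         (img.section_shape[1] - 1) / 2))
        shifted = vm.SectionStack(
            sections=[apply_transform_image(s, shift, order=1) for s in img.sections],
            pixel_size_xy=img.pixel_size_xy,
            section_thickness=img.section_thickness,
        )
        a = align_stack(img, max_rotation_deg=1.0)
        b = align_stack(shifted, max_rotation_deg=1.0)
        for ta, tb in zip(a, b):
            assert ta.dx == pytest.approx(tb.dx, abs=0.2)
            assert ta.dy == pytest.approx(tb.dy, abs=0.2)
            assert ta.theta_deg == pytest.approx(tb.theta_deg, abs=0.3)

    def test_reversed_stack_yields_inverse_transforms(self):
        img, _, truth = self._volume_stack(jitter=2.0, seed=17, n=9)
        fwd = align_stack(img, reference=4, max_rotation_deg=1.0)
        rev_stack = vm.SectionStack(
            sections=list(reversed(img.sections)),
            pixel_size_xy=img.pixel_size_xy,
            section_thickness=img.section_thickness,
        )
        rev = align_stack(rev_stack, reference=4, max_rotation_deg=1.0)
        for k in range(len(img)):
            a, b = fwd[k], rev[len(img) - 1 - k]
            assert a.dx == pytest.approx(b.dx, abs=0.3)
            assert a.dy == pytest.approx(b.dy, abs=0.3)
            assert a.theta_deg == pytest.approx(b.theta_deg, abs=0.2)

    def test_failing_pair_is_reported(self):
        img, _, _ = self._volume_stack(n=6)
        sections = list(img.sections)
        sections[2] = np.zeros_like(sections[2])
        broken = vm.SectionStack(
            sections=sections, pixel_size_xy=1.0, section_thickness=4.0
        )
        with pytest.raises(ValueError, match=r"pair \((1, 2|2, 1|2, 3|3, 2)\)"):
            align_stack(broken, max_rotation_deg=1.0)
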