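"""Centerline extraction and perpendicular virtual re-sectioning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vesselmorph as vm
from vesselmorph.reslice import Centerline, plane_frame


def straight_tube_labels(length=40, radius=6, shape=(40, 21, 21), spacing=(1.0, 1.0, 1.0)):
    z, y, x = np.indices(shape)
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    lumen = (np.hypot(y - cy, x - cx) < radius) & (z < length)
    data = np.where(lumen, vm.LUMEN, vm.BACKGROUND).astype(np.uint8)
    return vm.LabelVolume(data=data, spacing=spacing)


class TestExtractCenterline:
    def test_straight_tube_tangents_along_z(self):
        labels = straight_tube_labels()
        cl = vm.extract_centerline(labels)
        assert np.allclose(cl.tangents, [1.0, 0.0, 0.0], atol=1e-6)

    def test_straight_tube_arclength(self):
        labels = straight_tube_labels(length=40, shape=(40, 21, 21))
        cl = vm.extract_centerline(labels, smoothing_window=1)
        # 40 slices of 1 µm: voxel-center polyline spans 39 µm
        assert cl.total_arclength == pytest.approx(39.0, abs=0.5)

    def test_arc_tangents_match_analytic_derivative(self, arc_spec, arc_label_volume):
        cl = vm.extract_centerline(arc_label_volume)
        # compare away from the ends (one-sided differences + tangential
        # slices distort the extremes)
        lo, hi = 0.1 * cl.total_arclength, 0.75 * cl.total_arclength
        for point, tangent, s in zip(cl.points, cl.tangents, cl.arclength):
            if not lo <= s <= hi:
                continue
            phi = math.atan2(tangent[1], tangent[0])
            s_frac = phi / math.radians(arc_spec.arc_angle_deg)
            analytic = arc_spec.centerline_tangents(np.clip(s_frac, 0, 1))
            angle = math.degrees(
                math.acos(np.clip(np.dot(tangent, analytic), -1.0, 1.0))
            )
            assert angle <= 2.0

    def test_multiple_lumen_components_rejected(self):
        labels = straight_tube_labels()
        data = labels.data.copy()
        data[:, 2, 2] = vm.LUMEN  # a second, disconnected branch
        with pytest.raises(ValueError, match="crop"):
            vm.extract_centerline(vm.LabelVolume(data=data, spacing=labels.spacing))

    def test_too_few_lumen_slices_rejected(self):
        labels = straight_tube_labels(length=2)
        with pytest.raises(ValueError, match="3 sections"):
            vm.extract_centerline(labels)


unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).filter(lambda v: np.linalg.norm(v) > 1e-3)


class TestPlaneFrame:
    @given(unit_vectors)
    def test_orthonormal_right_handed(self, normal):
        n = np.asarray(normal) / np.linalg.norm(normal)
        e1, e2 = plane_frame(n)
        assert abs(np.dot(e1, n)) < 1e-9
        assert abs(np.dot(e2, n)) < 1e-9
        assert abs(np.dot(e1, e2)) < 1e-9
        assert np.linalg.norm(e1) == pytest.approx(1.0)
        assert np.linalg.norm(e2) == pytest.approx(1.0)
        assert np.allclose(np.cross(n, e1), e2)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError, match="zero normal"):
            plane_frame((0.0, 0.0, 0.0))


class TestResamplePlane:
    def test_axis_aligned_plane_reproduces_section(self, noiseless_seg_phantom):
        _, vol, _ = noiseless_seg_phantom
        k = vol.shape[0] // 2
        size = 41
        cy, cx = (vol.shape[1] - 1) / 2, (vol.shape[2] - 1) / 2
        center = vol.physical_position((k, cy, cx))
        cs = vm.resample_plane(
            vol, center, normal=(1.0, 0.0, 0.0), size=size, pixel_size=1.0,
            interpolation="nearest",
        )
        half = (size - 1) // 2
        y0, x0 = int(cy) - half, int(cx) - half
        crop = vol.data[k, y0 : y0 + size, x0 : x0 + size]
        # frame axes may be permuted/flipped relative to (y, x); compare sets
        assert crop.sum() == pytest.approx(cs.image.sum())
        assert np.allclose(np.sort(cs.image.ravel()), np.sort(crop.ravel()))

    def test_label_plane_keeps_codes(self, arc_label_volume):
        cl = vm.extract_centerline(arc_label_volume)
        point, tangent = cl.interpolate_at(cl.total_arclength / 2)
        cs = vm.resample_plane(arc_label_volume, point, tangent, size=90, pixel_size=1.0)
        assert cs.image.dtype == np.uint8
        assert set(np.unique(cs.image)) <= {0, 1, 2}

    def test_perpendicular_annulus_area_matches_closed_form(
        self, straight_spec, straight_volume
    ):
        _, lab = straight_volume
        cl = vm.extract_centerline(lab)
        point, tangent = cl.interpolate_at(cl.total_arclength / 2)
        cs = vm.resample_plane(lab, point, tangent, size=130, pixel_size=1.0)
        a_n, a_l, _ = vm.ni_from_label_section(cs.image, pixel_area=1.0)
        R, r = straight_spec.outer_radius_um, 25.0
        assert a_n == pytest.approx(math.pi * (R**2 - r**2), rel=0.03)
        assert a_l == pytest.approx(math.pi * r**2, rel=0.03)

    def test_tilted_tube_circularizes_under_perpendicular_reslice(
        self, straight_volume
    ):
        vol, lab = straight_volume
        plan = vm.SectioningSpec(
            pixel_size_xy=1.0, section_thickness=4.0, tilt_deg=60.0, seed=0
        )
        _, labs, _ = vm.section_volume(vol, lab, plan)
        labvol = vm.LabelVolume(
            data=labs.as_array().astype(np.uint8), spacing=(4.0, 1.0, 1.0)
        )

        def axis_ratio(mask):
            ys, xs = np.nonzero(mask)
            cov = np.cov(np.stack([ys, xs]) - np.array([[ys.mean()], [xs.mean()]]))
            evals = np.sort(np.linalg.eigvalsh(cov))
            return math.sqrt(evals[1] / evals[0])

        neo = [np.count_nonzero(s == vm.NEOINTIMA) for s in labs.sections]
        stack_mask = labs.sections[int(np.argmax(neo))] != vm.BACKGROUND
        assert axis_ratio(stack_mask) == pytest.approx(2.0, rel=0.1)

        cl = vm.extract_centerline(labvol)
        point, tangent = cl.interpolate_at(cl.total_arclength / 2)
        cs = vm.resample_plane(labvol, point, tangent, size=130, pixel_size=1.0)
        assert axis_ratio(cs.image != vm.BACKGROUND) == pytest.approx(1.0, abs=0.05)

    def test_rotation_invariance_of_resampling(self, noiseless_seg_phantom):
        _, vol, _ = noiseless_seg_phantom
        # rotate the volume 90° about z (exact axis permutation y -> x)
        rotated = vm.Volume(
            data=np.rot90(vol.data, k=1, axes=(1, 2)).copy(),
            spacing=(vol.spacing[0], vol.spacing[2], vol.spacing[1]),
        )
        k = vol.shape[0] // 2
        cy, cx = (vol.shape[1] - 1) / 2, (vol.shape[2] - 1) / 2
        normal = np.array([0.3, 0.0, 0.954])
        normal /= np.linalg.norm(normal)
        center = vol.physical_position((k, cy, cx))
        cs = vm.resample_plane(vol, center, normal, size=25, pixel_size=1.0)
        rot_normal = np.array([normal[0], normal[2], -normal[1]])
        rcy, rcx = (rotated.shape[1] - 1) / 2, (rotated.shape[2] - 1) / 2
        rcenter = rotated.physical_position((k, rcy, rcx))
        cs_rot = vm.resample_plane(rotated, rcenter, rot_normal, size=25, pixel_size=1.0)
        assert cs.image.mean() == pytest.approx(cs_rot.image.mean(), abs=0.02)
        assert np.sort(cs.image.ravel()) == pytest.approx(
            np.sort(cs_rot.image.ravel()), abs=0.06
        )

    def test_zero_normal_rejected(self, noiseless_seg_phantom):
        _, vol, _ = noiseless_seg_phantom
        with pytest.raises(ValueError, match="zero normal"):
            vm.resample_plane(vol, (0, 0, 0), (0, 0, 0))


class TestPerpendicularSeries:
    def synthetic_centerline(self, length=108.0, n=109):
        z = np.linspace(0.0, length, n)
        points = np.stack([z, np.zeros(n), np.zeros(n)], axis=1)
        return Centerline.from_points(points)

    def test_count_formula(self):
        cl = self.synthetic_centerline(length=108.0)
        labels = straight_tube_labels()
        series = vm.perpendicular_series(None, labels, cl, step=4.0, size=8, pixel_size=1.0)
        assert len(series) == 28

    def test_straight_tube_constant_normals(self):
        labels = straight_tube_labels()
        cl = vm.extract_centerline(labels)
        series = vm.perpendicular_series(None, labels, cl, step=4.0, size=16, pixel_size=1.0)
        for _, lab_cs, _ in series:
            assert np.allclose(lab_cs.normal, [1.0, 0.0, 0.0], atol=1e-6)

    def test_constant_profile_arc_has_constant_ni(self, arc_label_volume):
        cl = vm.extract_centerline(arc_label_volume)
        margin = 16.0
        arcs = cl.arclength[
            (cl.arclength > margin) & (cl.arclength < cl.total_arclength - margin)
        ]
        series = vm.perpendicular_series(
            None, arc_label_volume, cl, arclengths=arcs, size=90, pixel_size=1.0
        )
        nis = np.array([vm.ni_from_label_section(lab_cs)[2] for _, lab_cs, _ in series])
        assert np.all(np.abs(nis - 75.0) <= 2.0)

    def test_degenerate_centerline_rejected(self):
        labels = straight_tube_labels()
        cl = Centerline(
            points=np.array([[0.0, 0.0, 0.0]]),
            tangents=np.array([[1.0, 0.0, 0.0]]),
            arclength=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            vm.perpendicular_series(None, labels, cl, step=4.0)

    def test_nonpositive_step_rejected(self):
        labels = straight_tube_labels()
        cl = self.synthetic_centerline()
        with pytest.raises(ValueError, match="step"):
            vm.perpendicular_series(None, labels, cl, step=0.0)
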