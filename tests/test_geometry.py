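"""Vector/plane arithmetic and LVOT axis reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from aortaflow.errors import (
    DegenerateGeometryError,
    GeometryError,
    InconsistentLandmarksError,
)
from aortaflow.geometry import (
    LandmarkSet,
    PlaneGeometry,
    angle_between,
    in_plane_direction,
    normalize,
    pixel_to_patient,
    patient_to_pixel,
    reconstruct_axis,
)
from conftest import axis_aligned_plane, random_plane, random_unit


class TestPixelToPatient:
    @pytest.mark.parametrize("pixel, origin, spacing, expected", [
        ((0, 0), (0, 0, 0), 1.0, (0, 0, 0)),          # origin maps to itself
        ((0, 10), (0, 0, 0), 1.0, (0, 10, 0)),        # column index -> col_dir
        ((3, 4), (1, 1, 1), 2.0, (7, 9, 1)),          # scaled and offset
    ])
    def test_axis_aligned_mapping(self, pixel, origin, spacing, expected):
        g = axis_aligned_plane(origin=origin, spacing=spacing)
        np.testing.assert_allclose(pixel_to_patient(pixel, g), expected)

    def test_round_trip_with_inverse(self, rng):
        for _ in range(20):
            g = random_plane(rng)
            p = tuple(rng.uniform(-50, 50, size=2))
            np.testing.assert_allclose(patient_to_pixel(pixel_to_patient(p, g), g),
                                       p, atol=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(GeometryError):
            pixel_to_patient((np.nan, 0), axis_aligned_plane())


class TestPlaneGeometry:
    def test_requires_orthogonal_axes(self):
        with pytest.raises(GeometryError):
            PlaneGeometry(origin=(0, 0, 0), row_dir=(1, 0, 0),
                          col_dir=(0.01, 1, 0), spacing_row=1, spacing_col=1)

    def test_requires_positive_spacing(self):
        with pytest.raises(GeometryError):
            PlaneGeometry(origin=(0, 0, 0), row_dir=(1, 0, 0),
                          col_dir=(0, 1, 0), spacing_row=0.0, spacing_col=1)

    def test_normal_is_unit_cross_product(self, rng):
        g = random_plane(rng)
        np.testing.assert_allclose(g.normal, np.cross(g.row_dir, g.col_dir),
                                   atol=1e-12)
        assert np.linalg.norm(g.normal) == pytest.approx(1.0, abs=1e-12)


class TestInPlaneDirection:
    def test_parallel_segments_give_col_dir(self):
        g = axis_aligned_plane()
        l = LandmarkSet(p1=(0, 0), p2=(0, 10), p3=(10, 0), p4=(10, 10))
        np.testing.assert_allclose(in_plane_direction(l, g), (0, 1, 0), atol=1e-12)

    def test_vector_average_of_oblique_segments(self):
        # hand arithmetic: (1,2)+(3,2) = (4,4) -> normalized diagonal
        g = axis_aligned_plane()
        l = LandmarkSet(p1=(0, 0), p2=(1, 2), p3=(0, 0), p4=(3, 2))
        d = in_plane_direction(l, g)
        np.testing.assert_allclose(d, (0.70710678, 0.70710678, 0), atol=1e-8)

    def test_result_lies_in_plane(self, rng):
        for _ in range(20):
            g = random_plane(rng)
            l = LandmarkSet(p1=tuple(rng.uniform(0, 40, 2)),
                            p2=tuple(rng.uniform(60, 100, 2)),
                            p3=tuple(rng.uniform(0, 40, 2)),
                            p4=tuple(rng.uniform(60, 100, 2)))
            d = in_plane_direction(l, g)
            assert abs(np.dot(d, g.normal)) < 1e-9

    def test_antiparallel_segments_rejected(self):
        g = axis_aligned_plane()
        l = LandmarkSet(p1=(0, 0), p2=(0, 10), p3=(10, 10), p4=(10, 0))
        with pytest.raises(InconsistentLandmarksError):
            in_plane_direction(l, g)

    def test_degenerate_segment_rejected_at_construction(self):
        with pytest.raises(GeometryError):
            LandmarkSet(p1=(1, 1), p2=(1, 1), p3=(0, 0), p4=(1, 0))


def _project(v, normal):
    """Independent projection oracle for the round-trip property."""
    n = np.asarray(normal) / np.linalg.norm(normal)
    p = np.asarray(v, float) - np.dot(v, n) * n
    return p / np.linalg.norm(p)


class TestReconstructAxis:
    def test_vector_lying_in_both_planes(self):
        gA = random_plane(np.random.default_rng(1), normal=(1, 0, 0))
        gB = random_plane(np.random.default_rng(2), normal=(0, 1, 0))
        d = reconstruct_axis((0, 0, 1), gA, (0, 0, 1), gB)
        np.testing.assert_allclose(d, (0, 0, 1), atol=1e-12)

    def test_hand_computed_oblique_case(self):
        # projections of (1,1,1) onto z=0 and x=0 planes
        gA = random_plane(np.random.default_rng(3), normal=(0, 0, 1))
        gB = random_plane(np.random.default_rng(4), normal=(1, 0, 0))
        pA = normalize((1, 1, 0))
        pB = normalize((0, 1, 1))
        d = reconstruct_axis(pA, gA, pB, gB)
        np.testing.assert_allclose(d, np.ones(3) / np.sqrt(3), atol=1e-12)

    def test_near_parallel_planes_rejected(self):
        gA = random_plane(np.random.default_rng(5), normal=(0, 0, 1))
        gB = random_plane(np.random.default_rng(6), normal=(0, 0.001, 1))
        with pytest.raises(DegenerateGeometryError):
            reconstruct_axis((1, 0, 0), gA, (1, 0, 0), gB)

    def test_projection_round_trip_oracle(self, rng):
        """1000 random directions and plane pairs: reconstruction inverts
        projection to < 1e-6 degrees."""
        worst = 0.0
        done = 0
        while done < 1000:
            v = random_unit(rng)
            gA, gB = random_plane(rng), random_plane(rng)
            if np.linalg.norm(np.cross(gA.normal, gB.normal)) <= 0.1:
                continue
            pA, pB = _project(v, gA.normal), _project(v, gB.normal)
            # orient projections along v so the sign convention applies
            if np.dot(pA, v) < 0:
                pA = -pA
            if np.dot(pB, v) < 0:
                pB = -pB
            d = reconstruct_axis(pA, gA, pB, gB)
            worst = max(worst, angle_between(d, v))
            done += 1
        assert worst < 1e-6

    def test_rotational_invariance(self, rng):
        """One rigid rotation of planes, landmarks and fields leaves the
        jet/axis angle arithmetic unchanged to < 1e-9 degrees."""
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        for _ in range(25):
            u, v = rng.normal(size=3), rng.normal(size=3)
            assert angle_between(u, v) == pytest.approx(
                angle_between(R @ u, R @ v), abs=1e-9)
        gA, gB = random_plane(rng), random_plane(rng)
        v = random_unit(rng)
        pA, pB = _project(v, gA.normal), _project(v, gB.normal)
        d = reconstruct_axis(pA, gA, pB, gB)

        def rot_plane(g):
            return PlaneGeometry(origin=R @ g.origin, row_dir=R @ g.row_dir,
                                 col_dir=R @ g.col_dir,
                                 spacing_row=g.spacing_row,
                                 spacing_col=g.spacing_col)
        d_rot = reconstruct_axis(R @ pA, rot_plane(gA), R @ pB, rot_plane(gB))
        assert angle_between(d_rot, R @ d) < 1e-9


class TestAngleBetween:
    @pytest.mark.parametrize("u, v, expected", [
        ((1, 0, 0), (1, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_reference_angles(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            angle_between((0, 0, 0), (1, 0, 0))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6),
           st.floats(0.1, 100), st.floats(0.1, 100))
    def test_symmetry_and_scale_invariance(self, comps, ka, kb):
        u = np.array(comps[:3])
        v = np.array(comps[3:])
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        a = angle_between(u, v)
        assert a == pytest.approx(angle_between(v, u), abs=1e-9)
        assert a == pytest.approx(angle_between(ka * u, kb * v), abs=1e-9)
        assert 0.0 <= a <= 180.0
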