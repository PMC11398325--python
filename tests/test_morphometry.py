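"""3D/2D shape morphometrics against analytic shapes and brute-force oracles."""

import numpy as np
import pytest
import trimesh

import geldepot as gd
from geldepot.errors import EmptyMeshError, ValidationError
from tests.conftest import digital_ball, digital_disk


def brute_force_hull_volume(points: np.ndarray, h: float) -> float:
    """Voxelized-fill hull volume/area oracle, independent of Qhull's exact
    polytope volume: count dense subgrid cells whose centers fall inside
    the hull (Delaunay membership test) and multiply by the cell measure."""
    from scipy.spatial import ConvexHull, Delaunay

    pts = np.asarray(points, dtype=float)
    d = pts.shape[1]
    hull = Delaunay(pts[ConvexHull(pts).vertices])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    grids = [np.arange(l + h / 2, u, h) for l, u in zip(lo, hi)]
    centers = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, d)
    return float((hull.find_simplex(centers) >= 0).sum() * h ** d)


def hull_fill_fraction_3d(mask: np.ndarray, h: float = 0.5) -> float:
    """Brute-force solidity oracle over the same hull point set the
    implementation uses (marching-cubes mesh vertices)."""
    verts = gd.mesh_from_mask(mask).vertices
    return mask.sum() / brute_force_hull_volume(verts, h)


def hull_fill_fraction_2d(mask: np.ndarray, h: float = 0.25) -> float:
    """Brute-force 2D solidity oracle over the pixel-corner hull points."""
    idx = np.array(np.nonzero(mask), dtype=float).T
    corners = np.vstack([idx + off for off in np.array(
        np.meshgrid(*[(-0.5, 0.5)] * 2)).reshape(2, -1).T])
    return mask.sum() / brute_force_hull_volume(corners, h)


def as_mesh(tm: trimesh.Trimesh) -> gd.SurfaceMesh:
    return gd.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


class TestMeshFromMask:
    def test_digital_sphere_area_within_2_percent(self):
        mesh = gd.mesh_from_mask(digital_ball(10))
        assert mesh.area_mm2 == pytest.approx(4 * np.pi * 100, rel=0.02)

    def test_mesh_is_watertight(self):
        assert gd.mesh_from_mask(digital_ball(6)).is_watertight()

    def test_single_voxel_is_closed_octahedron(self):
        """A lone voxel is too small to survive anti-alias smoothing, so the
        raw marching-cubes midpoint octahedron is returned: 8 faces of total
        area sqrt(3) (half-diagonal 0.5 in each axis)."""
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        mesh = gd.mesh_from_mask(mask)
        assert mesh.is_watertight()
        assert mesh.n_faces == 8
        assert mesh.area_mm2 == pytest.approx(np.sqrt(3.0), rel=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMeshError):
            gd.mesh_from_mask(np.zeros((4, 4, 4), dtype=bool))

    def test_vertices_in_world_mm(self):
        mesh = gd.mesh_from_mask(digital_ball(8), spacing=(0.5, 0.5, 2.0))
        ext = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        np.testing.assert_allclose(ext, [8.0, 8.0, 32.0], rtol=0.1)


class TestMorphometrics3D:
    def test_analytic_sphere_is_spherical_and_solid(self):
        m = gd.mesh_morphometrics(as_mesh(trimesh.creation.icosphere(4, radius=10.0)))
        assert m.sphericity == pytest.approx(1.0, abs=0.001)
        assert m.solidity == pytest.approx(1.0, abs=1e-9)

    def test_analytic_cube(self):
        m = gd.mesh_morphometrics(as_mesh(trimesh.creation.box(extents=(20, 20, 20))))
        assert m.sphericity == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-9)
        assert m.solidity == pytest.approx(1.0, abs=1e-9)
        assert m.volume_ml == pytest.approx(8.0)
        assert m.surface_area_cm2 == pytest.approx(24.0)
        assert m.sa_to_v_cm == pytest.approx(3.0)

    def test_plus_sign_prism_solidity_matches_hull_fill_oracle(self):
        mask = np.zeros((20, 20, 8), dtype=bool)
        mask[7:13, 2:18, 2:6] = True
        mask[2:18, 7:13, 2:6] = True
        m = gd.morphometrics_3d(mask, spacing=(1, 1, 1))
        oracle = hull_fill_fraction_3d(mask)
        assert m.solidity < 1.0
        # mesh-vertex hull vs voxel-corner hull differ by a sub-voxel band
        assert m.solidity == pytest.approx(oracle, rel=0.05)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_blob_solidity_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.normal(size=(28, 28, 28)), 4.0)
        mask = field > np.percentile(field, 88)
        from scipy.ndimage import label

        lab, _ = label(mask)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == np.argmax(sizes)  # keep the largest blob
        m = gd.morphometrics_3d(mask, spacing=(1, 1, 1))
        assert m.solidity == pytest.approx(hull_fill_fraction_3d(mask), rel=0.08)

    def test_solidity_invariant_under_axis_rotations(self):
        mask = np.zeros((20, 20, 12), dtype=bool)
        mask[7:13, 2:18, 2:6] = True
        mask[2:18, 7:13, 2:6] = True
        base = gd.morphometrics_3d(mask, spacing=(1, 1, 1))
        rotated = gd.morphometrics_3d(np.rot90(mask, axes=(0, 1)), spacing=(1, 1, 1))
        assert rotated.solidity == pytest.approx(base.solidity, rel=1e-6)
        assert rotated.sphericity == pytest.approx(base.sphericity, rel=1e-6)

    def test_scores_are_scale_free(self):
        mask = digital_ball(7)
        a = gd.morphometrics_3d(mask, spacing=(1, 1, 1))
        b = gd.morphometrics_3d(mask, spacing=(2, 2, 2))
        assert b.sphericity == pytest.approx(a.sphericity, rel=1e-6)
        assert b.solidity == pytest.approx(a.solidity, rel=1e-6)
        assert b.volume_ml == pytest.approx(8 * a.volume_ml, rel=1e-12)
        assert b.surface_area_cm2 == pytest.approx(4 * a.surface_area_cm2, rel=1e-6)

    def test_mean_hu_over_mask(self, clean_sphere_spec, clean_sphere_volume):
        from geldepot.synthetic_data import depot_true_mask

        mask = depot_true_mask(clean_sphere_spec)
        m = gd.morphometrics_3d(mask, clean_sphere_volume)
        assert m.mean_hu == pytest.approx(50.0 + 40 * gd.HU_PER_MG_ML)

    def test_sphericity_bounded_by_one_plus_mesh_tolerance(self):
        # 2% mesh tolerance at depot-scale resolution (radius >= 8 voxels);
        # very coarse structures carry a larger discretization band
        for r in (8, 10, 13):
            m = gd.morphometrics_3d(digital_ball(r), spacing=(1, 1, 1))
            assert m.sphericity <= 1.02
        coarse = gd.morphometrics_3d(digital_ball(5), spacing=(1, 1, 1))
        assert coarse.sphericity <= 1.10

    def test_coplanar_points_report_hull_degeneracy(self):
        from geldepot.morphometry import _hull_volume

        flat = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        with pytest.raises(ValidationError, match="degenerate"):
            _hull_volume(flat)


class TestMorphometrics2D:
    def test_digital_circle_circularity_near_one(self):
        m = gd.morphometrics_2d(digital_disk(50))
        assert m.circularity == pytest.approx(1.0, abs=0.03)
        assert m.major_axis_cm == pytest.approx(10.0, rel=0.01)
        assert m.minor_axis_cm == pytest.approx(10.0, rel=0.01)

    def test_digital_square(self):
        mask = np.zeros((111, 111), dtype=bool)
        mask[5:106, 5:106] = True
        m = gd.morphometrics_2d(mask)
        assert m.circularity == pytest.approx(np.pi / 4, rel=0.03)
        assert m.solidity == pytest.approx(1.0, abs=1e-9)
        assert m.area_cm2 == pytest.approx(101 * 101 / 100.0)

    def test_cross_solidity_matches_hull_fill_oracle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 5:35] = True
        mask[5:35, 15:25] = True
        m = gd.morphometrics_2d(mask)
        assert m.solidity < 1.0
        assert m.solidity == pytest.approx(hull_fill_fraction_2d(mask), rel=0.02)

    def test_regular_ngon_circularity_increases_with_n(self):
        from skimage.draw import polygon

        circs = []
        for n in (3, 4, 6, 12):
            theta = np.arange(n) * 2 * np.pi / n
            rr, cc = polygon(100 + 80 * np.sin(theta), 100 + 80 * np.cos(theta),
                             shape=(200, 200))
            mask = np.zeros((200, 200), dtype=bool)
            mask[rr, cc] = True
            circs.append(gd.morphometrics_2d(mask).circularity)
        assert np.all(np.diff(circs) > 0)
        assert circs[-1] < 1.01

    def test_single_pixel_has_finite_axes(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        m = gd.morphometrics_2d(mask)
        assert m.major_axis_cm > 0
        assert m.area_cm2 == pytest.approx(0.01)

    def test_anisotropic_pixels_respected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 10x10 px
        m = gd.morphometrics_2d(mask, pixel_spacing=(2.0, 1.0))
        assert m.area_cm2 == pytest.approx(2.0)  # 100 px * 2 mm^2
        assert m.major_axis_cm > m.minor_axis_cm

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            gd.morphometrics_2d(np.zeros((4, 4), dtype=bool))


class TestSerialPerML:
    def _sphere_mask(self, r_mm, grid=26, h=1.0):
        c = (grid - 1) / 2 * h
        zz, yy, xx = np.mgrid[:grid, :grid, :grid]
        arr = (xx * h - c) ** 2 + (yy * h - c) ** 2 + (zz * h - c) ** 2 <= r_mm ** 2
        return gd.SegmentationMask(mask=arr, spacing=(h, h, h))

    AXIS = (np.array([12.5, 12.5, 0.0]), np.array([0.0, 0.0, 1.0]))

    def test_identical_masks_give_zero_increments(self):
        masks = [self._sphere_mask(8)] * 3
        with pytest.warns(UserWarning, match="non-increasing"):
            dep = gd.serial_per_ml_analysis(masks, self.AXIS)
        np.testing.assert_allclose(dep.incremental_volumes_ml[1:], 0.0, atol=1e-12)
        assert dep.non_increasing_volume

    def test_concentric_spheres_give_unit_ml_increments(self):
        radii = (6.2, 7.8, 8.9, 9.8)  # ~1 mL shells; 0.5 mm grid
        masks = [self._sphere_mask(r, grid=44, h=0.5) for r in radii]
        dep = gd.serial_per_ml_analysis(masks, self.AXIS)
        np.testing.assert_allclose(dep.incremental_volumes_ml, 1.0, rtol=0.05)
        assert not dep.non_increasing_volume

    def test_alignment_of_translated_copy(self):
        base = self._sphere_mask(6, grid=32)
        shift = np.array([4.0, 3.0, 2.0])
        from scipy.ndimage import shift as nd_shift

        moved = gd.SegmentationMask(
            mask=nd_shift(base.mask.astype(float), shift, order=0) > 0.5,
            spacing=(1, 1, 1),
        )
        p0 = np.array([15.5, 15.5, 0.0])
        d = np.array([0.0, 0.0, 1.0])
        dep = gd.serial_per_ml_analysis(
            [base, moved], [(p0, d), (p0 + shift, d)]
        )
        c0 = np.array(np.nonzero(dep.masks[0].mask)).mean(axis=1)
        c1 = np.array(np.nonzero(dep.masks[1].mask)).mean(axis=1)
        assert np.linalg.norm(c1 - c0) < 1.0

    def test_needs_two_steps(self):
        with pytest.raises(ValidationError):
            gd.serial_per_ml_analysis([self._sphere_mask(6)], self.AXIS)
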