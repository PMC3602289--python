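import numpy as np
import pytest
import trimesh

from torsofuse.imagedata import DeformationField, VoxelVolume
from torsofuse.validation import (
    DiceReport,
    UndefinedDiceError,
    build_torso_mesh,
    compare_methods,
    dice_2d,
    dice_3d,
    jacobian_determinant,
    voxelize,
)


def circle_ring(radius, z, n=90, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            center[0] + radius * np.cos(ang),
            center[1] + radius * np.sin(ang),
            np.full(n, z),
        ]
    )


class TestDice2D:
    def test_identical_masks_give_one(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        assert dice_2d(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:5], b[10:] = True, True
        assert dice_2d(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 100, |A & B| = 50 -> 2*50/200 = 0.5
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[0:5, 0:20] = True
        b[0:10, 10:20] = True
        assert a.sum() == b.sum() == 100 and (a & b).sum() == 50
        assert dice_2d(a, b) == 0.5

    def test_symmetry(self, rng):
        a = rng.random((30, 30)) > 0.5
        b = rng.random((30, 30)) > 0.5
        assert dice_2d(a, b) == dice_2d(b, a)

    def test_empty_masks_rejected(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(UndefinedDiceError):
            dice_2d(z, z)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            dice_2d(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestTorsoMesh:
    def test_two_circles_make_a_cylinder(self):
        """Stitching two circular contours 12 mm apart gives a closed
        cylinder with the analytic surface area."""
        R, h = 100.0, 12.0
        mesh = build_torso_mesh([circle_ring(R, 0.0), circle_ring(R, h)])
        assert mesh.is_watertight
        analytic = 2 * np.pi * R * h + 2 * np.pi * R**2
        assert abs(mesh.area - analytic) / analytic < 0.02
        assert abs(mesh.volume - np.pi * R**2 * h) / (np.pi * R**2 * h) < 0.02

    def test_subdivision_quadruples_faces(self):
        rings = [circle_ring(100.0, z) for z in (0.0, 12.0, 24.0)]
        coarse = build_torso_mesh(rings, subdivide=False)
        fine = build_torso_mesh(rings, subdivide=True)
        assert len(fine.faces) == 4 * len(coarse.faces)
        # subdivision keeps the surface within chord tolerance
        assert abs(fine.volume - coarse.volume) / coarse.volume < 1e-9

    def test_stacked_contours_volume(self):
        """Mesh over a stack of circular contours matches the closed-form
        cylinder volume."""
        R, h = 120.0, 396.0
        rings = [circle_ring(R, z) for z in np.arange(0.0, h + 1, 12.0)]
        mesh = build_torso_mesh(rings)
        analytic = np.pi * R**2 * h
        assert abs(mesh.volume - analytic) / analytic < 0.03

    def test_too_few_contours_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_torso_mesh([circle_ring(50.0, 0.0)])


class TestVoxelize:
    def test_box_count(self):
        mesh = trimesh.creation.box(extents=(100.0, 100.0, 99.0))
        vol = voxelize(mesh, spacing=(1.0, 1.0, 3.0))
        ones = int(vol.occupancy.sum())
        assert abs(ones - 100 * 100 * 33) <= 100 * 100  # one boundary layer

    def test_sphere_volume_within_two_percent(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=50.0)
        vol = voxelize(mesh, spacing=(1.0, 1.0, 3.0))
        analytic = 4 / 3 * np.pi * 50.0**3
        assert abs(vol.volume_mm3() - analytic) / analytic < 0.02

    def test_translation_invariance(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=40.0)
        a = voxelize(mesh, spacing=(1.0, 1.0, 3.0))
        moved = mesh.copy()
        moved.vertices = moved.vertices + np.array([13.37, -2.1, 7.77])
        b = voxelize(moved, spacing=(1.0, 1.0, 3.0))
        assert abs(int(a.occupancy.sum()) - int(b.occupancy.sum())) <= 0.005 * a.occupancy.sum()

    def test_non_watertight_rejected(self):
        mesh = trimesh.creation.box(extents=(10, 10, 10))
        open_mesh = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[:-2], process=False
        )
        with pytest.raises(ValueError, match="watertight"):
            voxelize(open_mesh)


class TestDice3D:
    def test_identical_volumes(self):
        occ = np.zeros((10, 10, 5), dtype=np.uint8)
        occ[2:8, 2:8, 1:4] = 1
        v = VoxelVolume(occ, (1.0, 1.0, 3.0), (0, 0, 0))
        assert dice_3d(v, v) == 1.0

    def test_containment_two_thirds(self):
        """B fully inside A with half the voxel count: 2c/(c+2c) = 2/3."""
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        a[0:10, 0:10, 0:2] = 1  # 200 voxels
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        b[0:10, 0:10, 0:1] = 1  # 100 voxels, contained
        va = VoxelVolume(a, (1.0, 1.0, 3.0), (0, 0, 0))
        vb = VoxelVolume(b, (1.0, 1.0, 3.0), (0, 0, 0))
        assert dice_3d(va, vb) == pytest.approx(2 / 3)

    def test_origin_offset_handled(self):
        occ = np.ones((4, 4, 4), dtype=np.uint8)
        va = VoxelVolume(occ, (1.0, 1.0, 1.0), (0, 0, 0))
        vb = VoxelVolume(occ, (1.0, 1.0, 1.0), (2.0, 0.0, 0.0))
        assert dice_3d(va, vb) == pytest.approx(2 * 32 / 128)

    def test_spacing_mismatch_rejected(self):
        occ = np.ones((2, 2, 2), dtype=np.uint8)
        va = VoxelVolume(occ, (1.0, 1.0, 3.0), (0, 0, 0))
        vb = VoxelVolume(occ, (1.0, 1.0, 1.0), (0, 0, 0))
        with pytest.raises(ValueError, match="spacing"):
            dice_3d(va, vb)


class TestJacobian:
    def test_zero_displacement_gives_unit_determinant(self):
        field = DeformationField(np.zeros((40, 40, 2)), (1.0, 1.0))
        det = jacobian_determinant(field)
        np.testing.assert_allclose(det, 1.0, atol=1e-12)

    def test_uniform_scale_gives_squared_determinant(self):
        """x' = 1.1 x, y' = 1.1 y -> det = 1.21 away from the boundary."""
        n = 48
        uu, vv = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        disp = np.stack([0.1 * uu, 0.1 * vv], axis=-1)
        det = jacobian_determinant(DeformationField(disp, (1.0, 1.0)))
        interior = det[12:-12, 12:-12]
        np.testing.assert_allclose(interior, 1.21, atol=1e-3)

    def test_matches_central_difference_oracle(self):
        """Gaussian-derivative determinant tracks a plain central-difference
        determinant within 5% interior RMS on a seeded smooth field."""
        rng = np.random.default_rng(5)
        n = 32
        uu, vv = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        disp = np.zeros((n, n, 2))
        for _ in range(3):
            ax, ay = rng.uniform(-2, 2, 2)
            fx, fy = rng.uniform(0.05, 0.15, 2)
            px, py = rng.uniform(0, 2 * np.pi, 2)
            disp[..., 0] += ax * np.sin(fx * uu + px) * np.cos(fy * vv + py)
            disp[..., 1] += ay * np.cos(fx * uu + px) * np.sin(fy * vv + py)
        det = jacobian_determinant(DeformationField(disp, (1.0, 1.0)))

        # independent oracle: central differences, no smoothing
        du_dx = np.gradient(disp[..., 0], axis=1)
        du_dy = np.gradient(disp[..., 0], axis=0)
        dv_dx = np.gradient(disp[..., 1], axis=1)
        dv_dy = np.gradient(disp[..., 1], axis=0)
        oracle = (1 + du_dx) * (1 + dv_dy) - du_dy * dv_dx

        sl = (slice(6, -6), slice(6, -6))
        rms = np.sqrt(np.mean((det[sl] - oracle[sl]) ** 2))
        scale = np.sqrt(np.mean(oracle[sl] ** 2))
        assert rms / scale < 0.05

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            jacobian_determinant(DeformationField(np.zeros((8, 8, 2)), (1, 1)), sigma=0)


class TestCompareMethods:
    def make_report(self, name, values):
        return DiceReport(name, list(enumerate(values)))

    def test_identical_reports_give_p_one(self):
        r = self.make_report("a", [0.9, 0.91, 0.92, 0.93])
        cmp_ = compare_methods({"a": r, "b": DiceReport("b", r.per_slice)})
        assert cmp_.p_values[("a", "b")] == 1.0
        assert cmp_.summary.loc["a", "mean"] == cmp_.summary.loc["b", "mean"]

    def test_summary_matches_recomputation(self):
        vals = [0.8, 0.85, 0.9, 0.95]
        r = self.make_report("m", vals)
        cmp_ = compare_methods({"m": r, "o": self.make_report("o", [0.7] * 4)})
        assert cmp_.summary.loc["m", "mean"] == pytest.approx(np.mean(vals))
        assert cmp_.summary.loc["m", "sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_index_mismatch_rejected(self):
        a = self.make_report("a", [0.9, 0.91])
        b = DiceReport("b", [(5, 0.9), (6, 0.91)])
        with pytest.raises(ValueError, match="index"):
            compare_methods({"a": a, "b": b})

    def test_phantom_method_ordering(self, pipeline_result):
        """On the phantom study the proposed method outperforms both
        baselines (the paper-style ordering)."""
        cmp_ = pipeline_result.comparison
        assert cmp_.ordering["proposed>articulated"]
        assert cmp_.ordering["proposed>rigid"]

    def test_ttest_variant_runs(self, pipeline_result):
        cmp_ = compare_methods(pipeline_result.reports, test="ttest")
        assert cmp_.p_values[("articulated", "proposed")] < 0.01
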