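import numpy as np
import pytest
import trimesh
from shapely.geometry import Point, Polygon

from torsofuse.articulated import build_articulated, cross_modality_transforms
from torsofuse.phantom import CurvatureParams, ProneParams, generate_study
from torsofuse.soft_tissue import (
    CorrespondenceSet,
    NoCutError,
    WeightedDeformation,
    distance_maps,
    extract_ray_correspondences,
    fit_edge_tps,
    invert_displacement,
    mask_contour,
    planar_cut,
    register_slice,
    weighted_displace,
)
from torsofuse.tps import evaluate_tps, fit_tps


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def bone_transforms_for(study):
    mri = build_articulated(study.spine_prone.frames, "MRI")
    xray = build_articulated(study.spine_standing.frames, "Xray")
    return dict(
        zip(study.spine_prone.labels, cross_modality_transforms(mri, xray))
    )


class TestPlanarCut:
    def test_cylinder_horizontal_cut_is_circle(self):
        mesh = trimesh.creation.cylinder(radius=150.0, height=400.0, sections=128)
        cut = planar_cut(mesh, (0, 0, 10.0), (0, 0, 1.0))
        r = np.linalg.norm(cut.points[:, :2], axis=1)
        assert np.abs(r - 150.0).max() < 0.2  # chord tolerance at 128 segments

    def test_plane_above_mesh_raises(self):
        mesh = trimesh.creation.cylinder(radius=50.0, height=100.0)
        with pytest.raises(NoCutError):
            planar_cut(mesh, (0, 0, 500.0), (0, 0, 1.0))

    def test_tilted_sphere_cut_matches_analytic_circle(self):
        """A tilted planar cut of a sphere is a circle of radius
        sqrt(R^2 - d^2) about the projected center (closed-form conic)."""
        R = 100.0
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=R)
        n = np.array([0.0, np.sin(np.radians(20)), np.cos(np.radians(20))])
        p0 = np.array([0.0, 0.0, 30.0])
        d = float(p0 @ n)
        cut = planar_cut(mesh, p0, n)
        r_analytic = np.sqrt(R**2 - d**2)
        r = np.linalg.norm(cut.points - d * n, axis=1)
        assert np.abs(r - r_analytic).max() < 0.3

    def test_multi_loop_selection_by_inside_point(self):
        a = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
        b = a.copy()
        b.vertices = b.vertices + np.array([200.0, 0.0, 0.0])
        mesh = trimesh.util.concatenate([a, b])
        cut = planar_cut(mesh, (0, 0, 0.0), (0, 0, 1.0), inside_point=(200.0, 0, 0))
        assert np.abs(cut.points[:, 0].mean() - 200.0) < 1.0


class TestRayCorrespondences:
    @pytest.fixture
    def concentric(self):
        mask = disk_mask((300, 300), (150, 150), 100)
        ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        tp = np.column_stack(
            [150 + 120 * np.cos(ang), 150 + 120 * np.sin(ang)]
        )
        return mask, tp

    def test_concentric_circles(self, concentric):
        mask, tp = concentric
        corr = extract_ray_correspondences(
            mask, tp, (150.0, 150.0), (0.0, 1.0), angular_step=30
        )
        assert len(corr) == 12  # 360 / 30 pairs
        r_t = np.linalg.norm(corr.target - (150, 150), axis=1)
        np.testing.assert_allclose(r_t, 120.0, atol=0.1)
        r_s = np.linalg.norm(corr.source - (150, 150), axis=1)
        np.testing.assert_allclose(r_s, 100.0, atol=1.0)  # raster tolerance

    def test_angle_zero_pair_along_anterior(self, concentric):
        mask, tp = concentric
        ant = np.array([0.6, 0.8])
        corr = extract_ray_correspondences(mask, tp, (150.0, 150.0), ant)
        for p in (corr.source[0], corr.target[0]):
            v = p - (150, 150)
            cross = ant[0] * v[1] - ant[1] * v[0]
            assert abs(cross) / np.linalg.norm(v) < 1e-6
            assert v @ ant > 0

    def test_center_outside_contour_rejected(self, concentric):
        mask, tp = concentric
        with pytest.raises(ValueError, match="inside"):
            extract_ray_correspondences(mask, tp, (10.0, 10.0), (0.0, 1.0))

    def test_bad_angular_step_rejected(self, concentric):
        mask, tp = concentric
        with pytest.raises(ValueError, match="divide"):
            extract_ray_correspondences(mask, tp, (150.0, 150.0), (0, 1.0), 25.0)


class TestEdgeTPS:
    def ring(self, radius, center=(150.0, 150.0), k=12):
        ang = np.radians(30.0 * np.arange(k) + 90.0)
        return np.column_stack(
            [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
        )

    def corr(self, src, tgt):
        return CorrespondenceSet(
            angles=30.0 * np.arange(len(src)),
            source=src,
            target=tgt,
            center=np.array([150.0, 150.0]),
            anterior=np.array([0.0, 1.0]),
        )

    def test_coincident_contours_identity(self, rng):
        src = self.ring(100.0)
        model = fit_edge_tps(self.corr(src, src), lam=0.0)
        held_out = rng.uniform(60, 240, (50, 2))
        np.testing.assert_allclose(evaluate_tps(model, held_out), held_out, atol=1e-8)

    def test_uniform_scaling_reproduced_everywhere(self):
        """Scaling about the center is affine: held-out contour points map
        to exactly 1.2x radius."""
        src = self.ring(100.0)
        c = np.array([150.0, 150.0])
        model = fit_edge_tps(self.corr(src, c + 1.2 * (src - c)), lam=0.0)
        probe = self.ring(100.0)[::1] + 0.0
        ang = np.linspace(0, 2 * np.pi, 37)
        probe = np.column_stack(
            [150 + 100 * np.cos(ang), 150 + 100 * np.sin(ang)]
        )
        out = evaluate_tps(model, probe)
        np.testing.assert_allclose(
            np.linalg.norm(out - c, axis=1), 120.0, atol=1e-6
        )

    def test_interpolating_fit_reproduces_targets(self, rng):
        src = self.ring(100.0) + rng.normal(0, 3, (12, 2))
        tgt = self.ring(115.0) + rng.normal(0, 3, (12, 2))
        model = fit_edge_tps(self.corr(src, tgt), lam=0.0)
        np.testing.assert_allclose(evaluate_tps(model, src), tgt, atol=1e-8)


class TestDistanceMaps:
    def test_zero_on_borders(self):
        torso = disk_mask((64, 64), (32, 32), 25)
        vert = disk_mask((64, 64), (30, 30), 8)
        d_v, d_s = distance_maps(torso, vert)
        from scipy import ndimage

        cross = ndimage.generate_binary_structure(2, 1)
        t_border = torso & ~ndimage.binary_erosion(torso, cross)
        v_border = vert & ~ndimage.binary_erosion(vert, cross)
        assert np.all(d_s[t_border] == 0)
        assert np.all(d_v[v_border] == 0)
        assert np.all(d_s[~t_border] > 0)

    def test_matches_brute_force_nearest_border(self):
        """Exact agreement with an exhaustive nearest-border-pixel scan."""
        torso = disk_mask((64, 64), (33, 31), 24)
        vert = disk_mask((64, 64), (30, 29), 7)
        d_v, d_s = distance_maps(torso, vert, pixel_size=(1.0, 1.0))
        from scipy import ndimage

        cross = ndimage.generate_binary_structure(2, 1)

        def brute(mask):
            border = np.argwhere(mask & ~ndimage.binary_erosion(mask, cross))
            yy, xx = np.mgrid[:64, :64]
            pix = np.column_stack([yy.ravel(), xx.ravel()])
            d = np.sqrt(
                ((pix[:, None, :] - border[None, :, :]) ** 2).sum(-1)
            ).min(axis=1)
            return d.reshape(64, 64)

        np.testing.assert_allclose(d_v, brute(vert), atol=1e-9)
        np.testing.assert_allclose(d_s, brute(torso), atol=1e-9)

    def test_bad_masks_rejected(self):
        torso = disk_mask((32, 32), (16, 16), 10)
        with pytest.raises(ValueError, match="non-empty"):
            distance_maps(torso, np.zeros_like(torso))
        outside = disk_mask((32, 32), (2, 2), 3)
        with pytest.raises(ValueError, match="contained"):
            distance_maps(torso, outside)


class TestWeightedDeformation:
    @pytest.fixture
    def deformation(self):
        # straight borders so nearest-border-pixel distances are exact:
        # vertebra square cols/rows 40..60, torso square 10..90
        shape = (101, 101)
        torso = np.zeros(shape, dtype=bool)
        torso[10:91, 10:91] = True
        vert = np.zeros(shape, dtype=bool)
        vert[40:61, 40:61] = True
        d_v, d_s = distance_maps(torso, vert)
        c = np.array([50.0, 50.0])
        ang = np.radians(30.0 * np.arange(12))
        src = c + 40.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        model = fit_tps(src, c + 1.2 * (src - c), lam=0.0)  # exact x1.2 scaling
        return WeightedDeformation(model, d_v, d_s, vert)

    def test_identity_inside_vertebra(self, deformation):
        p = np.array([55.0, 50.0])
        np.testing.assert_array_equal(weighted_displace(p, deformation), p)
        ij = np.argwhere(deformation.vertebra_mask)[::13].astype(float)
        pts = np.column_stack([ij[:, 1], ij[:, 0]])
        np.testing.assert_array_equal(weighted_displace(pts, deformation), pts)

    def test_full_deformation_on_torso_border(self, deformation):
        p = np.array([90.0, 50.0])  # on the torso border: D_surface = 0
        out = weighted_displace(p, deformation)
        np.testing.assert_allclose(out, [98.0, 50.0], atol=1e-6)

    def test_half_displacement_at_equal_distances(self, deformation):
        p = np.array([75.0, 50.0])  # D_vertebra = D_surface = 15
        out = weighted_displace(p, deformation)
        # full edge displacement is 0.2 * 25 = 5 mm; blended: half
        np.testing.assert_allclose(out, [77.5, 50.0], atol=1e-6)

    def test_rho_bounds(self, deformation):
        r = deformation.rho()
        assert r.min() >= 0.0 and r.max() <= 1.0
        assert np.all(r[deformation.vertebra_mask] == 0.0)

    def test_rho_monotone_along_ray(self, deformation):
        """On convex geometry the blend weight grows monotonically from
        the vertebra border (0) to the torso border (1)."""
        r = deformation.rho()
        profile = r[50, 60:91]  # from vertebra border to torso border
        assert profile[0] == 0.0 and profile[-1] == 1.0
        assert np.all(np.diff(profile) >= -1e-12)

    def test_field_inverse_consistency(self, deformation):
        """Fixed-point inversion composes with the forward field to
        near-zero residual away from the boundary."""
        field = deformation.displacement_field()
        inv = invert_displacement(field.displacements, (1.0, 1.0))
        ny, nx, _ = field.displacements.shape
        uu, vv = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
        from scipy import ndimage as ndi

        rows = vv + inv[..., 1]
        cols = uu + inv[..., 0]
        fwd = np.stack(
            [
                ndi.map_coordinates(field.displacements[..., k], [rows, cols], order=1)
                for k in range(2)
            ],
            axis=-1,
        )
        resid = np.linalg.norm(fwd + inv, axis=-1)
        interior = disk_mask((ny, nx), (50, 50), 38)
        assert resid[interior].max() < 1e-3


@pytest.fixture(scope="module")
def registered(study):
    transforms = bone_transforms_for(study)
    s = study.slices[16]
    return register_slice(s, transforms[s.vertebra_label], _tp_truth(study))


class TestRegisterSlice:
    def test_vertebra_region_is_rigid(self, registered):
        """Pairwise distances of vertebra pixels survive the full bone +
        soft-tissue composition exactly (identity branch)."""
        wd = registered.deformation
        ij = np.argwhere(wd.vertebra_mask)[::11].astype(float)
        pts = np.column_stack([ij[:, 1], ij[:, 0]])
        out = wd.displace(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_warped_contour_lands_on_tp_cut(self, registered):
        """The registered torso contour hugs the TP cut.  Between the
        30-degree correspondence rays the contour is only constrained by
        the spline, and rays fan out widely opposite the (posterior)
        vertebra center, so a few mm of between-ray deviation remain;
        at the control points themselves the fit is near-exact."""
        poly = Polygon(registered.tp_cut_2d)
        dists = [Point(*p).distance(poly.exterior) for p in registered.warped_contour_2d]
        outside = [
            Point(*p).distance(poly) for p in registered.warped_contour_2d
        ]
        assert max(outside) < 5.0
        assert np.median(dists) < 1.5  # contour hugs the cut

    def test_control_points_interpolated_with_zero_lambda(self, study):
        transforms = bone_transforms_for(study)
        s = study.slices[12]
        res = register_slice(
            s, transforms[s.vertebra_label], _tp_truth(study), lam=0.0
        )
        mapped = evaluate_tps(res.deformation.edge_model, res.correspondences.source)
        np.testing.assert_allclose(mapped, res.correspondences.target, atol=1e-6)

    def test_field_has_no_tearing(self, registered):
        """Displacement differences between 4-adjacent pixels stay small."""
        u = registered.field.displacements
        du = np.abs(np.diff(u, axis=0)).max()
        dv = np.abs(np.diff(u, axis=1)).max()
        assert max(du, dv) < 1.0

    def test_identity_phantom_slice_unchanged(self):
        """With no prone deformation at all, registration returns the
        slice unchanged up to raster tolerance."""
        study = generate_study(
            seed=3,
            prone=ProneParams(
                max_joint_rotation_deg=0.0,
                max_joint_translation_mm=0.0,
                anterior_compression=1.0,
            ),
            n_slices=5,
        )
        transforms = bone_transforms_for(study)
        s = study.slices[2]
        res = register_slice(s, transforms[s.vertebra_label], _tp_truth(study))
        assert np.abs(res.field.displacements).max() < 1.2  # sub-raster
        inter = res.slice.torso_mask & s.torso_mask
        dice = 2 * inter.sum() / (res.slice.torso_mask.sum() + s.torso_mask.sum())
        assert dice > 0.995


def _tp_truth(study):
    """TP mesh already in X-ray space (phantom ground truth)."""
    return study.torso_standing.surface
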